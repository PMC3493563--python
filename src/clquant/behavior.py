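"""Brief-access drinking (avoidance) analysis.

In a two-exposure brief-access assay each mouse first drinks plain water
(1st exposure) and then either water again (control sessions) or water
adulterated with a test compound (2nd exposure). The avoidance statistic is
the Exposure Intake Ratio (EIR), the 2nd-exposure intake divided by the
1st-exposure intake of the same mouse. Plotting mean EIR against compound
concentration gives a falling concentration-avoidance curve; its IC50-style
midpoint (here called EC50, following assay convention) quantifies the
aversiveness of the compound, and the log10 ratio of two genotypes' EC50s
is the horizontal shift between their curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import DoseResponseFit, fit_hill
from .errors import DataError, FitError

__all__ = [
    "AvoidanceCurve",
    "exposure_intake_ratio",
    "session_ratios",
    "avoidance_curve",
    "curve_shift",
]

logger = logging.getLogger(__name__)

SESSION_COLUMNS = [
    "mouse_id",
    "genotype",
    "concentration_uM",
    "intake1_ul",
    "intake2_ul",
    "session_type",
]


@dataclass(frozen=True)
class AvoidanceCurve:
    genotype: str
    table: pd.DataFrame  # concentration_uM, mean_eir, sem_eir, n
    fit: DoseResponseFit | None
    ec50: float | None

    @property
    def converged(self) -> bool:
        return self.fit is not None and self.fit.converged


def exposure_intake_ratio(intake1_ul: float, intake2_ul: float) -> float:
    """EIR = 2nd-exposure intake / 1st-exposure intake for one mouse."""
    if intake1_ul <= 0:
        raise DataError("intake1 must be > 0 to form an Exposure Intake Ratio")
    if intake2_ul < 0:
        raise DataError("intakes must be >= 0")
    return intake2_ul / intake1_ul


def session_ratios(sessions: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format EIR table (mouse_id, genotype, concentration_uM, eir).

    Sessions with zero 1st-exposure intake cannot be normalized and are
    excluded with a logged reason; mice in this assay essentially always
    sample the spout on the first exposure, so exclusions are exceptional.
    """
    missing = [c for c in SESSION_COLUMNS if c not in sessions.columns]
    if missing:
        raise DataError(f"session table is missing columns {missing}")
    usable = sessions["intake1_ul"] > 0
    for _, row in sessions.loc[~usable].iterrows():
        logger.warning(
            "excluding session (mouse %s, %.3g uM): zero 1st-exposure intake",
            row["mouse_id"],
            row["concentration_uM"],
        )
    kept = sessions.loc[usable].copy()
    kept["eir"] = kept["intake2_ul"] / kept["intake1_ul"]
    return kept[["mouse_id", "genotype", "concentration_uM", "eir"]].reset_index(
        drop=True
    )


def avoidance_curve(
    sessions: pd.DataFrame, min_concentrations: int = 4, min_mice: int = 2
) -> AvoidanceCurve:
    """Concentration-avoidance curve for one genotype.

    Computes mean EIR (+/- SEM) per concentration over the test sessions
    (``session_type == "solvent_capsaicin"`` rows with concentration > 0)
    and fits the falling Hill (inhibition) form to the per-concentration
    means, as for a mean avoidance curve. Degenerate data (no avoidance)
    yield ``fit=None`` / ``ec50=None`` instead of raising.
    """
    genotypes = sessions["genotype"].unique()
    if len(genotypes) != 1:
        raise DataError(f"expected a single genotype, got {list(genotypes)}")
    test = sessions[sessions["concentration_uM"] > 0]
    eirs = session_ratios(test)
    grouped = eirs.groupby("concentration_uM")["eir"]
    table = (
        pd.DataFrame(
            {
                "mean_eir": grouped.mean(),
                "sem_eir": grouped.sem(),
                "n": grouped.size(),
            }
        )
        .reset_index()
        .sort_values("concentration_uM", ignore_index=True)
    )
    if len(table) < min_concentrations:
        raise DataError(
            f"need >= {min_concentrations} concentrations, got {len(table)}"
        )
    if (table["n"] < min_mice).any():
        raise DataError(f"every concentration needs >= {min_mice} mice")
    try:
        fit = fit_hill(
            table["concentration_uM"], table["mean_eir"], direction="inhibition"
        )
    except FitError:
        logger.warning("avoidance curve degenerate for %s; no EC50", genotypes[0])
        return AvoidanceCurve(str(genotypes[0]), table, fit=None, ec50=None)
    return AvoidanceCurve(str(genotypes[0]), table, fit=fit, ec50=fit.ec50)


def curve_shift(curve_a: AvoidanceCurve, curve_b: AvoidanceCurve) -> float:
    """Rightward shift of curve_b relative to curve_a, log10(ec50_b / ec50_a)."""
    for curve in (curve_a, curve_b):
        if not curve.converged:
            raise FitError(
                f"avoidance fit for {curve.genotype!r} did not converge; "
                "shift undefined"
            )
    return float(np.log10(curve_b.ec50 / curve_a.ec50))
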