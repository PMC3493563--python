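"""Stern-Volmer calibration of a chloride-sensitive dye.

The dye (MQAE) is quenched collisionally by chloride:

    F0 / F = 1 + Ksv * [Cl-]

where F0 is the fluorescence at 0 mM chloride, F the steady-state
fluorescence at a known chloride concentration and Ksv the Stern-Volmer
constant (per molar). Calibration uses the double-ionophore technique:
ionophores equilibrate cytosolic chloride with a series of bath
concentrations (0, 20, 40, 60 mM by default), each held until the
fluorescence plateaus. Per cell, Ksv is the slope of the through-origin
regression of (F0/F - 1) on concentration; resting chloride is then read
off the resting fluorescence via the inverted relation.

All concentrations enter the regression in molar, so Ksv is in M^-1 while
the rest of the package works in mM; the conversion happens exactly once,
in :func:`fit_stern_volmer` / :func:`estimate_cl`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError, ProtocolError
from .traces import FluorescenceTrace

__all__ = [
    "CalibrationStep",
    "StepPlateau",
    "SternVolmerFit",
    "CellChlorideEstimate",
    "PopulationDistribution",
    "detect_steady_states",
    "fit_stern_volmer",
    "estimate_cl",
    "summarize_population",
    "bleaching_check",
    "calibrate_cells",
]

#: default fraction of each step used as the plateau tail
PLATEAU_FRAC = 0.2
#: default unsteadiness threshold: relative slope per frame over the tail
SLOPE_TOL = 5e-4
#: per-cell goodness-of-fit gate for population summaries
R2_THRESHOLD = 0.9


@dataclass(frozen=True)
class CalibrationStep:
    """One solution-exchange step of the double-ionophore protocol."""

    cl_mM: float
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.cl_mM < 0:
            raise ProtocolError(f"cl_mM must be >= 0, got {self.cl_mM}")
        if self.end_s <= self.start_s:
            raise ProtocolError("step end_s must exceed start_s")


@dataclass(frozen=True)
class StepPlateau:
    cl_mM: float
    fluorescence: float
    steady: bool
    rel_slope_per_frame: float


@dataclass(frozen=True)
class SternVolmerFit:
    f0: float
    ksv_per_M: float
    r_squared: float
    n_points: int
    cell_id: str = ""
    physical: bool = True  # False when ksv <= 0


@dataclass(frozen=True)
class CellChlorideEstimate:
    cell_id: str
    cl_i_mM: float
    f_rest: float
    fit: SternVolmerFit
    quality_flag: str  # ok | clamped | low_r2


@dataclass(frozen=True)
class PopulationDistribution:
    values: np.ndarray
    mean: float
    sem: float
    n: int
    n_excluded: int = 0


def detect_steady_states(
    trace: FluorescenceTrace,
    steps: Sequence[CalibrationStep],
    plateau_frac: float = PLATEAU_FRAC,
    slope_tol: float = SLOPE_TOL,
) -> list[StepPlateau]:
    """Plateau fluorescence per calibration step.

    The plateau is the mean over the last ``plateau_frac`` of the frames in
    each step window. A step is flagged unsteady when the linear slope over
    that tail, relative to the plateau level, exceeds ``slope_tol`` per
    frame (the cell had not equilibrated before the next exchange).
    """
    if not 0 < plateau_frac <= 1:
        raise ValueError("plateau_frac must be in (0, 1]")
    t0, t1 = trace.time_s[0], trace.time_s[-1]
    # step windows are half-open [start, end): an end one frame past the last
    # timestamp still covers recorded frames only
    dt = float(np.median(np.diff(trace.time_s))) if len(trace) > 1 else 0.0
    plateaus: list[StepPlateau] = []
    for step in steps:
        if step.start_s < t0 - 1e-9 or step.end_s > t1 + dt + 1e-9:
            raise ProtocolError(
                f"step window [{step.start_s}, {step.end_s}] s outside trace "
                f"[{t0}, {t1}] s"
            )
        mask = (trace.time_s >= step.start_s) & (trace.time_s < step.end_s)
        values = trace.values[mask]
        n_tail = max(2, int(round(plateau_frac * values.size)))
        tail = values[-n_tail:]
        level = float(np.mean(tail))
        slope = float(np.polyfit(np.arange(n_tail), tail, 1)[0])
        rel_slope = abs(slope) / abs(level) if level != 0 else np.inf
        plateaus.append(
            StepPlateau(step.cl_mM, level, rel_slope <= slope_tol, rel_slope)
        )
    if len(plateaus) < 2:
        raise CalibrationError("fewer than 2 calibration steps")
    return plateaus


def fit_stern_volmer(
    points: Iterable[tuple[float, float]], cell_id: str = ""
) -> SternVolmerFit:
    """Per-cell Stern-Volmer fit from (concentration mM, fluorescence) pairs.

    F0 is the mean fluorescence of the 0 mM point(s); the slope of the
    through-origin regression of (F0/F - 1) on concentration (in molar) is
    Ksv. The coefficient of determination is the uncentered r-squared of the
    through-origin model.
    """
    pts = [(float(c), float(f)) for c, f in points]
    if len({c for c, _ in pts}) < 2:
        raise CalibrationError("need >= 2 distinct concentrations")
    zero_f = [f for c, f in pts if c == 0.0]
    if not zero_f:
        raise CalibrationError(
            "no 0 mM point: F0 is undefined "
            f"(concentrations present: {sorted({c for c, _ in pts})} mM)"
        )
    f0 = float(np.mean(zero_f))
    if f0 <= 0:
        raise DataError("F0 must be > 0")
    conc_M = np.array([c for c, _ in pts if c > 0.0]) / 1000.0
    f = np.array([fv for c, fv in pts if c > 0.0])
    if np.any(f <= 0):
        raise DataError("fluorescence must be > 0 at every step")
    y = f0 / f - 1.0
    sxx = float(np.dot(conc_M, conc_M))
    ksv = float(np.dot(conc_M, y) / sxx)
    ss_res = float(np.sum((y - ksv * conc_M) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SternVolmerFit(
        f0=f0,
        ksv_per_M=ksv,
        r_squared=r2,
        n_points=len(pts),
        cell_id=cell_id,
        physical=ksv > 0,
    )


def estimate_cl(
    f_rest: float, fit: SternVolmerFit, r2_threshold: float = R2_THRESHOLD
) -> CellChlorideEstimate:
    """Resting [Cl-]i (mM) from resting fluorescence and a per-cell fit.

    cl_i = (F0/F_rest - 1) / Ksv, converted to mM. Raw negative estimates
    (F_rest above F0, expected for noisy low-chloride cells) clamp to 0 mM
    with flag ``clamped``; fits below the r-squared gate flag ``low_r2``.
    """
    if f_rest <= 0:
        raise DataError("f_rest must be > 0")
    if fit.ksv_per_M <= 0:
        raise CalibrationError("non-physical fit (ksv <= 0); cannot estimate [Cl-]i")
    raw_mM = (fit.f0 / f_rest - 1.0) / fit.ksv_per_M * 1000.0
    if fit.r_squared < r2_threshold:
        flag = "low_r2"
    elif raw_mM < 0:
        flag = "clamped"
    else:
        flag = "ok"
    return CellChlorideEstimate(
        cell_id=fit.cell_id,
        cl_i_mM=max(raw_mM, 0.0),
        f_rest=float(f_rest),
        fit=fit,
        quality_flag=flag,
    )


def summarize_population(
    estimates: Iterable[CellChlorideEstimate],
) -> PopulationDistribution:
    """Mean, SEM and n of [Cl-]i over ok-flagged cells; others counted as excluded."""
    estimates = list(estimates)
    ok = [e.cl_i_mM for e in estimates if e.quality_flag == "ok"]
    if not ok:
        raise CalibrationError("no usable (ok-flagged) cells in population")
    values = np.asarray(ok)
    n = values.size
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return PopulationDistribution(
        values=values,
        mean=float(np.mean(values)),
        sem=sem,
        n=n,
        n_excluded=len(estimates) - n,
    )


def bleaching_check(
    trace: FluorescenceTrace,
    window_s: float = 600.0,
    threshold_per_min: float = 0.01,
) -> tuple[float, bool]:
    """Photobleaching drift over an unstimulated segment.

    Returns (relative slope per minute, passed). The drift is the linear
    slope of F over the first ``window_s`` seconds divided by the segment
    mean; |drift| above ``threshold_per_min`` (default 1 %/min) fails.
    """
    mask = trace.time_s <= trace.time_s[0] + window_s
    if trace.time_s[mask].size < 3 or (
        trace.time_s[mask][-1] - trace.time_s[0] < window_s * 0.99
    ):
        raise DataError(f"trace shorter than the {window_s} s bleaching window")
    t_min = (trace.time_s[mask] - trace.time_s[0]) / 60.0
    values = trace.values[mask]
    slope = float(np.polyfit(t_min, values, 1)[0])
    drift = slope / float(np.mean(values))
    return drift, abs(drift) <= threshold_per_min


def calibrate_cells(
    traces: pd.DataFrame,
    steps: Sequence[CalibrationStep],
    rest_window: tuple[float, float],
    plateau_frac: float = PLATEAU_FRAC,
    slope_tol: float = SLOPE_TOL,
    r2_threshold: float = R2_THRESHOLD,
) -> list[CellChlorideEstimate]:
    """Full per-cell calibration over a trace table.

    ``traces`` is the standard wide table (column ``time_s`` plus one column
    per cell). The resting fluorescence is the plateau (tail mean) of the
    ``rest_window`` recorded before the ionophore steps.
    """
    time_s = traces["time_s"].to_numpy()
    estimates = []
    for cell in (c for c in traces.columns if c != "time_s"):
        trace = FluorescenceTrace(time_s, traces[cell].to_numpy(), cell_id=cell)
        rest_mask = (time_s >= rest_window[0]) & (time_s < rest_window[1])
        rest_values = trace.values[rest_mask]
        if rest_values.size < 2:
            raise ProtocolError("rest window not covered by trace")
        n_tail = max(2, int(round(plateau_frac * rest_values.size)))
        f_rest = float(np.mean(rest_values[-n_tail:]))
        plateaus = detect_steady_states(trace, steps, plateau_frac, slope_tol)
        fit = fit_stern_volmer(
            [(p.cl_mM, p.fluorescence) for p in plateaus], cell_id=cell
        )
        estimates.append(estimate_cl(f_rest, fit, r2_threshold=r2_threshold))
    return estimates
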