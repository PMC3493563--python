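"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the package (calibration, classification,
equilibrium prediction, dose-response and behavior fitting) is exercised on
data from these generators, whose true parameters are returned alongside
the traces so recovery can be asserted exactly.

What is emulated
----------------
* a cell population with an approximately Gaussian resting [Cl-]i
  distribution (truncated to a plausible single-cell range), per-cell
  Stern-Volmer constants and per-cell baseline brightness;
* double-ionophore calibration recordings: stepwise solution exchanges with
  first-order equilibration to each plateau, multiplicative frame noise and
  optional photobleaching;
* agonist stimulation recordings in which each cell's [Cl-]i relaxes
  first-order toward the equilibrium concentration set by the membrane
  potential — cells above the critical concentration lose chloride (dye
  fluorescence rises), cells below gain it;
* dual-channel Fura-2 recordings whose ratio transients grow with the
  chloride driving force (the chloride-amplification effect);
* brief-access drinking sessions whose intake suppression follows a Hill
  avoidance curve.

Randomness: one master seed; each generator draws from its own named
substream so modules stay decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .equilibrium import EquilibriumContext, critical_cli
from .errors import ConfigurationError
from .io import ProtocolStep

__all__ = [
    "PopulationParams",
    "KineticsParams",
    "FuraParams",
    "BehaviorParams",
    "gen_cell_population",
    "gen_calibration_traces",
    "gen_stimulation_traces",
    "gen_fura_traces",
    "gen_drinking_sessions",
    "gen_dose_response_points",
    "default_stimulation_protocol",
    "DEFAULT_CONTEXT",
    "GABA_EC50_UM",
    "GABA_HILL",
    "BICUCULLINE_IC50_UM",
    "BICUCULLINE_HILL",
]

# default ionic/electrical conditions of the imaging experiments
DEFAULT_CONTEXT = EquilibriumContext(cl_out_mM=151.0, rmp_mV=-54.0)

# default GABA activation curve (half-maximal dose in uM) and the
# GABA_A-antagonist inhibition curve used by the dose-response generator
GABA_EC50_UM = 24.7
GABA_HILL = 2.1
BICUCULLINE_IC50_UM = 1.3
BICUCULLINE_HILL = 1.0

# named substreams off the master seed
_STREAMS = {
    "population": 101,
    "calibration": 102,
    "stimulation": 103,
    "fura": 104,
    "behavior": 105,
    "dose": 106,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class PopulationParams:
    """Resting-[Cl-]i population and per-cell dye parameters.

    ``mean_cl`` is the mean of the *truncated* distribution actually
    sampled: the generator solves for the underlying Gaussian location so
    that truncation to [lower_trunc, upper_trunc] does not shift the
    population mean away from the target.
    """

    mean_cl: float = 34.1  # mM
    sd_cl: float = 27.6  # mM (Gaussian scale before truncation)
    lower_trunc: float = 2.0  # mM
    upper_trunc: float = 110.0  # mM
    n_cells: int = 200
    ksv_mean: float = 14.4  # M^-1
    ksv_sd: float = 3.3  # M^-1
    f0_mean: float = 100.0  # a.u.
    f0_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.upper_trunc <= self.lower_trunc:
            raise ConfigurationError("upper_trunc must exceed lower_trunc")
        if self.lower_trunc < 0 or self.sd_cl < 0:
            raise ConfigurationError("lower_trunc and sd_cl must be >= 0")
        if not self.lower_trunc <= self.mean_cl <= self.upper_trunc:
            raise ConfigurationError("mean_cl must lie within the truncation bounds")
        if self.ksv_mean <= 0 or self.n_cells < 1:
            raise ConfigurationError("ksv_mean must be > 0 and n_cells >= 1")

    @classmethod
    def wild_type(cls, n_cells: int = 200) -> "PopulationParams":
        """Untreated population: mean 34.1 mM, SD 27.6 mM."""
        return cls(mean_cl=34.1, sd_cl=27.6, n_cells=n_cells)

    @classmethod
    def nkcc1_ko(cls, n_cells: int = 200) -> "PopulationParams":
        """Cotransporter-knockout population: mean 13.2 mM, SD 6.3 mM."""
        return cls(mean_cl=13.2, sd_cl=6.3, n_cells=n_cells)

    @classmethod
    def bumetanide(cls, n_cells: int = 200) -> "PopulationParams":
        """Cotransporter-blocked population: mean 10.9 mM, SD 6.5 mM."""
        return cls(mean_cl=10.9, sd_cl=6.5, n_cells=n_cells)


@dataclass(frozen=True)
class KineticsParams:
    """Phenomenological trace kinetics (first-order [Cl-]i relaxation)."""

    rate_constant: float = 0.05  # 1/s
    noise_sd: float = 0.01  # relative (multiplicative) per frame
    bleach_rate: float = 0.0  # fractional fluorescence loss per frame

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ConfigurationError("rate_constant must be > 0")
        if self.noise_sd < 0 or self.bleach_rate < 0:
            raise ConfigurationError("noise_sd and bleach_rate must be >= 0")


@dataclass(frozen=True)
class FuraParams:
    """Fura-2 transient shape and chloride amplification.

    Per-cell peak ratio amplitude:
        base_amplitude * (1 + amplification * max(0, cl_i - critical)/critical)
    so cells without outward chloride driving force show the unamplified
    transient. The default ``amplification`` is tuned so the default
    low-chloride population's mean amplitude is ~38% below the untreated
    population's.
    """

    f340_baseline: float = 50.0
    f380_baseline: float = 100.0
    base_amplitude: float = 0.5  # peak delta-ratio for zero driving force
    amplification: float = 0.65
    rise_tau_s: float = 1.0
    decay_tau_s: float = 5.0
    f380_floor_frac: float = 1e-3  # floor on f380 as a fraction of its baseline

    def __post_init__(self) -> None:
        if min(self.f340_baseline, self.f380_baseline) <= 0:
            raise ConfigurationError("Fura channel baselines must be > 0")
        if self.base_amplitude < 0 or self.amplification < 0:
            raise ConfigurationError("amplitudes must be >= 0")


@dataclass(frozen=True)
class BehaviorParams:
    """Brief-access drinking avoidance parameters.

    Intake noise is multiplicative log-normal per intake; the default CV
    of 0.15 per intake gives a per-session EIR CV of ~0.21, matching the
    observed spread of control-day ratios.
    """

    ec50: float = 6.4  # uM
    hill_n: float = 1.2
    baseline_eir: float = 1.11
    intake1_mean: float = 242.0  # ul
    intake_noise_cv: float = 0.15
    n_mice: int = 11

    def __post_init__(self) -> None:
        if min(self.ec50, self.hill_n, self.baseline_eir, self.intake1_mean) <= 0:
            raise ConfigurationError("behavior parameters must be > 0")
        if self.n_mice < 1:
            raise ConfigurationError("n_mice must be >= 1")

    @classmethod
    def wild_type(cls) -> "BehaviorParams":
        return cls(ec50=6.4, baseline_eir=1.11)

    @classmethod
    def nkcc1_ko(cls) -> "BehaviorParams":
        return cls(ec50=17.3, baseline_eir=1.15)


# ---------------------------------------------------------------------------
# population


def _matched_location(target_mean, sd, lower, upper):
    """Underlying Gaussian location whose [lower, upper]-truncation has the target mean."""
    def shift(mu):
        a, b = (lower - mu) / sd, (upper - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    return optimize.brentq(shift, lower - 10 * sd, upper + 10 * sd, xtol=1e-12)


def gen_cell_population(params: PopulationParams, seed: int) -> pd.DataFrame:
    """Sample cell records (cell_id, cl_i_mM, ksv_per_M, f0).

    [Cl-]i is a truncated Gaussian with post-truncation mean ``mean_cl``;
    the quenching constant is a Gaussian truncated to positive values; the
    baseline brightness is log-normal (mean ``f0_mean``, CV ``f0_cv``).
    Deterministic given the seed.
    """
    rng = _rng(seed, "population")
    n = params.n_cells
    if params.sd_cl == 0:
        cl = np.full(n, params.mean_cl)
    else:
        mu = _matched_location(
            params.mean_cl, params.sd_cl, params.lower_trunc, params.upper_trunc
        )
        a = (params.lower_trunc - mu) / params.sd_cl
        b = (params.upper_trunc - mu) / params.sd_cl
        cl = stats.truncnorm.rvs(
            a, b, loc=mu, scale=params.sd_cl, size=n, random_state=rng
        )
    if params.ksv_sd == 0:
        ksv = np.full(n, params.ksv_mean)
    else:
        a_k = (0.0 - params.ksv_mean) / params.ksv_sd
        ksv = stats.truncnorm.rvs(
            a_k, np.inf, loc=params.ksv_mean, scale=params.ksv_sd, size=n,
            random_state=rng,
        )
    f0 = _lognormal(rng, params.f0_mean, params.f0_cv, n)
    width = len(str(n - 1))
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i:0{width}d}" for i in range(n)],
            "cl_i_mM": cl,
            "ksv_per_M": ksv,
            "f0": f0,
        }
    )


def _lognormal(rng, mean, cv, size):
    """Log-normal draws with the given arithmetic mean and CV (constant if cv=0)."""
    if cv == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _quench(cl_mM: np.ndarray, f0: np.ndarray, ksv: np.ndarray) -> np.ndarray:
    """Forward Stern-Volmer model, concentrations in mM."""
    return f0 / (1.0 + ksv * cl_mM / 1000.0)


def _relax_concentration(
    time_s: np.ndarray,
    segments: list[tuple[float, float, np.ndarray]],
    start_cl: np.ndarray,
    rate: float,
) -> np.ndarray:
    """Piecewise first-order relaxation of per-cell concentration.

    segments: (start_s, end_s, per-cell target concentration). Returns an
    array (n_frames, n_cells); each segment starts from the analytic end
    state of the previous one.
    """
    n_cells = start_cl.size
    cl = np.empty((time_s.size, n_cells))
    current = start_cl.astype(float).copy()
    for start_s, end_s, target in segments:
        mask = (time_s >= start_s) & (time_s < end_s)
        dt = time_s[mask] - start_s
        cl[mask] = target + (current - target) * np.exp(-rate * dt)[:, None]
        current = target + (current - target) * np.exp(-rate * (end_s - start_s))
    return cl


def _apply_noise_and_bleach(
    f: np.ndarray, kinetics: KineticsParams, rng: np.random.Generator
) -> np.ndarray:
    if kinetics.bleach_rate > 0:
        frames = np.arange(f.shape[0])
        f = f * (1.0 - kinetics.bleach_rate) ** frames[:, None]
    if kinetics.noise_sd > 0:
        f = f * (1.0 + kinetics.noise_sd * rng.standard_normal(f.shape))
    return f


def _trace_frame(time_s: np.ndarray, f: np.ndarray, cells: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(f, columns=list(cells["cell_id"]))
    out.insert(0, "time_s", time_s)
    return out


# ---------------------------------------------------------------------------
# calibration traces


def gen_calibration_traces(
    cells: pd.DataFrame,
    conc_steps: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0),
    step_duration_s: float = 600.0,
    rest_duration_s: float = 120.0,
    dt_s: float = 2.0,
    kinetics: KineticsParams = KineticsParams(),
    seed: int = 0,
) -> tuple[pd.DataFrame, list[ProtocolStep], dict]:
    """Double-ionophore calibration recordings.

    The trace opens with a resting segment at each cell's own [Cl-]i (the
    resting-fluorescence reference), then steps through the calibration
    solutions; within each step the cytosolic concentration equilibrates
    first-order, and each step lasts long enough (default 10 min) for a
    steady state. Returns (trace table, protocol, ground truth).
    """
    if not conc_steps:
        raise ConfigurationError("conc_steps must be non-empty")
    if 0.0 not in conc_steps:
        raise ConfigurationError("conc_steps must include 0 mM (defines F0)")
    rng = _rng(seed, "calibration")
    n_cells = len(cells)
    cl_rest = cells["cl_i_mM"].to_numpy()

    total = rest_duration_s + step_duration_s * len(conc_steps)
    time_s = np.arange(0.0, total, dt_s)
    protocol = [ProtocolStep("rest", 0.0, rest_duration_s)]
    segments = [(0.0, rest_duration_s, cl_rest)]
    t = rest_duration_s
    for conc in conc_steps:
        protocol.append(
            ProtocolStep(f"cal_{conc:g}mM", t, t + step_duration_s, cl_mM=float(conc))
        )
        segments.append((t, t + step_duration_s, np.full(n_cells, float(conc))))
        t += step_duration_s

    cl = _relax_concentration(time_s, segments, cl_rest, kinetics.rate_constant)
    f = _quench(cl, cells["f0"].to_numpy(), cells["ksv_per_M"].to_numpy())
    f = _apply_noise_and_bleach(f, kinetics, rng)
    truth = {
        "cells": cells.to_dict(orient="records"),
        "conc_steps_mM": list(conc_steps),
        "kinetics": {
            "rate_constant": kinetics.rate_constant,
            "noise_sd": kinetics.noise_sd,
            "bleach_rate": kinetics.bleach_rate,
        },
    }
    return _trace_frame(time_s, f, cells), protocol, truth


# ---------------------------------------------------------------------------
# stimulation traces


def default_stimulation_protocol(
    pre_s: float = 30.0,
    stim_s: float = 30.0,
    post_s: float = 60.0,
    stimulus: str = "GABA",
) -> list[ProtocolStep]:
    """Baseline / stimulus / washout protocol."""
    return [
        ProtocolStep("baseline", 0.0, pre_s),
        ProtocolStep(stimulus, pre_s, pre_s + stim_s, stimulus=stimulus),
        ProtocolStep("washout", pre_s + stim_s, pre_s + stim_s + post_s),
    ]


def gen_stimulation_traces(
    cells: pd.DataFrame,
    protocol: list[ProtocolStep] | None = None,
    ctx: EquilibriumContext = DEFAULT_CONTEXT,
    kinetics: KineticsParams = KineticsParams(),
    dt_s: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[ProtocolStep], dict]:
    """Chloride-dye recordings under agonist stimulation.

    While the stimulus is on, each cell's [Cl-]i relaxes first-order toward
    the critical concentration set by the membrane potential (the chloride
    conductance is open, so the cell runs toward electrochemical
    equilibrium); cells above it lose chloride and brighten, cells below
    gain and dim. Off stimulus, [Cl-]i recovers toward its resting value.

    Ground truth carries, per cell, the predicted direction and both the
    full-equilibration and actually-attained fluorescence changes (%).
    """
    if protocol is None:
        protocol = default_stimulation_protocol()
    rng = _rng(seed, "stimulation")
    cl_rest = cells["cl_i_mM"].to_numpy()
    f0 = cells["f0"].to_numpy()
    ksv = cells["ksv_per_M"].to_numpy()
    crit = critical_cli(ctx)

    time_s = np.arange(protocol[0].start_s, protocol[-1].end_s, dt_s)
    segments = []
    current = cl_rest.astype(float).copy()
    attained = None
    for step in protocol:
        target = np.full(current.size, crit) if step.stimulus else cl_rest
        segments.append((step.start_s, step.end_s, target))
        current = target + (current - target) * np.exp(
            -kinetics.rate_constant * (step.end_s - step.start_s)
        )
        if step.stimulus:
            attained = current.copy()

    cl = _relax_concentration(time_s, segments, cl_rest, kinetics.rate_constant)
    f = _quench(cl, f0, ksv)
    f = _apply_noise_and_bleach(f, kinetics, rng)

    f_rest = _quench(cl_rest, f0, ksv)
    plateau_pct = 100.0 * (_quench(np.full_like(cl_rest, crit), f0, ksv) / f_rest - 1.0)
    attained_pct = (
        100.0 * (_quench(attained, f0, ksv) / f_rest - 1.0)
        if attained is not None
        else np.zeros_like(cl_rest)
    )
    direction = np.where(
        cl_rest > crit, "efflux", np.where(cl_rest < crit, "influx", "none")
    )
    truth = {
        "critical_cl_mM": crit,
        "rmp_mV": ctx.rmp_mV,
        "cl_out_mM": ctx.cl_out_mM,
        "cells": [
            {
                "cell_id": cid,
                "cl_i_mM": c,
                "direction": d,
                "plateau_delta_f_pct": p,
                "attained_delta_f_pct": a,
            }
            for cid, c, d, p, a in zip(
                cells["cell_id"], cl_rest, direction, plateau_pct, attained_pct
            )
        ],
        "efflux_fraction": float(np.mean(cl_rest > crit)),
    }
    return _trace_frame(time_s, f, cells), protocol, truth


# ---------------------------------------------------------------------------
# Fura-2 traces


def gen_fura_traces(
    cells: pd.DataFrame,
    protocol: list[ProtocolStep] | None = None,
    fura: FuraParams = FuraParams(),
    ctx: EquilibriumContext = DEFAULT_CONTEXT,
    kinetics: KineticsParams = KineticsParams(),
    dt_s: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ProtocolStep], dict]:
    """Dual-channel (f340, f380) calcium recordings.

    Each stimulus evokes one ratio transient (exponential rise while the
    stimulus is on, exponential decay after) whose peak amplitude grows
    with the cell's outward chloride driving force per
    :class:`FuraParams`. Returns (f340 table, f380 table, protocol, truth).
    """
    if protocol is None:
        protocol = default_stimulation_protocol()
    rng = _rng(seed, "fura")
    crit = critical_cli(ctx)
    cl_rest = cells["cl_i_mM"].to_numpy()
    amplitude = fura.base_amplitude * (
        1.0 + fura.amplification * np.maximum(0.0, cl_rest - crit) / crit
    )

    time_s = np.arange(protocol[0].start_s, protocol[-1].end_s, dt_s)
    shape = np.zeros(time_s.size)
    for step in protocol:
        if not step.stimulus:
            continue
        on = (time_s >= step.start_s) & (time_s < step.end_s)
        shape[on] = np.maximum(
            shape[on], 1.0 - np.exp(-(time_s[on] - step.start_s) / fura.rise_tau_s)
        )
        after = time_s >= step.end_s
        peak = 1.0 - np.exp(-(step.end_s - step.start_s) / fura.rise_tau_s)
        shape[after] = np.maximum(
            shape[after],
            peak * np.exp(-(time_s[after] - step.end_s) / fura.decay_tau_s),
        )

    r0 = fura.f340_baseline / fura.f380_baseline
    q = amplitude / r0  # relative ratio excursion at full transient
    u = q / (2.0 + q)  # symmetric channel deflection giving that excursion
    s = shape[:, None] * u[None, :]
    f340 = fura.f340_baseline * (1.0 + s)
    f380 = fura.f380_baseline * (1.0 - s)
    if kinetics.noise_sd > 0:
        f340 = f340 * (1.0 + kinetics.noise_sd * rng.standard_normal(f340.shape))
        f380 = f380 * (1.0 + kinetics.noise_sd * rng.standard_normal(f380.shape))
    f380 = np.maximum(f380, fura.f380_floor_frac * fura.f380_baseline)

    truth = {
        "critical_cl_mM": crit,
        "baseline_ratio": r0,
        "amplitudes": {
            cid: a for cid, a in zip(cells["cell_id"], amplitude)
        },
    }
    return (
        _trace_frame(time_s, f340, cells),
        _trace_frame(time_s, f380, cells),
        protocol,
        truth,
    )


# ---------------------------------------------------------------------------
# drinking sessions


def gen_drinking_sessions(
    params: BehaviorParams,
    concentrations: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
    genotype: str = "WT",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Brief-access drinking sessions for one genotype cohort.

    Per mouse: one water/water control session (concentration 0) plus one
    test session per concentration. First-exposure intake is log-normal
    around ``intake1_mean``; second-exposure intake is suppressed by the
    Hill avoidance curve

        EIR(c) = baseline_eir / (1 + (c / ec50)^hill_n)

    with multiplicative log-normal noise on each intake.
    """
    if any(c <= 0 for c in concentrations):
        raise ConfigurationError("concentrations must be > 0")
    rng = _rng(seed, "behavior")
    rows = []
    for m in range(params.n_mice):
        mouse = f"{genotype}_m{m:02d}"
        intake1 = _lognormal(rng, params.intake1_mean, params.intake_noise_cv, 1)[0]
        intake2 = (
            intake1
            * params.baseline_eir
            * _lognormal(rng, 1.0, params.intake_noise_cv, 1)[0]
        )
        rows.append((mouse, genotype, 0.0, intake1, intake2, "water_water"))
        for c in concentrations:
            intake1 = _lognormal(rng, params.intake1_mean, params.intake_noise_cv, 1)[0]
            eir = params.baseline_eir / (1.0 + (c / params.ec50) ** params.hill_n)
            intake2 = intake1 * eir * _lognormal(rng, 1.0, params.intake_noise_cv, 1)[0]
            rows.append((mouse, genotype, float(c), intake1, intake2, "solvent_capsaicin"))
    sessions = pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "genotype",
            "concentration_uM",
            "intake1_ul",
            "intake2_ul",
            "session_type",
        ],
    )
    truth = {
        "genotype": genotype,
        "ec50_uM": params.ec50,
        "hill_n": params.hill_n,
        "baseline_eir": params.baseline_eir,
        "expected_eir": {
            float(c): params.baseline_eir / (1.0 + (c / params.ec50) ** params.hill_n)
            for c in concentrations
        },
    }
    return sessions, truth


# ---------------------------------------------------------------------------
# dose-response points


def gen_dose_response_points(
    concentrations: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
    ec50: float = GABA_EC50_UM,
    hill_n: float = GABA_HILL,
    top: float = 1.0,
    bottom: float = 0.0,
    direction: str = "activation",
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Hill-curve sample points, optionally with multiplicative noise.

    Defaults reproduce the GABA activation curve (EC50 24.7 uM, Hill 2.1)
    normalized to [0, 1].
    """
    conc = np.asarray(concentrations, dtype=float)
    if direction == "activation":
        resp = bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill_n)
    elif direction == "inhibition":
        resp = bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill_n)
    else:
        raise ConfigurationError(f"unknown direction {direction!r}")
    if noise_cv > 0:
        rng = _rng(seed, "dose")
        resp = resp * (1.0 + noise_cv * rng.standard_normal(resp.size))
    points = pd.DataFrame({"concentration_uM": conc, "response": resp})
    truth = {
        "ec50": ec50,
        "hill_n": hill_n,
        "top": top,
        "bottom": bottom,
        "direction": direction,
    }
    return points, truth
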