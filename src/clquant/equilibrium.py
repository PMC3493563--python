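"""Nernst-equation computations for chloride.

The chloride reversal potential of a cell with intracellular concentration
``[Cl-]i`` bathed in ``[Cl-]o`` is

    E_Cl = -(RT / zF) ln([Cl-]o / [Cl-]i) = s * log10([Cl-]i / [Cl-]o)

for the chloride valence z = -1, where ``s`` is the decade slope
(mV per tenfold concentration ratio).  Opening a chloride conductance
depolarizes the cell (chloride efflux) exactly when E_Cl is more positive
than the resting membrane potential (RMP); rearranging, efflux requires

    [Cl-]i > [Cl-]o * 10^(RMP / s)

which we call the *critical* intracellular chloride concentration.

Two slope conventions are supported: a fixed constant (default 58.0
mV/decade, the rounded room-temperature value that reproduces the
commonly quoted 17.7 mM critical concentration at RMP -54 mV and
[Cl-]o 151 mM) and the physically exact temperature-derived slope
``ln(10)*R*T/F`` (58.56 mV/decade at 22 degC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "decade_slope_mv",
    "EquilibriumContext",
    "EquilibriumResult",
    "nernst_ecl",
    "critical_cli",
    "efflux_fraction",
    "efflux_fraction_gaussian",
    "classify_equilibrium",
]

GAS_CONSTANT = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212  # C / mol


def decade_slope_mv(temperature_c: float) -> float:
    """Nernst decade slope ln(10)*R*T/F in mV at the given temperature (degC)."""
    t_kelvin = temperature_c + 273.15
    return math.log(10.0) * GAS_CONSTANT * t_kelvin / FARADAY * 1000.0


@dataclass(frozen=True)
class EquilibriumContext:
    """Ionic and electrical context for chloride equilibrium calculations.

    Parameters
    ----------
    cl_out_mM : extracellular chloride concentration, mM.
    rmp_mV : resting membrane potential, mV (intracellular minus bath).
    decade_slope_mV : mV per tenfold concentration ratio.  Either set
        directly (default 58.0) or derive from temperature with
        :meth:`at_temperature`; exactly one convention is active per context.
    temperature_c : record of the temperature when the slope was derived
        from it; ``None`` for a fixed slope.
    """

    cl_out_mM: float
    rmp_mV: float
    decade_slope_mV: float = 58.0
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        if self.cl_out_mM <= 0:
            raise ConfigurationError(f"cl_out_mM must be > 0, got {self.cl_out_mM}")
        if self.decade_slope_mV <= 0:
            raise ConfigurationError(
                f"decade_slope_mV must be > 0, got {self.decade_slope_mV}"
            )

    @classmethod
    def at_temperature(
        cls, cl_out_mM: float, rmp_mV: float, temperature_c: float
    ) -> "EquilibriumContext":
        """Context with the slope derived from temperature (ln10*R*T/F)."""
        return cls(
            cl_out_mM=cl_out_mM,
            rmp_mV=rmp_mV,
            decade_slope_mV=decade_slope_mv(temperature_c),
            temperature_c=temperature_c,
        )


@dataclass(frozen=True)
class EquilibriumResult:
    """Bundle of equilibrium quantities for one cell."""

    cl_i_mM: float
    e_cl_mV: float
    critical_cl_mM: float
    driving_force_mV: float  # rmp - e_cl; negative drives efflux (depolarizing)
    efflux_predicted: bool


def nernst_ecl(cl_i_mM, ctx: EquilibriumContext):
    """Chloride reversal potential, mV.

    Negative when ``cl_i < cl_out`` (the physiological case); increases
    monotonically with intracellular chloride. Accepts scalars or arrays.
    """
    cl_i = np.asarray(cl_i_mM, dtype=float)
    if np.any(cl_i <= 0):
        raise ValueError("cl_i_mM must be > 0")
    out = ctx.decade_slope_mV * np.log10(cl_i / ctx.cl_out_mM)
    return float(out) if np.isscalar(cl_i_mM) else out


def critical_cli(ctx: EquilibriumContext) -> float:
    """Intracellular chloride (mM) at which E_Cl equals the RMP.

    Cells strictly above this concentration lose chloride (depolarize) when
    a chloride conductance opens.
    """
    return ctx.cl_out_mM * 10.0 ** (ctx.rmp_mV / ctx.decade_slope_mV)


def efflux_fraction(cl_i_values: Sequence[float], ctx: EquilibriumContext) -> float:
    """Empirical fraction of cells with [Cl-]i strictly above the critical level."""
    values = np.asarray(cl_i_values, dtype=float)
    if values.size == 0:
        raise ValueError("empty [Cl-]i sample")
    return float(np.mean(values > critical_cli(ctx)))


def efflux_fraction_gaussian(
    mean_mM: float, sd_mM: float, ctx: EquilibriumContext
) -> float:
    """Closed-form efflux-competent fraction for a Gaussian [Cl-]i population.

    P(C > critical) = Phi((mean - critical) / sd).
    """
    if sd_mM <= 0:
        raise ValueError("sd_mM must be > 0")
    return float(norm.cdf((mean_mM - critical_cli(ctx)) / sd_mM))


def classify_equilibrium(cl_i_mM: float, ctx: EquilibriumContext) -> EquilibriumResult:
    """Reversal potential, critical concentration, driving force and efflux call."""
    e_cl = nernst_ecl(cl_i_mM, ctx)
    crit = critical_cli(ctx)
    # strict inequality: a cell exactly at equilibrium has zero driving force
    efflux = e_cl > ctx.rmp_mV
    assert efflux == (cl_i_mM > crit) or math.isclose(cl_i_mM, crit, rel_tol=1e-12)
    return EquilibriumResult(
        cl_i_mM=float(cl_i_mM),
        e_cl_mV=e_cl,
        critical_cl_mM=crit,
        driving_force_mV=ctx.rmp_mV - e_cl,
        efflux_predicted=bool(efflux),
    )
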