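"""Hill-equation dose-response fitting.

Activation (agonist) curves follow

    r(c) = bottom + (top - bottom) / (1 + (ec50 / c)^n)

and inhibition (antagonist) curves the mirrored form

    r(c) = bottom + (top - bottom) / (1 + (c / ic50)^n)

so an inhibition curve decreases with concentration from ``top`` (its
zero-dose asymptote) to ``bottom``. Both are single-site fits; n is the
Hill coefficient. Fitting is unweighted nonlinear least squares (optional
1/sem^2 weights), parameterized internally on log10(ec50) for conditioning,
with asymptotic standard errors from the Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError

__all__ = ["DoseResponseFit", "hill_activation", "hill_inhibition", "fit_hill", "predict"]


@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float  # half-maximal concentration (IC50 for inhibition), in input units
    hill_n: float
    top: float
    bottom: float
    direction: str  # activation | inhibition
    se_ec50: float
    se_hill: float
    converged: bool
    rss: float
    n_points: int = 0


def hill_activation(c, ec50, hill_n, top, bottom):
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill_n)


def hill_inhibition(c, ic50, hill_n, top, bottom):
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill_n)


def _init_ec50(conc: np.ndarray, resp: np.ndarray, direction: str) -> float:
    """Geometric mean of the two concentrations bracketing the half-range response."""
    order = np.argsort(conc)
    c, r = conc[order], resp[order]
    half = 0.5 * (r.max() + r.min())
    # walk the (sorted-by-dose) response for the first crossing of half-range
    crossing = np.nonzero(np.diff(np.sign(r - half)) != 0)[0]
    if crossing.size:
        i = crossing[0]
        return float(np.sqrt(c[i] * c[i + 1]))
    return float(np.sqrt(c[0] * c[-1]))


def fit_hill(
    concentrations: Sequence[float],
    responses: Sequence[float],
    direction: str = "activation",
    sem: Sequence[float] | None = None,
    init_overrides: Mapping[str, float] | None = None,
) -> DoseResponseFit:
    """Least-squares Hill fit.

    Parameters
    ----------
    concentrations, responses : matched arrays; concentrations must be > 0
        (a zero-dose baseline belongs in ``bottom``/``top``, not the data).
    direction : ``activation`` (rising) or ``inhibition`` (falling).
    sem : optional per-point SEMs enabling 1/sem^2 weighting.
    init_overrides : optional initial values for any of
        ``ec50``, ``hill_n``, ``top``, ``bottom``.

    Raises :class:`FitError` for flat (degenerate) data. Non-convergence is
    reported via ``converged=False``, not an exception.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("concentrations and responses must be matched 1-D arrays")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if direction not in ("activation", "inhibition"):
        raise ValueError(f"unknown direction {direction!r}")
    if np.ptp(resp) == 0:
        raise FitError("responses are constant; Hill parameters are unidentifiable")
    n_distinct = np.unique(conc).size
    if n_distinct < 4:
        warnings.warn(
            f"only {n_distinct} distinct concentrations; Hill fit may be "
            "poorly constrained",
            stacklevel=2,
        )

    model = hill_activation if direction == "activation" else hill_inhibition
    weights = np.ones_like(resp)
    if sem is not None:
        sem = np.asarray(sem, dtype=float)
        if np.any(sem > 0):
            weights = np.where(sem > 0, 1.0 / np.maximum(sem, 1e-300), 0.0)

    init = {
        "ec50": _init_ec50(conc, resp, direction),
        "hill_n": 1.0,
        "top": float(resp.max()),
        "bottom": float(resp.min()),
    }
    if init_overrides:
        init.update(init_overrides)

    lo_c, hi_c = np.log10(conc.min() / 100.0), np.log10(conc.max() * 100.0)
    span = float(resp.max() - resp.min())

    def residuals(p):
        log_ec50, hill_n, top, bottom = p
        return weights * (model(conc, 10.0**log_ec50, hill_n, top, bottom) - resp)

    x0 = np.array(
        [
            np.clip(np.log10(init["ec50"]), lo_c, hi_c),
            np.clip(init["hill_n"], 1e-3, 10.0),
            init["top"],
            init["bottom"],
        ]
    )
    bounds = (
        [lo_c, 1e-6, resp.min() - 10 * span, resp.min() - 10 * span],
        [hi_c, 10.0, resp.max() + 10 * span, resp.max() + 10 * span],
    )
    result = least_squares(
        residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    log_ec50, hill_n, top, bottom = result.x
    ec50 = float(10.0**log_ec50)
    rss = float(2.0 * result.cost)

    # asymptotic covariance from the Jacobian at the optimum
    se_log_ec50 = se_hill = np.nan
    dof = conc.size - 4
    if dof > 0:
        jtj = result.jac.T @ result.jac
        try:
            cov = np.linalg.inv(jtj) * rss / dof
            se_log_ec50 = float(np.sqrt(max(cov[0, 0], 0.0)))
            se_hill = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            pass
    se_ec50 = float(se_log_ec50 * np.log(10.0) * ec50)

    converged = bool(result.success)
    if not converged:
        warnings.warn("Hill fit did not converge; parameters are provisional", stacklevel=2)
    return DoseResponseFit(
        ec50=ec50,
        hill_n=float(hill_n),
        top=float(top),
        bottom=float(bottom),
        direction=direction,
        se_ec50=se_ec50,
        se_hill=float(se_hill),
        converged=converged,
        rss=rss,
        n_points=int(conc.size),
    )


def predict(fit: DoseResponseFit, concentrations) -> np.ndarray:
    """Evaluate a fitted Hill curve at the given concentrations."""
    model = hill_activation if fit.direction == "activation" else hill_inhibition
    return np.asarray(
        model(concentrations, fit.ec50, fit.hill_n, fit.top, fit.bottom), dtype=float
    )
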