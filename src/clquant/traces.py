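"""Fluorescence time-series analysis.

Baseline statistics, relative fluorescence change (dF, in percent of the
pre-stimulus baseline), k-sigma response classification for the
chloride-sensitive dye channel, and ratiometric (f340/f380) calcium trace
handling.

Sign convention, fixed here and nowhere else: the chloride dye (MQAE) is
collisionally quenched by chloride, so a fluorescence *increase* reports a
*decrease* of intracellular chloride, i.e. chloride **efflux**. Positive dF
therefore maps to ``direction == "efflux"``. Calcium ratio analyses carry no
direction labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = [
    "FluorescenceTrace",
    "BaselineStats",
    "ResponseCall",
    "baseline_stats",
    "delta_f",
    "classify_response",
    "ratio_trace",
    "response_amplitude",
    "viability_filter",
    "false_positive_bound",
]

#: relative floor applied to a zero-noise baseline SD (fraction of baseline mean)
SD_FLOOR_REL = 1e-6

MQAE_NOTE = "MQAE: fluorescence increase = [Cl-]i decrease (efflux)"


@dataclass
class FluorescenceTrace:
    """One cell's intensity time series on one channel.

    time_s must be strictly increasing and the same length as values.
    """

    time_s: np.ndarray
    values: np.ndarray
    cell_id: str = ""
    channel: str = "mqae"  # mqae | fura340 | fura380 | ratio

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.shape != self.values.shape or self.time_s.ndim != 1:
            raise DataError("time_s and values must be 1-D arrays of equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise DataError("time_s must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DataError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.time_s.size

    def window(self, start_s: float, end_s: float) -> "FluorescenceTrace":
        """Sub-trace with start_s <= t < end_s."""
        mask = (self.time_s >= start_s) & (self.time_s < end_s)
        return FluorescenceTrace(
            self.time_s[mask], self.values[mask], self.cell_id, self.channel
        )


@dataclass(frozen=True)
class BaselineStats:
    mean: float
    sd: float
    n_frames: int


@dataclass(frozen=True)
class ResponseCall:
    direction: str  # efflux | influx | none
    amplitude_pct: float  # signed dF extremum, % of baseline
    threshold_pct: float  # k * baseline SD, % of baseline
    window: tuple[float, float]
    cell_id: str = ""
    note: str = field(default=MQAE_NOTE)


def baseline_stats(trace: FluorescenceTrace, n_frames: int = 10) -> BaselineStats:
    """Mean and sample SD of the first ``n_frames`` (pre-stimulus) frames."""
    if n_frames < 2:
        raise DataError("n_frames must be >= 2")
    if len(trace) < n_frames:
        raise DataError(
            f"trace has {len(trace)} frames, baseline needs {n_frames}"
        )
    head = trace.values[:n_frames]
    return BaselineStats(float(np.mean(head)), float(np.std(head, ddof=1)), n_frames)


def delta_f(trace: FluorescenceTrace, baseline: BaselineStats) -> np.ndarray:
    """dF_t = 100 * (F_t - baseline mean) / baseline mean, percent."""
    if baseline.mean <= 0:
        raise DataError("baseline mean must be > 0 for relative dF")
    return 100.0 * (trace.values - baseline.mean) / baseline.mean


def _floored_sd(baseline: BaselineStats) -> float:
    return max(baseline.sd, SD_FLOOR_REL * abs(baseline.mean))


def classify_response(
    trace: FluorescenceTrace,
    baseline: BaselineStats,
    stim_window: tuple[float, float],
    k: float = 4.0,
    tail_s: float = 10.0,
) -> ResponseCall:
    """k-sigma response call on the chloride channel.

    The amplitude is the signed dF extremum (largest absolute excursion)
    within the stimulus window extended by ``tail_s`` seconds. A call of
    ``efflux`` requires amplitude > +k*SD, ``influx`` amplitude < -k*SD
    (SD in percent-of-baseline units); otherwise ``none``.
    """
    start, end = stim_window
    dff = delta_f(trace, baseline)
    mask = (trace.time_s >= start) & (trace.time_s <= end + tail_s)
    if not np.any(mask):
        raise DataError(f"stimulus window [{start}, {end}] not covered by trace")
    seg = dff[mask]
    amplitude = float(seg[np.argmax(np.abs(seg))])
    threshold = 100.0 * k * _floored_sd(baseline) / baseline.mean
    if amplitude > threshold:
        direction = "efflux"
    elif amplitude < -threshold:
        direction = "influx"
    else:
        direction = "none"
    return ResponseCall(
        direction=direction,
        amplitude_pct=amplitude,
        threshold_pct=threshold,
        window=(start, end),
        cell_id=trace.cell_id,
    )


def ratio_trace(
    f340: FluorescenceTrace, f380: FluorescenceTrace
) -> FluorescenceTrace:
    """Elementwise f340/f380 ratio on a shared time base.

    Traces must have the same frame count and timestamps aligned to better
    than half the median frame interval; the denominator must be strictly
    positive everywhere.
    """
    if len(f340) != len(f380):
        raise DataError("f340 and f380 differ in frame count")
    if len(f340) >= 2:
        half_dt = 0.5 * float(np.median(np.diff(f340.time_s)))
        if np.max(np.abs(f340.time_s - f380.time_s)) > half_dt:
            raise DataError("f340/f380 time bases misaligned beyond half a frame")
    if np.any(f380.values <= 0):
        raise DataError("f380 must be strictly positive to form a ratio")
    return FluorescenceTrace(
        f340.time_s, f340.values / f380.values, f340.cell_id, channel="ratio"
    )


def response_amplitude(
    ratio: FluorescenceTrace,
    baseline: BaselineStats,
    stim_window: tuple[float, float],
) -> float:
    """Peak-minus-baseline amplitude of a ratio trace within the window."""
    start, end = stim_window
    mask = (ratio.time_s >= start) & (ratio.time_s <= end)
    if not np.any(mask):
        raise DataError(f"window [{start}, {end}] not covered by trace")
    return float(np.max(ratio.values[mask]) - baseline.mean)


def viability_filter(
    ratio: FluorescenceTrace,
    baseline: BaselineStats,
    kcl_window: tuple[float, float],
    min_amplitude: float,
) -> bool:
    """Keep a cell iff its depolarization (KCl) response reaches min_amplitude.

    High-K+ depolarization opens voltage-gated calcium channels in any live
    neuron, so an absent response marks a dead or non-neuronal ROI.
    """
    return response_amplitude(ratio, baseline, kcl_window) >= min_amplitude


def false_positive_bound(
    k: float = 4.0, n_baseline: int = 10, n_window: int = 1
) -> float:
    """Analytic upper bound on the no-response false-positive rate.

    With Gaussian frame noise, the per-frame statistic
    (F_t - baseline mean) / baseline SD follows a Student-t law with
    ``n_baseline - 1`` degrees of freedom scaled by sqrt(1 + 1/n_baseline),
    because both baseline moments are estimated from ``n_baseline`` frames.
    The probability that the signed extremum over ``n_window`` frames exceeds
    k sigma in either direction is then Bonferroni-bounded by

        n_window * 2 * S_t(k / sqrt(1 + 1/n_baseline); df = n_baseline - 1)

    where S_t is the t survival function. As n_baseline grows this reduces
    to the familiar Gaussian bound n_window * 2 * Phi(-k).
    """
    if n_baseline < 2:
        raise ValueError("n_baseline must be >= 2")
    scale = np.sqrt(1.0 + 1.0 / n_baseline)
    per_frame = 2.0 * stats.t.sf(k / scale, df=n_baseline - 1)
    return float(min(1.0, n_window * per_frame))
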