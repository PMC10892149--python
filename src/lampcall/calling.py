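"""Positive/negative calling of wells from hue time series.

The analysis mirrors real-time PCR thresholding, applied to color instead
of fluorescence.  For each well the raw 8-bit hues are unwrapped onto a
continuous scale, smoothed with a trailing three-point moving average, and
compared against a threshold built from the early-run baseline: the mean of
the raw hues in the baseline window (default minutes 0-2) plus or minus
``k_sd`` baseline standard deviations, in the dye's direction of change
(hue rises for phenol red, falls for hydroxynaphthol blue).  The first
frame after the baseline window whose smoothed deviation exceeds the
threshold sets the crossing time; a call latches, so a later reversion does
not rescind it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .color import DyeProfile, unwrap_series
from .plate import WellID

__all__ = [
    "BaselineStats",
    "CallResult",
    "HueSeries",
    "baseline_stats",
    "call_plate",
    "call_well",
    "smooth_ma3",
]

#: Default baseline window in minutes (closed interval).
DEFAULT_BASELINE_WINDOW = (0.0, 2.0)
#: Floor on the threshold in hue units, guarding a perfectly flat baseline
#: (sd = 0) against calling 1-unit flicker positive.
DEFAULT_MIN_DELTA = 2.0


def smooth_ma3(raw_unwrapped: Sequence[float]) -> np.ndarray:
    """Trailing 3-point moving average; the first two points use the
    partial window available so the output has the input's length."""
    x = np.asarray(raw_unwrapped, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("smooth_ma3 requires a non-empty 1-D series")
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    starts = np.maximum(np.arange(n) - 2, 0)
    return (c[np.arange(n) + 1] - c[starts]) / (np.arange(n) + 1 - starts)


@dataclass
class HueSeries:
    """Per-well hue trajectory: raw 8-bit values, their unwrapped form,
    and the smoothed curve used for calling."""

    well: WellID
    times: np.ndarray
    raw: np.ndarray
    unwrapped: np.ndarray = field(init=False)
    smoothed: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.times.shape != self.raw.shape:
            raise ValueError("times and raw must have equal length")
        if self.times.size == 0:
            raise ValueError("empty series")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.unwrapped = unwrap_series(self.raw)
        self.smoothed = smooth_ma3(self.unwrapped)


@dataclass(frozen=True)
class BaselineStats:
    """Mean and sample SD of the unwrapped raw hues in the baseline window."""

    mean: float
    sd: float
    window_minutes: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class CallResult:
    """Outcome for one well.

    ``threshold_delta`` is the effective threshold actually applied,
    ``max(k_sd * sd, min_delta)``, in hue units relative to the baseline
    mean along the dye's direction.
    """

    well: WellID
    status: str  # "positive" | "negative"
    threshold_delta: float
    baseline: BaselineStats
    dye: str
    crossing_index: int | None = None
    crossing_time_min: float | None = None


def baseline_stats(
    series: HueSeries,
    window_minutes: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> BaselineStats:
    """Baseline mean and sample SD over the closed time window.

    Statistics are computed on the unwrapped values, so a series that
    happens to sit on the red wrap (254, 2, ...) does not produce a
    spurious ~252-unit jump.  With one point the SD is 0.
    """
    lo, hi = window_minutes
    mask = (series.times >= lo) & (series.times <= hi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no samples inside the baseline window [{lo}, {hi}] min")
    vals = series.unwrapped[mask]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return BaselineStats(mean=float(vals.mean()), sd=sd, window_minutes=(lo, hi), n_points=n)


def call_well(
    series: HueSeries,
    dye: DyeProfile,
    stats: BaselineStats | None = None,
    min_delta: float = DEFAULT_MIN_DELTA,
    window_minutes: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    k_sd: float | None = None,
) -> CallResult:
    """Call one well positive or negative.

    Positive at the first index strictly after the baseline window where

        direction * (smoothed[t] - baseline_mean) > max(k_sd * sd, min_delta)

    (strict inequality: a value exactly at the threshold is negative).
    The call latches at the first crossing.
    """
    if stats is None:
        stats = baseline_stats(series, window_minutes)
    k = dye.k_sd if k_sd is None else k_sd
    threshold = max(k * stats.sd, min_delta)
    after = series.times > stats.window_minutes[1]
    if not after.any():
        raise ValueError(
            f"well {series.well}: series does not extend beyond the baseline window"
        )
    deviation = dye.direction * (series.smoothed - stats.mean)
    exceeds = after & (deviation > threshold)
    if exceeds.any():
        i = int(np.argmax(exceeds))
        return CallResult(
            well=series.well,
            status="positive",
            threshold_delta=threshold,
            baseline=stats,
            dye=dye.name,
            crossing_index=i + 1,  # frame ordinals start at 1
            crossing_time_min=float(series.times[i]),
        )
    return CallResult(
        well=series.well,
        status="negative",
        threshold_delta=threshold,
        baseline=stats,
        dye=dye.name,
    )


def call_plate(
    all_series: Sequence[HueSeries],
    dye: DyeProfile,
    min_delta: float = DEFAULT_MIN_DELTA,
    window_minutes: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    k_sd: float | None = None,
    return_history: bool = False,
):
    """Call every well; optionally also return the per-frame call map.

    The call map is the history a live display would show: for each frame
    index, the (latched, hence non-decreasing) set of wells positive by
    that frame.

    Returns
    -------
    dict[WellID, CallResult], or (dict, list[frozenset[WellID]]) when
    ``return_history`` is true.
    """
    calls: dict[WellID, CallResult] = {}
    for series in all_series:
        calls[series.well] = call_well(
            series, dye, min_delta=min_delta, window_minutes=window_minutes, k_sd=k_sd
        )
    if not return_history:
        return calls
    n_frames = max(len(s.times) for s in all_series) if all_series else 0
    history = []
    for i in range(1, n_frames + 1):
        history.append(
            frozenset(
                w for w, c in calls.items()
                if c.crossing_index is not None and c.crossing_index <= i
            )
        )
    return calls, history
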