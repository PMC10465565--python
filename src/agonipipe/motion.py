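"""Group-level action segmentation from motion-magnitude time series.

A fixed overhead camera watching a pen of group-housed animals produces,
after dense optical flow at 1 fps, a univariate series of mean displacement
magnitudes (pixels per 1-s step).  Quiescent periods sit near zero; bouts of
chasing/fleeing produce sustained high-magnitude runs.  This module turns
that series into "action intervals" (the clips worth analysing further) and
hourly activity summaries.

The segmentation filter chain, in order:

1. suppress magnitudes below 1 (sub-pixel motion is treated as noise);
2. rolling median, 7-s window (removes isolated spikes);
3. rolling mean, 15-s window (smooths the magnitude envelope);
4. a 1-D dilation-like pass restoring onset/offset samples eaten by the
   median filter, extending runs outward while the raw suppressed signal is
   nonzero, at most 7 s per side;
5. merging of high-magnitude runs separated by gaps shorter than 60 s,
   filling the gap with the median of the two neighbouring runs;
6. retention of runs whose mean filtered magnitude exceeds 1.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from ._farneback import farneback_flow

SUPPRESS_BELOW = 1.0
MEDIAN_WINDOW_S = 7
MEAN_WINDOW_S = 15
MERGE_GAP_S = 60
RETAIN_MEAN_MAGNITUDE = 1.2
DILATION_CAP_S = MEDIAN_WINDOW_S // 2
SAVGOL_WINDOW_H = 11
SAVGOL_ORDER = 3


@dataclass(frozen=True)
class MagnitudeSeries:
    """Per-second mean optical-flow displacement magnitude for one pen."""

    pen_id: str
    values: np.ndarray
    t0: float = 0.0  # absolute timestamp (s) of the first sample

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("magnitude series must be 1-D")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("magnitudes must be finite and non-negative")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t_offset_s": np.arange(len(self.values)), "magnitude": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pen_id: str = "pen", t0: float = 0.0) -> "MagnitudeSeries":
        df = pd.read_csv(path)
        return cls(pen_id=pen_id, values=df["magnitude"].to_numpy(), t0=t0)


@dataclass(frozen=True)
class ActionInterval:
    """Half-open [start_s, end_s) action interval with its mean magnitude."""

    start_s: int
    end_s: int
    mean_magnitude: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class HourlyActivity:
    hour_index: int
    active_seconds_raw: int
    active_seconds_smoothed: float


def flow_magnitude_series(
    video_frames: Iterable[np.ndarray],
    pen_id: str = "pen",
    t0: float = 0.0,
    **flow_params,
) -> MagnitudeSeries:
    """Mean dense-flow displacement magnitude for each consecutive frame pair.

    ``video_frames`` is a sequence of grayscale frames already downsampled to
    1 fps (at the native 25 fps this means keeping every 25th frame).  Flow
    is computed with the Farnebäck method using pyramid scale 0.5, 3 levels,
    window size 15, 3 iterations, polynomial neighbourhood 5 and polynomial
    sigma 1.2; override via ``flow_params``.
    """
    params = dict(pyr_scale=0.5, levels=3, winsize=15,
                  iterations=3, poly_n=5, poly_sigma=1.2)
    params.update(flow_params)
    it: Iterator[np.ndarray] = iter(video_frames)
    try:
        prev = np.asarray(next(it), dtype=float)
    except StopIteration:
        raise ValueError("need at least 2 frames") from None
    mags = []
    for frame in it:
        frame = np.asarray(frame, dtype=float)
        if frame.shape != prev.shape:
            raise ValueError(
                f"frame size mismatch: {frame.shape} vs {prev.shape}")
        flow = farneback_flow(prev, frame, **params)
        mags.append(float(np.hypot(flow[..., 0], flow[..., 1]).mean()))
        prev = frame
    if not mags:
        raise ValueError("need at least 2 frames")
    return MagnitudeSeries(pen_id=pen_id, values=np.array(mags), t0=t0)


def _rolling(values: np.ndarray, window: int, stat) -> np.ndarray:
    """Centered rolling statistic; the window shrinks at the boundaries."""
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).agg(stat).to_numpy()


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as half-open (start, end) pairs."""
    idx = np.flatnonzero(np.diff(np.r_[False, mask, False].astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def segment_actions(series: MagnitudeSeries) -> list[ActionInterval]:
    """Extract action intervals from a 1-Hz magnitude series.

    Returns sorted, disjoint intervals whose mean filtered magnitude exceeds
    1.2.  Series shorter than the largest filter window yield an empty list
    with a warning.
    """
    v = series.values
    if len(v) < MEAN_WINDOW_S:
        warnings.warn(
            f"series of {len(v)} s is shorter than the {MEAN_WINDOW_S}-s "
            "filter window; no segmentation performed")
        return []

    suppressed = np.where(v < SUPPRESS_BELOW, 0.0, v)
    med = _rolling(suppressed, MEDIAN_WINDOW_S, "median")
    smooth = _rolling(med, MEAN_WINDOW_S, "mean")

    # Run support comes from the median-filtered signal (which preserves
    # block boundaries); the mean-filtered signal supplies magnitudes.
    support = med > 0

    # Dilation-like edge restoration: extend each run outward while the raw
    # suppressed signal is nonzero, at most DILATION_CAP_S samples per side.
    restored = support.copy()
    for start, end in _runs(support):
        i = start - 1
        while i >= 0 and start - i <= DILATION_CAP_S and suppressed[i] > 0:
            restored[i] = True
            i -= 1
        i = end
        while i < len(v) and i - end < DILATION_CAP_S and suppressed[i] > 0:
            restored[i] = True
            i += 1

    # Magnitude signal used for the retention test: mean-filtered where the
    # run support holds, raw suppressed on restored edge samples.
    mag = np.where(support, smooth, suppressed)

    # Merge runs separated by gaps < MERGE_GAP_S, filling the gap with the
    # median of the two neighbouring runs.
    runs = _runs(restored)
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < MERGE_GAP_S:
            p_start, p_end = merged[-1]
            fill = np.median(np.r_[mag[p_start:p_end], mag[start:end]])
            mag[p_end:start] = fill
            merged[-1] = (p_start, end)
        else:
            merged.append((start, end))

    intervals = []
    for start, end in merged:
        mean_mag = float(mag[start:end].mean())
        if mean_mag > RETAIN_MEAN_MAGNITUDE:
            intervals.append(ActionInterval(int(start), int(end), mean_mag))
    return intervals


def hourly_activity(
    intervals: Sequence[ActionInterval], horizon_hours: int
) -> list[HourlyActivity]:
    """Seconds of action per clock hour, raw and Savitzky–Golay smoothed.

    Smoothing uses window 11, polynomial order 3; negative values produced by
    the smoother are ceiled to zero.  Horizons shorter than the smoothing
    window skip smoothing with a warning.
    """
    raw = np.zeros(horizon_hours, dtype=int)
    for iv in intervals:
        for h in range(iv.start_s // 3600, min((iv.end_s - 1) // 3600 + 1,
                                               horizon_hours)):
            lo, hi = max(iv.start_s, h * 3600), min(iv.end_s, (h + 1) * 3600)
            raw[h] += max(hi - lo, 0)
    if horizon_hours < SAVGOL_WINDOW_H:
        warnings.warn("horizon shorter than smoothing window; returning raw")
        smoothed = raw.astype(float)
    else:
        smoothed = np.maximum(
            savgol_filter(raw.astype(float), SAVGOL_WINDOW_H, SAVGOL_ORDER),
            0.0)
    return [
        HourlyActivity(h, int(raw[h]), float(smoothed[h]))
        for h in range(horizon_hours)
    ]


def intervals_to_csv(intervals: Sequence[ActionInterval], path) -> None:
    pd.DataFrame(
        [(iv.start_s, iv.end_s, iv.mean_magnitude) for iv in intervals],
        columns=["start_s", "end_s", "mean_magnitude"],
    ).to_csv(path, index=False)


def intervals_from_csv(path) -> list[ActionInterval]:
    df = pd.read_csv(path)
    return [
        ActionInterval(int(r.start_s), int(r.end_s), float(r.mean_magnitude))
        for r in df.itertuples()
    ]
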