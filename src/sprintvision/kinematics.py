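"""Instantaneous speed from the fused position series and 10-m subtask means.

Speed is the secant slope of the position series over a fixed frame window
(4 frames at 30 Hz by default): ``(loc[i+w] - loc[i]) / (t[i+w] - t[i])``.
Each sample is anchored at the *midpoint* of its window — time
``(t[i] + t[i+w]) / 2`` and location ``(loc[i] + loc[i+w]) / 2`` — so the
secant, which measures the average speed across the window, is attributed to
the place and moment it was actually measured.  Anchoring at the leading
frame instead would date every sample half a window early and bias the bin
means wherever the runner is accelerating or decelerating.

Subtask speeds V1..V10 are the arithmetic means of the speed samples whose
anchored location falls in each consecutive 10-m bin; bins are half-open
``[start, end)`` with the final bin closed so each sample belongs to exactly
one bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .frames_io import RunConfig
from .fusion import WorldTrack

__all__ = [
    "SubtaskSpeeds",
    "VelocitySeries",
    "average_speed",
    "instantaneous_velocity",
    "round_half_up",
    "segment_subtasks",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, as report tables are conventionally printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VelocitySeries:
    """Windowed speed samples; ``frame_index`` is the leading frame of each window."""

    frame_index: np.ndarray
    time_s: np.ndarray
    location_m: np.ndarray
    speed_m_per_s: np.ndarray
    window_frames: int

    def __post_init__(self) -> None:
        n = len(self.frame_index)
        if not (n == len(self.time_s) == len(self.location_m) == len(self.speed_m_per_s)):
            raise ValueError("velocity sample arrays must align")
        if not np.all(np.isfinite(self.speed_m_per_s)):
            raise ValueError("velocity series contains non-finite speeds")

    def __len__(self) -> int:
        return len(self.frame_index)


def instantaneous_velocity(track: WorldTrack, window_frames: int) -> VelocitySeries:
    """Secant speed over ``window_frames`` frames for a gap-free track."""
    if window_frames < 1:
        raise ValueError(f"velocity window must be >= 1, got {window_frames}")
    loc = track.location_m
    t = track.time_s
    if np.isnan(loc).any():
        raise ValueError("track contains gaps; fill_missing before differentiating")
    n = len(loc)
    if n < window_frames + 1:
        raise ValueError(
            f"track of {n} frames is too short for a {window_frames}-frame window"
        )
    w = window_frames
    dt = t[w:] - t[:-w]
    speed = (loc[w:] - loc[:-w]) / dt
    return VelocitySeries(
        frame_index=track.frame_index[:-w],
        time_s=0.5 * (t[:-w] + t[w:]),
        location_m=0.5 * (loc[:-w] + loc[w:]),
        speed_m_per_s=speed,
        window_frames=w,
    )


@dataclass(frozen=True)
class SubtaskSpeeds:
    """Mean speed per consecutive distance bin, plus whole-run summary."""

    start_m: np.ndarray
    end_m: np.ndarray
    mean_speed_m_per_s: np.ndarray  # NaN for a bin with no samples
    n_samples: np.ndarray
    total_time_s: float
    average_speed_m_per_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_m": self.start_m,
                "bin_end_m": self.end_m,
                "mean_speed": self.mean_speed_m_per_s,
                "n_samples": self.n_samples,
            }
        )

    def labels(self) -> list[str]:
        return [f"V{i + 1}" for i in range(len(self.start_m))]


def _crossing_time(t: np.ndarray, x: np.ndarray, target: float) -> float:
    """Time at which the (near-monotone) location series crosses ``target``.

    Interpolates between the bracketing samples; if the series starts past or
    ends short of the target, extrapolates with the nearest sample-to-sample
    slope (falling back to the end sample's time for a non-advancing series).
    """
    idx = np.flatnonzero(x >= target)
    if idx.size and idx[0] > 0:
        i = idx[0]
        return float(np.interp(target, x[i - 1 : i + 1], t[i - 1 : i + 1]))
    if idx.size:  # starts at/above target: extrapolate backwards
        slope = (x[1] - x[0]) / (t[1] - t[0]) if len(x) > 1 else 0.0
        return float(t[0] - (x[0] - target) / slope) if slope > 0 else float(t[0])
    slope = (x[-1] - x[-2]) / (t[-1] - t[-2]) if len(x) > 1 else 0.0
    return float(t[-1] + (target - x[-1]) / slope) if slope > 0 else float(t[-1])


def segment_subtasks(vel: VelocitySeries, config: RunConfig) -> SubtaskSpeeds:
    """Bin the speed samples into consecutive subtask distances and average.

    A bin with no samples is reported with a missing mean and ``n_samples``
    0.  The whole-run time is the interval between the (interpolated) 0-m and
    track-end crossings of the sample locations.
    """
    edges = np.arange(config.n_subtasks + 1) * config.subtask_length_m
    loc = vel.location_m
    speed = vel.speed_m_per_s
    means = np.full(config.n_subtasks, np.nan)
    counts = np.zeros(config.n_subtasks, dtype=int)
    for k in range(config.n_subtasks):
        sel = (loc >= edges[k]) & (loc < edges[k + 1])
        if k == config.n_subtasks - 1:  # final bin closed at the finish line
            sel = (loc >= edges[k]) & (loc <= edges[k + 1])
        counts[k] = int(sel.sum())
        if counts[k]:
            means[k] = speed[sel].mean()
    order = np.argsort(vel.time_s)
    t_start = _crossing_time(vel.time_s[order], loc[order], 0.0)
    t_end = _crossing_time(vel.time_s[order], loc[order], config.track_length_m)
    total = t_end - t_start
    return SubtaskSpeeds(
        start_m=edges[:-1],
        end_m=edges[1:],
        mean_speed_m_per_s=means,
        n_samples=counts,
        total_time_s=total,
        average_speed_m_per_s=config.track_length_m / total if total > 0 else np.nan,
    )


def average_speed(distance_m: float, time_s: float) -> float:
    """Mean speed over a distance; report tables print it at 3 decimals."""
    if time_s <= 0:
        raise ValueError(f"time must be positive, got {time_s}")
    return distance_m / time_s
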