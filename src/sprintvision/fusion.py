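"""Fusing the four per-camera segment tracks into one 0-100 m position series.

Each camera reports the runner's position only while it is inside that
camera's 25-m segment (plus a small slack).  Stitching selects, frame by
frame, the report of the segment whose range contains the runner; where two
adjacent cameras both report (the runner crossing a marker line), the camera
whose segment midpoint lies closer to the reported position wins.  Frames in
which no camera reports carry a missing value, later recovered by linear
interpolation, and the filled series is smoothed with a centred moving
average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import EDGE_SLACK_M, SegmentTrack
from .frames_io import RunConfig

__all__ = ["WorldTrack", "fill_missing", "smooth_track", "stitch_tracks"]

#: Provenance label for entries recovered by interpolation.
INTERPOLATED = "interpolated"
#: Provenance label for entries no camera reported (pre-fill only).
MISSING = "missing"


@dataclass(frozen=True)
class WorldTrack:
    """Fused body-position time series along the full track."""

    frame_index: np.ndarray
    location_m: np.ndarray
    frame_rate_hz: float
    source: np.ndarray  # per-entry camera id, "interpolated", or "missing"

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_index", np.asarray(self.frame_index, dtype=int))
        object.__setattr__(self, "location_m", np.asarray(self.location_m, dtype=float))
        object.__setattr__(self, "source", np.asarray(self.source, dtype=object))
        if not (len(self.frame_index) == len(self.location_m) == len(self.source)):
            raise ValueError("frame_index, location_m and source must align")

    @property
    def time_s(self) -> np.ndarray:
        return self.frame_index / self.frame_rate_hz

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.location_m).sum())


def _check_coverage(segments: list[SegmentTrack], config: RunConfig) -> None:
    ranges = sorted(seg.valid_range_m for seg in segments)
    lo0, hi_prev = ranges[0]
    if abs(lo0) > 1e-6:
        raise ValueError(f"segments do not start at 0 m (first range {ranges[0]})")
    for lo, hi in ranges[1:]:
        overlap = hi_prev - lo
        if overlap > EDGE_SLACK_M:
            raise ValueError(
                f"segment ranges overlap by {overlap:.2f} m (> {EDGE_SLACK_M} m slack)"
            )
        if overlap < -1e-6:
            raise ValueError(f"gap of {-overlap:.2f} m between segment ranges")
        hi_prev = hi
    if abs(hi_prev - config.track_length_m) > 1e-6:
        raise ValueError(
            f"segments end at {hi_prev} m, expected track length "
            f"{config.track_length_m} m"
        )


def stitch_tracks(segments: list[SegmentTrack], config: RunConfig) -> WorldTrack:
    """Combine per-segment tracks into one series (gaps left as NaN).

    Requires a common frame indexing (the shared-clock contract) and segment
    ranges that tile ``[0, track_length_m]``.  Present locations are clamped
    into ``[0, track_length_m]``; edge-slack excursions outside the track are
    an artefact of the centroid crossing the outermost marker lines.
    """
    if not segments:
        raise ValueError("no segment tracks to stitch")
    _check_coverage(segments, config)
    frame_index = segments[0].frame_index
    for seg in segments[1:]:
        if len(seg.frame_index) != len(frame_index) or np.any(
            seg.frame_index != frame_index
        ):
            raise ValueError(
                f"camera {seg.camera_id}: frame indexing differs from "
                f"{segments[0].camera_id} (unsynchronized tracks)"
            )

    n = len(frame_index)
    location = np.full(n, np.nan)
    source = np.full(n, MISSING, dtype=object)
    midpoints = {seg.camera_id: 0.5 * sum(seg.valid_range_m) for seg in segments}
    # lower-offset camera first so it wins exact distance ties
    ordered = sorted(segments, key=lambda s: s.valid_range_m[0])
    for i in range(n):
        best_dist = np.inf
        for seg in ordered:
            loc = seg.location_m[i]
            if np.isnan(loc):
                continue
            dist = abs(loc - midpoints[seg.camera_id])
            if dist < best_dist:
                best_dist = dist
                location[i] = loc
                source[i] = seg.camera_id
    np.clip(location, 0.0, config.track_length_m, out=location)
    return WorldTrack(frame_index, location, segments[0].frame_rate_hz, source)


def fill_missing(track: WorldTrack) -> WorldTrack:
    """Recover missing locations by linear interpolation against frame index.

    Interior gaps are interpolated between their neighbours; leading and
    trailing gaps take the nearest present value (no extrapolated motion
    before the start signal or after the finish).
    """
    present = np.isfinite(track.location_m)
    if present.sum() < 2:
        raise ValueError(
            f"cannot interpolate: only {int(present.sum())} present location(s) "
            "in the fused track"
        )
    if present.all():
        return track
    filled = track.location_m.copy()
    missing = ~present
    filled[missing] = np.interp(
        track.frame_index[missing],
        track.frame_index[present],
        track.location_m[present],
    )
    source = track.source.copy()
    source[missing] = INTERPOLATED
    return replace(track, location_m=filled, source=source)


def smooth_track(track: WorldTrack, window_frames: int) -> WorldTrack:
    """Centred moving average of the locations; window 1 is the identity.

    Near the ends the window shrinks symmetrically, so a linear series is
    reproduced exactly everywhere and no phase lag is introduced.
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window_frames}")
    if window_frames == 1:
        return track
    if np.isnan(track.location_m).any():
        raise ValueError("smooth_track requires a gap-free track; fill_missing first")
    loc = track.location_m
    n = len(loc)
    half = window_frames // 2
    out = np.empty(n)
    csum = np.concatenate(([0.0], np.cumsum(loc)))
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return replace(track, location_m=out)
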