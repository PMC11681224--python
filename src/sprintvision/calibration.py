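"""Two-point pixel-to-metre calibration of each camera view.

Each camera sees a 25-m segment of the track bounded by two physical markers
whose pixel columns are known.  The span in metres divided by the signed pixel
span gives a metres-per-pixel factor; the runner's world position is then an
affine function of its centroid column:

    location = (x_centroid - marker_end_px) * metres_per_pixel + segment_offset

A signed factor supports cameras in which the runner moves toward decreasing
pixel x.  Only the horizontal pixel coordinate enters the mapping; the track
is calibrated in the horizontal plane and the vertical centroid is kept for
diagnostics only.  No lens or perspective correction is applied — the model is
a pure two-point linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames_io import CameraGeometry

__all__ = [
    "CameraCalibration",
    "SegmentTrack",
    "calibrate_camera",
    "pixel_to_world",
    "to_segment_track",
    "world_to_pixel",
]

#: Metres of slack beyond a camera's nominal segment before a mapped location
#: is declared out of view: the body's centre legitimately crosses a marker
#: line mid-frame.
EDGE_SLACK_M = 1.0


@dataclass(frozen=True)
class CameraCalibration:
    camera_id: str
    marker_start_px: float
    marker_end_px: float
    segment_span_m: float
    segment_offset_m: float
    metres_per_pixel: float

    @property
    def valid_range_m(self) -> tuple[float, float]:
        return (self.segment_offset_m, self.segment_offset_m + self.segment_span_m)


@dataclass(frozen=True)
class SegmentTrack:
    """World positions (metres along the track) seen by one camera."""

    camera_id: str
    frame_index: np.ndarray
    location_m: np.ndarray
    valid_range_m: tuple[float, float]
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_index", np.asarray(self.frame_index, dtype=int))
        object.__setattr__(self, "location_m", np.asarray(self.location_m, dtype=float))
        if len(self.frame_index) != len(self.location_m):
            raise ValueError("frame_index and location_m must have equal length")


def calibrate_camera(
    marker_start_px: float,
    marker_end_px: float,
    segment_span_m: float = 25.0,
    segment_offset_m: float = 0.0,
    camera_id: str = "cam",
) -> CameraCalibration:
    """Derive the metres-per-pixel factor from the two marker columns.

    ``metres_per_pixel = segment_span_m / (marker_start_px - marker_end_px)``;
    the sign encodes the camera's orientation.
    """
    if segment_span_m <= 0:
        raise ValueError(f"segment span must be positive, got {segment_span_m}")
    cal_volume_px = marker_start_px - marker_end_px
    if cal_volume_px == 0:
        raise ValueError(
            f"camera {camera_id}: marker pixels coincide at {marker_start_px}"
        )
    return CameraCalibration(
        camera_id=camera_id,
        marker_start_px=float(marker_start_px),
        marker_end_px=float(marker_end_px),
        segment_span_m=float(segment_span_m),
        segment_offset_m=float(segment_offset_m),
        metres_per_pixel=float(segment_span_m) / cal_volume_px,
    )


def calibrate_from_geometry(geom: CameraGeometry) -> CameraCalibration:
    return calibrate_camera(
        geom.marker_start_px,
        geom.marker_end_px,
        geom.segment_span_m,
        geom.segment_offset_m,
        camera_id=geom.camera_id,
    )


def pixel_to_world(x_centroid_px, cal: CameraCalibration):
    """Map a centroid column (scalar or array) to metres along the track."""
    x = np.asarray(x_centroid_px, dtype=float)
    loc = (x - cal.marker_end_px) * cal.metres_per_pixel + cal.segment_offset_m
    return float(loc) if np.isscalar(x_centroid_px) else loc


def world_to_pixel(location_m, cal: CameraCalibration):
    """Inverse of :func:`pixel_to_world`; used by the synthetic renderer."""
    loc = np.asarray(location_m, dtype=float)
    x = (loc - cal.segment_offset_m) / cal.metres_per_pixel + cal.marker_end_px
    return float(x) if np.isscalar(location_m) else x


def to_segment_track(
    track, cal: CameraCalibration, slack_m: float = EDGE_SLACK_M
) -> SegmentTrack:
    """Convert a pixel centroid track to world metres within the camera's segment.

    Missing centroids stay missing; mapped locations outside the nominal
    25-m range by more than ``slack_m`` are set missing (runner not yet, or no
    longer, in this camera's view).
    """
    if track.camera_id != cal.camera_id:
        raise ValueError(
            f"camera id mismatch: track {track.camera_id!r} vs "
            f"calibration {cal.camera_id!r}"
        )
    loc = pixel_to_world(track.x_px, cal)
    lo, hi = cal.valid_range_m
    loc = np.where((loc >= lo - slack_m) & (loc <= hi + slack_m), loc, np.nan)
    return SegmentTrack(
        camera_id=track.camera_id,
        frame_index=track.frame_index,
        location_m=loc,
        valid_range_m=(lo, hi),
        frame_rate_hz=track.frame_rate_hz,
    )
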