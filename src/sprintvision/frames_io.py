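"""Reading and writing the on-disk artefacts of a multi-camera sprint recording.

A recording session produces, per camera, a directory of grayscale frames
(zero-padded integer filenames define temporal order) and one background image
captured before the run, plus a JSON run configuration.  All four cameras share
frame 0 = the start signal and a common frame rate; that shared-clock contract
is validated whenever sequences are loaded together.

Tracks (pixel centroids, per-segment world positions, the fused 0-100 m track)
and per-10-m subtask tables round-trip through headered CSV files in which a
missing value is an empty field.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "CameraGeometry",
    "ConfigError",
    "FrameSequence",
    "RunConfig",
    "load_run_config",
    "load_run_directory",
    "read_background",
    "read_frame_sequence",
    "read_track_csv",
    "write_run_config",
    "write_subtasks_csv",
    "write_track_csv",
]

#: Rec. 709 luma weights used to collapse colour frames to grayscale.
_LUMA = np.array([0.2125, 0.7154, 0.0721])

_FRAME_EXTS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}
_VIDEO_EXTS = {".avi", ".mp4", ".mov", ".mkv"}


class ConfigError(ValueError):
    """A run-configuration value violates its documented range."""


@dataclass(frozen=True)
class CameraGeometry:
    """Placement of one camera's two calibration markers along the track.

    ``marker_end_px`` is the pixel column of the marker at the *near* (lower
    world position) end of the camera's 25-m segment and ``marker_start_px``
    the far end, following the convention that a camera covering world metres
    ``[segment_offset_m, segment_offset_m + segment_span_m]`` measures the
    runner from its end marker.
    """

    camera_id: str
    marker_start_px: float
    marker_end_px: float
    segment_span_m: float = 25.0
    segment_offset_m: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the speed-tracking pipeline.

    Defaults are the system's operating point: grayscale difference threshold
    tau = 40, a 3x3 binary median filter, instantaneous speed over a 4-frame
    window at 30 Hz, and a 100-m track split into ten 10-m subtasks.
    """

    threshold_tau: float = 40.0
    median_kernel_px: int = 3
    velocity_window_frames: int = 4
    subtask_length_m: float = 10.0
    track_length_m: float = 100.0
    smoothing_window_frames: int = 5
    min_blob_area_px: int = 25
    frame_rate_hz: float = 30.0
    cameras: tuple[CameraGeometry, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_tau <= 255.0:
            raise ConfigError(
                f"threshold_tau must lie in [0, 255], got {self.threshold_tau}"
            )
        for name in ("median_kernel_px", "smoothing_window_frames"):
            value = getattr(self, name)
            if value < 1 or value % 2 == 0:
                raise ConfigError(f"{name} must be an odd integer >= 1, got {value}")
        if self.velocity_window_frames < 1:
            raise ConfigError(
                "velocity_window_frames must be >= 1, got "
                f"{self.velocity_window_frames}"
            )
        if self.subtask_length_m <= 0 or self.track_length_m <= 0:
            raise ConfigError("subtask_length_m and track_length_m must be positive")
        ratio = self.track_length_m / self.subtask_length_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"subtask_length_m ({self.subtask_length_m}) must divide "
                f"track_length_m ({self.track_length_m})"
            )
        if self.min_blob_area_px < 0:
            raise ConfigError("min_blob_area_px must be >= 0")
        if self.frame_rate_hz <= 0:
            raise ConfigError("frame_rate_hz must be positive")

    @property
    def n_subtasks(self) -> int:
        return int(round(self.track_length_m / self.subtask_length_m))


@dataclass(frozen=True)
class FrameSequence:
    """Ordered grayscale frames from one camera.

    ``frames`` is an ``(n_frames, height, width)`` uint8 array; stacking
    enforces that every frame shares the same dimensions.
    """

    camera_id: str
    frames: np.ndarray
    frame_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError(
                f"camera {self.camera_id}: frames must be a non-empty stack of "
                f"2-D grids, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError(
                    f"camera {self.camera_id}: intensities must lie in [0, 255]"
                )
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "frames", arr)
        if self.frame_rate_hz <= 0:
            raise ValueError(f"camera {self.camera_id}: frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height_px(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width_px(self) -> int:
        return int(self.frames.shape[2])

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def _as_gray(img: np.ndarray) -> np.ndarray:
    """Collapse an image to a 2-D uint8 grayscale grid (Rec. 709 luma)."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            arr = arr @ _LUMA
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def read_frame_sequence(
    path: str | Path,
    camera_id: str,
    frame_rate_hz: float | None = None,
) -> FrameSequence:
    """Read a camera's frames from an image directory or a video container.

    Directory input: files with image extensions, lexicographic filename order
    defines frame order (zero-padded integer names recommended).  Video input:
    any container imageio can open; the frame rate is taken from container
    metadata unless ``frame_rate_hz`` overrides it.  Directories have no rate
    metadata, so the override (or the 30 Hz default) applies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no frames for camera {camera_id}: {path} missing")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS
        )
        if not files:
            raise ValueError(f"no frames for camera {camera_id} in {path}")
        frames = [_as_gray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(
                f"camera {camera_id}: mixed frame dimensions {sorted(shapes)}"
            )
        rate = 30.0 if frame_rate_hz is None else frame_rate_hz
        return FrameSequence(camera_id, np.stack(frames), rate)
    if path.suffix.lower() in _VIDEO_EXTS:
        frames = [_as_gray(f) for f in iio.imiter(path)]
        if not frames:
            raise ValueError(f"no frames for camera {camera_id} in {path}")
        rate = frame_rate_hz
        if rate is None:
            rate = float(iio.immeta(path).get("fps", 30.0))
        return FrameSequence(camera_id, np.stack(frames), rate)
    raise ValueError(
        f"camera {camera_id}: {path} is neither a frame directory nor a "
        "supported video container"
    )


def read_background(path: str | Path, camera_id: str = "?") -> np.ndarray:
    """Read the pre-run background image for one camera as grayscale."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing background image for camera {camera_id}: {path}")
    return _as_gray(iio.imread(path))


def load_run_directory(
    path: str | Path, config: RunConfig
) -> tuple[list[FrameSequence], list[np.ndarray]]:
    """Load all ``cam*/`` frame directories and their background images.

    Enforces the synchronization contract: every camera contributes the same
    number of frames at the same rate, with frame 0 = the start signal.
    """
    path = Path(path)
    cam_dirs = sorted(p for p in path.iterdir() if p.is_dir() and p.name.startswith("cam"))
    if not cam_dirs:
        raise ValueError(f"no cam*/ frame directories found in {path}")
    sequences, backgrounds = [], []
    for cam_dir in cam_dirs:
        cam_id = cam_dir.name
        seq = read_frame_sequence(cam_dir, cam_id, config.frame_rate_hz)
        bg = read_background(path / f"{cam_id}_background.png", cam_id)
        if bg.shape != seq.frames.shape[1:]:
            raise ValueError(
                f"camera {cam_id}: background shape {bg.shape} does not match "
                f"frame shape {seq.frames.shape[1:]}"
            )
        sequences.append(seq)
        backgrounds.append(bg)
    counts = {s.n_frames for s in sequences}
    if len(counts) > 1:
        raise ValueError(
            "unsynchronized cameras: frame counts differ "
            f"({ {s.camera_id: s.n_frames for s in sequences} })"
        )
    return sequences, backgrounds


def load_run_config(path: str | Path) -> RunConfig:
    """Load a JSON run configuration; unspecified fields take the defaults."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys in {path}: {sorted(unknown)}")
    if "cameras" in raw:
        raw["cameras"] = tuple(CameraGeometry(**cam) for cam in raw["cameras"])
    return RunConfig(**raw)


def write_run_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    data["cameras"] = [asdict(cam) for cam in config.cameras]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Track / table CSV round trips


def _track_frame(track) -> pd.DataFrame:
    """Build the canonical DataFrame for any track-like object."""
    if hasattr(track, "x_px"):  # CentroidTrack
        return pd.DataFrame(
            {
                "frame": track.frame_index,
                "time_s": track.frame_index / track.frame_rate_hz,
                "x_px": track.x_px,
                "y_px": track.y_px,
            }
        )
    if hasattr(track, "source"):  # WorldTrack
        return pd.DataFrame(
            {
                "frame": track.frame_index,
                "time_s": track.time_s,
                "location_m": track.location_m,
                "source": track.source,
            }
        )
    # SegmentTrack
    return pd.DataFrame(
        {
            "frame": track.frame_index,
            "time_s": track.frame_index / track.frame_rate_hz,
            "location_m": track.location_m,
        }
    )


def write_track_csv(track, path: str | Path) -> None:
    """Write a track as headered CSV, one row per frame, missing = empty field."""
    df = _track_frame(track)
    if len(df) == 0:
        raise ValueError("refusing to write an empty track")
    df.to_csv(path, index=False, na_rep="", float_format="%.6f")


def read_track_csv(path: str | Path) -> pd.DataFrame:
    """Read a track CSV back; empty fields become NaN."""
    return pd.read_csv(path)


def write_subtasks_csv(subtasks, path: str | Path) -> None:
    """Write the ten-bin subtask-speed table as CSV."""
    subtasks.to_frame().to_csv(path, index=False, na_rep="", float_format="%.6f")
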