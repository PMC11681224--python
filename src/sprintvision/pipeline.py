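"""End-to-end driver: frames -> centroids -> metres -> fused track -> speeds.

Chains the detection, calibration, fusion and kinematics stages and collects
a run report (per-camera detection rates, warnings with the frame ranges they
refer to, whole-run time and average speed).  Stage failures are re-raised as
:class:`PipelineError` naming the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calibration as cal_mod
from . import detection, fusion, kinematics
from .calibration import CameraCalibration, SegmentTrack
from .detection import CentroidTrack
from .frames_io import FrameSequence, RunConfig, load_run_config, load_run_directory
from .fusion import WorldTrack
from .kinematics import SubtaskSpeeds, VelocitySeries

__all__ = ["PipelineError", "PipelineResult", "RunReport", "run_directory", "run_pipeline"]

#: An interior stretch of at least this many consecutive frames with no
#: camera report is flagged in the run report.
LONG_GAP_FRAMES = 10


class PipelineError(ValueError):
    """A stage of the tracking pipeline failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class ReportWarning:
    message: str
    frame_start: int
    frame_end: int

    def to_dict(self) -> dict:
        return {
            "message": self.message,
            "frame_start": self.frame_start,
            "frame_end": self.frame_end,
        }


@dataclass(frozen=True)
class RunReport:
    detection_rate: dict[str, float]
    n_frames: int
    n_interpolated: int
    total_time_s: float
    average_speed_m_per_s: float
    subtask_means: list[float]
    warnings: list[ReportWarning] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "detection_rate": self.detection_rate,
            "n_frames": self.n_frames,
            "n_interpolated": self.n_interpolated,
            "total_time_s": self.total_time_s,
            "average_speed_m_per_s": self.average_speed_m_per_s,
            "subtask_means": self.subtask_means,
            "warnings": [w.to_dict() for w in self.warnings],
        }


@dataclass(frozen=True)
class PipelineResult:
    centroid_tracks: list[CentroidTrack]
    segment_tracks: list[SegmentTrack]
    world: WorldTrack
    velocity: VelocitySeries
    subtasks: SubtaskSpeeds
    report: RunReport


def _gap_warnings(raw: WorldTrack) -> list[ReportWarning]:
    warnings = []
    missing = np.isnan(raw.location_m)
    present = np.flatnonzero(~missing)
    if present.size == 0:
        return warnings
    i = present[0]
    while i <= present[-1]:
        if missing[i]:
            j = i
            while missing[j]:
                j += 1
            if j - i >= LONG_GAP_FRAMES:
                warnings.append(
                    ReportWarning(
                        f"no camera reported the runner for {j - i} frames",
                        int(raw.frame_index[i]),
                        int(raw.frame_index[j - 1]),
                    )
                )
            i = j
        else:
            i += 1
    return warnings


def run_pipeline(
    sequences: list[FrameSequence],
    backgrounds: list[np.ndarray],
    calibrations: list[CameraCalibration],
    config: RunConfig,
) -> PipelineResult:
    """Run the full tracking chain on in-memory sequences."""
    if not (len(sequences) == len(backgrounds) == len(calibrations)):
        raise PipelineError("input", "sequences, backgrounds and calibrations must align")

    try:
        centroid_tracks = [
            detection.detect_track(seq, bg, config)
            for seq, bg in zip(sequences, backgrounds)
        ]
    except ValueError as exc:
        raise PipelineError("detection", str(exc)) from exc

    try:
        segment_tracks = [
            cal_mod.to_segment_track(track, cal)
            for track, cal in zip(centroid_tracks, calibrations)
        ]
    except ValueError as exc:
        raise PipelineError("calibration", str(exc)) from exc

    try:
        raw = fusion.stitch_tracks(segment_tracks, config)
        warnings = _gap_warnings(raw)
        filled = fusion.fill_missing(raw)
        world = fusion.smooth_track(filled, config.smoothing_window_frames)
    except ValueError as exc:
        raise PipelineError("fusion", str(exc)) from exc

    try:
        velocity = kinematics.instantaneous_velocity(world, config.velocity_window_frames)
        subtasks = kinematics.segment_subtasks(velocity, config)
    except ValueError as exc:
        raise PipelineError("kinematics", str(exc)) from exc

    report = RunReport(
        detection_rate={t.camera_id: t.detection_rate for t in centroid_tracks},
        n_frames=sequences[0].n_frames,
        n_interpolated=int(np.sum(world.source == fusion.INTERPOLATED)),
        total_time_s=subtasks.total_time_s,
        average_speed_m_per_s=subtasks.average_speed_m_per_s,
        subtask_means=[float(v) for v in subtasks.mean_speed_m_per_s],
        warnings=warnings,
    )
    return PipelineResult(centroid_tracks, segment_tracks, world, velocity, subtasks, report)


def run_directory(data_dir: str | Path, config: RunConfig | None = None) -> PipelineResult:
    """Load a fixture/recording directory and run the pipeline on it."""
    data_dir = Path(data_dir)
    if config is None:
        config_path = data_dir / "config.json"
        if not config_path.exists():
            raise PipelineError("input", f"no config given and {config_path} missing")
        config = load_run_config(config_path)
    if not config.cameras:
        raise PipelineError("input", "run config carries no camera calibration block")
    sequences, backgrounds = load_run_directory(data_dir, config)
    geoms = {g.camera_id: g for g in config.cameras}
    missing = [s.camera_id for s in sequences if s.camera_id not in geoms]
    if missing:
        raise PipelineError("input", f"no calibration block for cameras {missing}")
    calibrations = [cal_mod.calibrate_from_geometry(geoms[s.camera_id]) for s in sequences]
    return run_pipeline(sequences, backgrounds, calibrations, config)
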