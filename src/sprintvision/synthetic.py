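"""Ground-truthed synthetic sprints rendered as four-camera frame sequences.

The generator produces (a) a kinematic ground truth — a three-phase sprint
velocity profile integrated at the camera frame rate — and (b) pixel frames:
a dark rectangular silhouette translating across four 640x360 views, one per
25-m track segment, on a brighter uniform background with additive clipped
Gaussian noise and optional small distractor blobs.  Marker pixel columns are
emitted alongside so the calibration stage can be exercised with known truth.

The velocity profile is a saturating-exponential acceleration
``v(t) = v_max * (1 - exp(-t / accel_tau_s))`` up to ``decel_onset_m``,
followed by an exponential speed decay at ``decel_rate`` per second — the
acceleration / maximum-velocity / deceleration structure of a maximal 100-m
effort.  Defaults (v_max 8 m/s, tau 1.5 s, onset 70 m, decay 3 %/s) finish in
about 16 s at an average near 6.1 m/s, matching a trained collegiate
sprinter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import CameraCalibration, calibrate_camera, world_to_pixel
from .frames_io import CameraGeometry, FrameSequence, RunConfig, write_run_config

__all__ = [
    "RenderSpec",
    "RenderedRun",
    "SprintProfile",
    "Trajectory",
    "make_fixture",
    "render_cameras",
    "simulate_profile",
    "subtask_ground_truth",
]

#: Simulations that have not covered the track by this time raise.
_MAX_SIM_S = 60.0


@dataclass(frozen=True)
class SprintProfile:
    """Parameters of the three-phase sprint velocity profile."""

    v_max: float = 8.0
    accel_tau_s: float = 1.5
    decel_onset_m: float = 70.0
    decel_rate: float = 0.03
    frame_rate_hz: float = 30.0
    track_length_m: float = 100.0

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError(f"v_max must be positive, got {self.v_max}")
        if self.accel_tau_s < 0:
            raise ValueError(f"accel_tau_s must be >= 0, got {self.accel_tau_s}")
        if not 0 < self.decel_onset_m <= self.track_length_m:
            raise ValueError(
                f"decel_onset_m must lie in (0, {self.track_length_m}], "
                f"got {self.decel_onset_m}"
            )
        if self.decel_rate < 0:
            raise ValueError(f"decel_rate must be >= 0, got {self.decel_rate}")
        if self.frame_rate_hz <= 0 or self.track_length_m <= 0:
            raise ValueError("frame_rate_hz and track_length_m must be positive")

    @staticmethod
    def constant(speed_m_per_s: float, **kwargs) -> "SprintProfile":
        """A degenerate profile running the whole track at constant speed."""
        length = kwargs.pop("track_length_m", 100.0)
        return SprintProfile(
            v_max=speed_m_per_s,
            accel_tau_s=0.0,
            decel_onset_m=length,
            decel_rate=0.0,
            track_length_m=length,
            **kwargs,
        )


@dataclass(frozen=True)
class Trajectory:
    """Per-frame kinematic ground truth."""

    time_s: np.ndarray
    location_m: np.ndarray
    speed_m_per_s: np.ndarray
    frame_rate_hz: float

    def __len__(self) -> int:
        return len(self.time_s)


def _integrate(profile: SprintProfile, dt: float) -> tuple[list, list, list]:
    """Step the velocity law at interval dt until the track is covered."""
    times, locs, speeds = [0.0], [0.0], [0.0 if profile.accel_tau_s > 0 else profile.v_max]
    t, loc, v = 0.0, 0.0, speeds[0]
    decel_t0: float | None = None
    v_onset = 0.0
    while loc < profile.track_length_m:
        t += dt
        if t > _MAX_SIM_S:
            raise ValueError(
                f"profile does not cover {profile.track_length_m} m within "
                f"{_MAX_SIM_S} s (v_max={profile.v_max}, tau={profile.accel_tau_s})"
            )
        if decel_t0 is None:
            if profile.accel_tau_s > 0:
                v_new = profile.v_max * (1.0 - math.exp(-t / profile.accel_tau_s))
            else:
                v_new = profile.v_max
        else:
            v_new = v_onset * math.exp(-profile.decel_rate * (t - decel_t0))
        loc += 0.5 * (v + v_new) * dt
        v = v_new
        if decel_t0 is None and loc >= profile.decel_onset_m:
            decel_t0, v_onset = t, v
        times.append(t)
        locs.append(loc)
        speeds.append(v)
    return times, locs, speeds


def simulate_profile(profile: SprintProfile) -> Trajectory:
    """Integrate the profile at the camera frame rate (trapezoid rule).

    The final frame is the first one at or past the finish line, so every
    camera segment — including the last metres — is covered by samples.
    """
    dt = 1.0 / profile.frame_rate_hz
    times, locs, speeds = _integrate(profile, dt)
    return Trajectory(
        time_s=np.asarray(times),
        location_m=np.asarray(locs),
        speed_m_per_s=np.asarray(speeds),
        frame_rate_hz=profile.frame_rate_hz,
    )


def subtask_ground_truth(
    profile: SprintProfile, subtask_length_m: float = 10.0, dt: float = 2.5e-4
) -> pd.DataFrame:
    """True mean speed per distance bin from a fine-step integration.

    The mean speed over a bin is the bin width divided by the time spent in
    it (the time average of instantaneous speed); crossing times come from
    linear interpolation of a trajectory stepped at ``dt`` seconds,
    independent of the camera frame rate.
    """
    times, locs, _ = _integrate(profile, dt)
    t = np.asarray(times)
    x = np.asarray(locs)
    n_bins = int(round(profile.track_length_m / subtask_length_m))
    edges = np.arange(n_bins + 1) * subtask_length_m
    # x is non-decreasing, so interpolation of t against x is well-defined
    crossing = np.interp(edges, x, t)
    widths = np.diff(edges)
    return pd.DataFrame(
        {
            "bin_start_m": edges[:-1],
            "bin_end_m": edges[1:],
            "mean_speed": widths / np.diff(crossing),
        }
    )


@dataclass(frozen=True)
class RenderSpec:
    """Appearance parameters for the four-camera rendering.

    The runner is a ``runner_size_px`` rectangle at ``runner_intensity`` on a
    uniform ``background_intensity`` field (dark athlete clothing against a
    bright track); the default contrast of 137 gray levels is well above the
    detection threshold of 40.  ``marker_pixel_positions`` holds one
    (marker_start_px, marker_end_px) pair per camera; the default 500-px span
    for 25 m gives 0.05 m per pixel.
    """

    width_px: int = 640
    height_px: int = 360
    runner_size_px: tuple[int, int] = (16, 60)  # (width, height)
    runner_intensity: float = 28.0
    background_intensity: float = 165.0
    noise_sd: float = 4.0
    distractor_count: int = 0
    distractor_size_px: int = 3
    ground_row: int = 310  # bottom edge of the silhouette
    marker_pixel_positions: tuple[tuple[float, float], ...] = ((570.0, 70.0),) * 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("runner_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255], got {v}")
        w, h = self.runner_size_px
        if w >= self.width_px or h >= self.height_px:
            raise ValueError(
                f"runner size {self.runner_size_px} exceeds the "
                f"{self.width_px}x{self.height_px} frame"
            )
        if self.noise_sd < 0 or self.distractor_count < 0:
            raise ValueError("noise_sd and distractor_count must be >= 0")


@dataclass(frozen=True)
class RenderedRun:
    """A rendered synthetic run with its complete ground truth."""

    trajectory: Trajectory
    sequences: list[FrameSequence]
    backgrounds: list[np.ndarray]
    calibrations: list[CameraCalibration]
    truth_x_px: list[np.ndarray]  # rasterized centroid column per camera, NaN off-screen
    config: RunConfig


def _segment_offsets(track_length_m: float, n_cameras: int) -> np.ndarray:
    span = track_length_m / n_cameras
    return np.arange(n_cameras) * span


def run_config_for(
    spec: RenderSpec, profile: SprintProfile, **overrides
) -> RunConfig:
    """RunConfig whose camera block matches the renderer's geometry."""
    n_cam = len(spec.marker_pixel_positions)
    span = profile.track_length_m / n_cam
    cameras = tuple(
        CameraGeometry(
            camera_id=f"cam{k + 1}",
            marker_start_px=spec.marker_pixel_positions[k][0],
            marker_end_px=spec.marker_pixel_positions[k][1],
            segment_span_m=span,
            segment_offset_m=k * span,
        )
        for k in range(n_cam)
    )
    overrides.setdefault("frame_rate_hz", profile.frame_rate_hz)
    overrides.setdefault("track_length_m", profile.track_length_m)
    return RunConfig(cameras=cameras, **overrides)


def _rasterize(cx: float, spec: RenderSpec) -> tuple[slice, slice, float] | None:
    """Visible pixel extent of the silhouette centred at column ``cx``.

    Returns (row slice, column slice, rasterized centroid column) or None if
    entirely off-screen; a partially visible silhouette is clipped and its
    centroid is that of the clipped rectangle.
    """
    w, h = spec.runner_size_px
    left = int(round(cx - w / 2.0))
    right = left + w  # exclusive
    left_c = max(left, 0)
    right_c = min(right, spec.width_px)
    if right_c <= left_c:
        return None
    top = max(spec.ground_row - h, 0)
    cols = slice(left_c, right_c)
    true_cx = 0.5 * (left_c + right_c - 1)
    return slice(top, spec.ground_row), cols, true_cx


def render_cameras(
    trajectory: Trajectory, spec: RenderSpec, profile: SprintProfile | None = None
) -> RenderedRun:
    """Render the trajectory into four camera views with known ground truth.

    Each camera covers one quarter of the track; the silhouette's centre
    column is the calibration map's inverse at the runner's true location.
    The stored background image carries its own independent noise draw, as a
    real pre-run background capture would.  Identical (trajectory, spec)
    inputs produce byte-identical frames.
    """
    rng = np.random.default_rng(spec.seed)
    n_cam = len(spec.marker_pixel_positions)
    track_length = float(trajectory.location_m[-1]) if profile is None else profile.track_length_m
    # round down to the nominal length for offset computation
    track_length = (
        profile.track_length_m if profile is not None else round(track_length / n_cam) * n_cam
    )
    offsets = _segment_offsets(track_length, n_cam)
    span = track_length / n_cam
    n_frames = len(trajectory)
    h, w = spec.height_px, spec.width_px

    sequences, backgrounds, calibrations, truths = [], [], [], []
    for k in range(n_cam):
        cam_id = f"cam{k + 1}"
        m_start, m_end = spec.marker_pixel_positions[k]
        cal = calibrate_camera(m_start, m_end, span, offsets[k], camera_id=cam_id)
        base = np.full((h, w), spec.background_intensity, dtype=np.float32)

        def _noisy(img: np.ndarray) -> np.ndarray:
            if spec.noise_sd > 0:
                noise = rng.standard_normal(img.shape, dtype=np.float32)
                img = img + spec.noise_sd * noise
            return np.clip(np.rint(img), 0, 255).astype(np.uint8)

        background = _noisy(base)
        # distractors: small moving blobs absent from the background capture
        d_pos = rng.uniform([0, 0], [h - 8, w - 8], size=(spec.distractor_count, 2))
        d_vel = rng.uniform(-3.0, 3.0, size=(spec.distractor_count, 2))

        frames = np.empty((n_frames, h, w), dtype=np.uint8)
        truth = np.full(n_frames, np.nan)
        for i in range(n_frames):
            canvas = base.copy()
            for d in range(spec.distractor_count):
                r0 = int(d_pos[d, 0] + d_vel[d, 0] * i) % (h - spec.distractor_size_px)
                c0 = int(d_pos[d, 1] + d_vel[d, 1] * i) % (w - spec.distractor_size_px)
                canvas[
                    r0 : r0 + spec.distractor_size_px, c0 : c0 + spec.distractor_size_px
                ] = spec.runner_intensity + 40.0
            cx = world_to_pixel(trajectory.location_m[i], cal)
            placed = _rasterize(cx, spec)
            if placed is not None:
                rows, cols, true_cx = placed
                canvas[rows, cols] = spec.runner_intensity
                truth[i] = true_cx
            frames[i] = _noisy(canvas)
        sequences.append(FrameSequence(cam_id, frames, trajectory.frame_rate_hz))
        backgrounds.append(background)
        calibrations.append(cal)
        truths.append(truth)

    config = run_config_for(
        spec,
        profile
        if profile is not None
        else SprintProfile.constant(
            max(float(trajectory.speed_m_per_s.max()), 1e-6),
            frame_rate_hz=trajectory.frame_rate_hz,
            track_length_m=track_length,
        ),
    )
    return RenderedRun(
        trajectory=trajectory,
        sequences=sequences,
        backgrounds=backgrounds,
        calibrations=calibrations,
        truth_x_px=truths,
        config=config,
    )


def make_fixture(
    profile: SprintProfile, spec: RenderSpec, out_dir: str | Path
) -> Path:
    """Write a self-contained on-disk dataset loadable by the I/O layer.

    Layout: ``cam{1..4}/frame_%05d.png``, ``cam{k}_background.png``,
    ``config.json``, ``ground_truth.csv`` (per-frame time, location, speed)
    and ``ground_truth_subtasks.csv`` (per-bin true mean speeds).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trajectory = simulate_profile(profile)
    run = render_cameras(trajectory, spec, profile)
    for seq, bg in zip(run.sequences, run.backgrounds):
        cam_dir = out_dir / seq.camera_id
        cam_dir.mkdir(exist_ok=True)
        for i in range(seq.n_frames):
            iio.imwrite(cam_dir / f"frame_{i:05d}.png", seq.frames[i])
        iio.imwrite(out_dir / f"{seq.camera_id}_background.png", bg)
    write_run_config(run.config, out_dir / "config.json")
    pd.DataFrame(
        {
            "frame": np.arange(len(trajectory)),
            "time_s": trajectory.time_s,
            "location_m": trajectory.location_m,
            "speed_m_per_s": trajectory.speed_m_per_s,
        }
    ).to_csv(out_dir / "ground_truth.csv", index=False)
    subtask_ground_truth(profile).to_csv(
        out_dir / "ground_truth_subtasks.csv", index=False
    )
    return out_dir
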