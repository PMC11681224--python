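import numpy as np
import pytest

from sprintvision import (
    RenderSpec,
    SprintProfile,
    detect_track,
    make_fixture,
    render_cameras,
    simulate_profile,
    subtask_ground_truth,
)


class TestSimulateProfile:
    def test_constant_profile_closed_form(self):
        profile = SprintProfile.constant(6.0)
        traj = simulate_profile(profile)
        np.testing.assert_allclose(traj.speed_m_per_s, 6.0)
        # finishes at 100/6 s; the trajectory includes the first frame past it
        assert traj.time_s[-1] == pytest.approx(100.0 / 6.0, abs=1.0 / 30.0 + 1e-9)
        assert traj.location_m[-1] >= 100.0

    def test_acceleration_phase_matches_analytic_velocity(self):
        profile = SprintProfile(v_max=7.0, accel_tau_s=1.2, decel_onset_m=100.0,
                                decel_rate=0.0)
        traj = simulate_profile(profile)
        expected = 7.0 * (1.0 - np.exp(-traj.time_s / 1.2))
        np.testing.assert_allclose(traj.speed_m_per_s, expected, atol=1e-9)

    def test_three_phases_present(self):
        traj = simulate_profile(SprintProfile())
        v = traj.speed_m_per_s
        assert v[0] == 0.0
        assert v.max() > 0.95 * 8.0  # reaches near maximum speed
        assert v[-1] < v.max()  # decelerating at the finish

    def test_locations_non_decreasing(self):
        traj = simulate_profile(SprintProfile())
        assert np.all(np.diff(traj.location_m) >= 0)

    def test_non_finishing_profile_rejected(self):
        with pytest.raises(ValueError, match="does not cover"):
            simulate_profile(SprintProfile(v_max=1.2, accel_tau_s=1.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="v_max"):
            SprintProfile(v_max=-1.0)
        with pytest.raises(ValueError, match="decel_onset_m"):
            SprintProfile(decel_onset_m=150.0)


class TestSubtaskGroundTruth:
    def test_constant_profile_bins_exact(self):
        gt = subtask_ground_truth(SprintProfile.constant(6.0))
        np.testing.assert_allclose(gt["mean_speed"], 6.0, rtol=1e-6)

    def test_matches_brute_force_integrator_oracle(self):
        profile = SprintProfile()
        gt = subtask_ground_truth(profile)
        # independent oracle: explicit Euler-style stepping at a finer step,
        # mean bin speed = bin width / time spent in the bin
        dt = 1e-4
        t, loc, v = 0.0, 0.0, 0.0
        onset_t, onset_v = None, 0.0
        crossings = [0.0]
        next_edge = 10.0
        while loc < 100.0:
            t += dt
            if onset_t is None:
                v_new = profile.v_max * (1 - np.exp(-t / profile.accel_tau_s))
            else:
                v_new = onset_v * np.exp(-profile.decel_rate * (t - onset_t))
            loc += 0.5 * (v + v_new) * dt
            v = v_new
            if onset_t is None and loc >= profile.decel_onset_m:
                onset_t, onset_v = t, v
            while next_edge <= 100.0 and loc >= next_edge:
                crossings.append(t)
                next_edge += 10.0
        expected = 10.0 / np.diff(crossings)
        np.testing.assert_allclose(gt["mean_speed"], expected, rtol=5e-4)


class TestRenderCameras:
    def test_noiseless_render_recovers_centroids_exactly(self, small_run, config):
        profile = SprintProfile.constant(5.0, track_length_m=20.0)
        spec = RenderSpec(
            marker_pixel_positions=((570.0, 70.0), (570.0, 70.0)), noise_sd=0.0, seed=0
        )
        run = render_cameras(simulate_profile(profile), spec, profile)
        for seq, bg, truth in zip(run.sequences, run.backgrounds, run.truth_x_px):
            track = detect_track(seq, bg, run.config)
            visible = np.isfinite(truth)
            assert np.isfinite(track.x_px[visible]).all()
            np.testing.assert_allclose(track.x_px[visible], truth[visible], atol=0.5)

    def test_same_seed_identical_frame_bytes(self):
        profile = SprintProfile.constant(5.0, track_length_m=20.0)
        spec = RenderSpec(marker_pixel_positions=((570.0, 70.0),) * 2, seed=5)
        traj = simulate_profile(profile)
        a = render_cameras(traj, spec, profile)
        b = render_cameras(traj, spec, profile)
        for sa, sb in zip(a.sequences, b.sequences):
            np.testing.assert_array_equal(sa.frames, sb.frames)

    def test_different_seeds_share_ground_truth(self):
        profile = SprintProfile.constant(5.0, track_length_m=20.0)
        traj = simulate_profile(profile)
        spec_a = RenderSpec(marker_pixel_positions=((570.0, 70.0),) * 2, seed=1)
        spec_b = RenderSpec(marker_pixel_positions=((570.0, 70.0),) * 2, seed=2)
        a = render_cameras(traj, spec_a, profile)
        b = render_cameras(traj, spec_b, profile)
        assert not all(
            np.array_equal(sa.frames, sb.frames)
            for sa, sb in zip(a.sequences, b.sequences)
        )
        for ta, tb in zip(a.truth_x_px, b.truth_x_px):
            np.testing.assert_array_equal(ta, tb)

    def test_oversized_runner_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            RenderSpec(runner_size_px=(700, 60))

    def test_distractors_below_area_floor_do_not_disturb_detection(self, config):
        profile = SprintProfile.constant(5.0, track_length_m=20.0)
        spec = RenderSpec(
            marker_pixel_positions=((570.0, 70.0),) * 2,
            noise_sd=4.0,
            distractor_count=3,
            seed=7,
        )
        run = render_cameras(simulate_profile(profile), spec, profile)
        for seq, bg, truth in zip(run.sequences, run.backgrounds, run.truth_x_px):
            track = detect_track(seq, bg, run.config)
            visible = np.isfinite(truth)
            detected = visible & np.isfinite(track.x_px)
            assert detected.sum() >= 0.95 * visible.sum()
            np.testing.assert_allclose(
                track.x_px[detected], truth[detected], atol=2.0
            )


class TestMakeFixture:
    def test_fixture_layout_and_ground_truth(self, tmp_path):
        profile = SprintProfile.constant(5.0, track_length_m=20.0)
        spec = RenderSpec(marker_pixel_positions=((570.0, 70.0),) * 2, seed=3)
        out = make_fixture(profile, spec, tmp_path / "fx")
        assert (out / "config.json").exists()
        assert (out / "ground_truth.csv").exists()
        assert (out / "ground_truth_subtasks.csv").exists()
        for k in (1, 2):
            assert (out / f"cam{k}_background.png").exists()
            assert len(list((out / f"cam{k}").glob("frame_*.png"))) > 0

    def test_seed_isolation(self, tmp_path):
        profile = SprintProfile.constant(5.0, track_length_m=20.0)
        for seed, name in ((1, "a"), (2, "b")):
            spec = RenderSpec(marker_pixel_positions=((570.0, 70.0),) * 2, seed=seed)
            make_fixture(profile, spec, tmp_path / name)
        gt_a = (tmp_path / "a" / "ground_truth.csv").read_bytes()
        gt_b = (tmp_path / "b" / "ground_truth.csv").read_bytes()
        assert gt_a == gt_b  # trajectory independent of the render seed
        frame_a = (tmp_path / "a" / "cam1" / "frame_00010.png").read_bytes()
        frame_b = (tmp_path / "b" / "cam1" / "frame_00010.png").read_bytes()
        assert frame_a != frame_b  # noise differs
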