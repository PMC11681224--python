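import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

from sprintvision import (
    FrameSequence,
    RunConfig,
    denoise_mask,
    detect_track,
    locate_centroid,
    subtract_background,
    threshold_and_binarize,
)
from conftest import brute_force_median, flood_fill_components


class TestSubtractBackground:
    def test_identical_images_give_zero(self):
        img = np.full((8, 8), 120, np.uint8)
        assert subtract_background(img, img).max() == 0

    def test_single_pixel_arithmetic(self):
        f = np.full((4, 4), 160, np.uint8)
        b = f.copy()
        f[2, 1] = 200
        diff = subtract_background(f, b)
        assert diff[2, 1] == 40 and diff.sum() == 40

    def test_absolute_difference_matches_pixel_loop(self):
        rng = np.random.default_rng(42)
        f = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        b = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        diff = subtract_background(f, b)
        for r in range(20):
            for c in range(20):
                assert diff[r, c] == abs(int(f[r, c]) - int(b[r, c]))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="does not match"):
            subtract_background(np.zeros((4, 4)), np.zeros((4, 5)))


class TestThreshold:
    def test_strict_inequality_at_tau(self):
        diff = np.array([[40, 41]], dtype=np.uint8)
        mask = threshold_and_binarize(diff, 40)
        assert mask.tolist() == [[0, 1]]

    def test_zero_difference_gives_empty_mask(self):
        assert threshold_and_binarize(np.zeros((6, 6), np.uint8), 40).sum() == 0

    def test_foreground_count_matches_brute_force(self):
        rng = np.random.default_rng(7)
        diff = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        mask = threshold_and_binarize(diff, 40)
        expected = sum(1 for v in diff.ravel() if v > 40)
        assert mask.sum() == expected

    def test_out_of_range_tau(self):
        with pytest.raises(ValueError, match="tau"):
            threshold_and_binarize(np.zeros((2, 2)), 300)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 1000),
        tau_lo=st.integers(0, 254),
        delta=st.integers(1, 100),
    )
    def test_raising_tau_never_adds_foreground(self, seed, tau_lo, delta):
        rng = np.random.default_rng(seed)
        diff = rng.integers(0, 256, (15, 15), dtype=np.uint8)
        lo = threshold_and_binarize(diff, tau_lo)
        hi = threshold_and_binarize(diff, min(tau_lo + delta, 255))
        assert hi.sum() <= lo.sum()
        assert np.all(lo >= hi)  # foreground at high tau is a subset


class TestDenoiseMask:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), np.uint8)
        mask[4, 4] = 1
        assert denoise_mask(mask, 3).sum() == 0

    def test_solid_block_interior_unchanged(self):
        mask = np.zeros((14, 14), np.uint8)
        mask[2:12, 2:12] = 1
        out = denoise_mask(mask, 3)
        np.testing.assert_array_equal(out[3:11, 3:11], 1)

    @pytest.mark.parametrize("kernel", [1, 3, 5, 7])
    def test_matches_sliding_window_median_oracle(self, kernel):
        rng = np.random.default_rng(3)
        mask = (rng.random((24, 31)) < 0.4).astype(np.uint8)
        np.testing.assert_array_equal(
            denoise_mask(mask, kernel), brute_force_median(mask, kernel)
        )

    def test_matches_independent_scipy_median(self):
        rng = np.random.default_rng(5)
        mask = (rng.random((40, 40)) < 0.5).astype(np.uint8)
        np.testing.assert_array_equal(
            denoise_mask(mask, 3), ndi.median_filter(mask, size=3, mode="nearest")
        )

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            denoise_mask(np.zeros((4, 4), np.uint8), 2)

    def test_output_binary(self):
        rng = np.random.default_rng(9)
        mask = (rng.random((20, 20)) < 0.5).astype(np.uint8)
        assert set(np.unique(denoise_mask(mask, 5))) <= {0, 1}


class TestLocateCentroid:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[7, 5] = 1
        assert locate_centroid(mask, min_blob_area_px=1) == (5.0, 7.0)

    def test_symmetric_block(self):
        mask = np.zeros((10, 20), np.uint8)
        mask[2:5, 10:13] = 1
        assert locate_centroid(mask, min_blob_area_px=1) == (11.0, 3.0)

    def test_area_filter_and_largest_blob_vs_flood_fill(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[2:12, 2:7] = 1  # area 50
        mask[20:24, 20:23] = 1  # area 12, below the floor
        got = locate_centroid(mask, min_blob_area_px=20)
        comps = flood_fill_components(mask)
        big = max(comps, key=len)
        assert len(big) == 50
        expected = (
            float(np.mean([c for _, c in big])),
            float(np.mean([r for r, _ in big])),
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_no_surviving_blob_is_missing_not_error(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[0, 0] = 1
        assert locate_centroid(mask, min_blob_area_px=5) is None

    def test_tie_broken_by_topleft_corner(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[10:13, 1:4] = 1  # same area, lower-right
        mask[1:4, 10:13] = 1  # upper block wins (smaller row of corner)
        x, y = locate_centroid(mask, min_blob_area_px=1)
        assert (x, y) == (11.0, 2.0)

    def test_centroid_inside_component_bounding_box(self):
        rng = np.random.default_rng(17)
        mask = (rng.random((40, 40)) < 0.45).astype(np.uint8)
        found = locate_centroid(mask, min_blob_area_px=1)
        assert found is not None
        x, y = found
        labels, _ = ndi.label(mask, structure=np.ones((3, 3)))
        areas = np.bincount(labels.ravel())[1:]
        rows, cols = np.nonzero(labels == int(np.argmax(areas)) + 1)
        assert cols.min() <= x <= cols.max() and rows.min() <= y <= rows.max()


class TestDetectTrack:
    def _make_seq(self, n=40, step=4.0, noise=None, seed=0):
        """Dark 20x60 rectangle translating on a uniform bright background."""
        h, w = 200, 400
        bg = np.full((h, w), 160, np.uint8)
        frames = np.empty((n, h, w), np.uint8)
        truth = []
        rng = np.random.default_rng(seed)
        for i in range(n):
            f = bg.copy()
            left = int(round(10 + step * i))
            f[100:160, left : left + 20] = 30
            truth.append(left + 9.5)
            if noise:
                sp = rng.random((h, w))
                f[sp < noise / 2] = 0
                f[sp > 1 - noise / 2] = 255
            frames[i] = f
        return FrameSequence("cam1", frames, 30.0), bg, np.array(truth)

    def test_translating_rectangle_advances_four_px_per_frame(self, config):
        seq, bg, truth = self._make_seq()
        track = detect_track(seq, bg, config)
        assert track.n_detected == seq.n_frames
        steps = np.diff(track.x_px)
        np.testing.assert_allclose(steps, 4.0, atol=0.5)
        np.testing.assert_allclose(track.x_px, truth, atol=0.5)

    def test_background_only_sequence_is_all_missing(self, config):
        bg = np.full((50, 80), 160, np.uint8)
        seq = FrameSequence("cam1", np.repeat(bg[None], 5, axis=0), 30.0)
        track = detect_track(seq, bg, config)
        assert track.n_detected == 0

    def test_salt_and_pepper_noise_tolerated(self, config):
        seq, bg, truth = self._make_seq(noise=0.05, seed=1)
        track = detect_track(seq, bg, config)
        assert track.detection_rate >= 0.95
        detected = np.isfinite(track.x_px)
        assert np.max(np.abs(track.x_px[detected] - truth[detected])) <= 2.0

    def test_stage_composition_equals_manual_chain(self, config):
        """The stacked fast path must equal the single-frame stage functions."""
        seq, bg, _ = self._make_seq(n=6, noise=0.05, seed=2)
        track = detect_track(seq, bg, config)
        for i in range(seq.n_frames):
            diff = subtract_background(seq.frames[i], bg)
            mask = threshold_and_binarize(diff, config.threshold_tau)
            mask = denoise_mask(mask, config.median_kernel_px)
            found = locate_centroid(mask, config.min_blob_area_px)
            if found is None:
                assert np.isnan(track.x_px[i])
            else:
                assert track.x_px[i] == pytest.approx(found[0], abs=1e-12)
                assert track.y_px[i] == pytest.approx(found[1], abs=1e-12)
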