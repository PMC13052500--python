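"""Signal math (reflectivity, phase retardation) and en-face map operations."""

import numpy as np
import pytest

import kerapol as kp
from kerapol.psoct import _window_pixels


class TestSignalMath:
    @pytest.mark.parametrize(
        "a1, a2, expected",
        [([0.0], [0.0], [0.0]), ([1.0], [0.0], [1.0]), ([3.0], [4.0], [25.0])],
    )
    def test_reflectivity_sum_of_squares(self, a1, a2, expected):
        pair = kp.AScanPair(np.array(a1), np.array(a2))
        np.testing.assert_allclose(kp.compute_reflectivity(pair), expected)

    @pytest.mark.parametrize(
        "a1, a2, expected_deg",
        [([1.0], [1.0], 45.0), ([1.0], [0.0], 0.0), ([0.0], [1.0], 90.0)],
    )
    def test_phase_retardation_arctan_cases(self, a1, a2, expected_deg):
        pair = kp.AScanPair(np.array(a1), np.array(a2))
        pr, valid = kp.compute_phase_retardation(pair)
        assert valid.all()
        np.testing.assert_allclose(pr, [expected_deg], atol=1e-12)

    def test_zero_zero_sample_flagged_invalid(self):
        pair = kp.AScanPair(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        _, valid = kp.compute_phase_retardation(pair)
        assert valid.tolist() == [True, False]

    def test_channel_swap_symmetry(self):
        """Swapping channels leaves R unchanged and maps PR to 90 - PR."""
        rng = np.random.default_rng(3)
        a1, a2 = rng.uniform(0.1, 2.0, 16), rng.uniform(0.1, 2.0, 16)
        p = kp.AScanPair(a1, a2)
        q = kp.AScanPair(a2, a1)
        np.testing.assert_allclose(kp.compute_reflectivity(p), kp.compute_reflectivity(q))
        pr_p, _ = kp.compute_phase_retardation(p)
        pr_q, _ = kp.compute_phase_retardation(q)
        np.testing.assert_allclose(pr_p, 90.0 - pr_q, atol=1e-9)

    @pytest.mark.parametrize("theta", range(0, 91, 15))
    def test_synthesize_recover_round_trip(self, theta):
        pair = kp.synthesize_ascan_pair(theta, amplitude=1.5, n_depth=8, noise_sd=0.0)
        pr, valid = kp.compute_phase_retardation(pair)
        assert valid.all()
        np.testing.assert_allclose(pr, theta, atol=1e-9)

    def test_noisy_recovery_unbiased(self):
        """Monte-Carlo: mean recovered PR within 3 sd of the 30-degree truth."""
        est = []
        for s in range(1000):
            pair = kp.synthesize_ascan_pair(30.0, 2.0, 16, 0.01, rng_seed=s)
            pr, _ = kp.compute_phase_retardation(pair)
            est.append(pr.mean())
        est = np.asarray(est)
        assert abs(est.mean() - 30.0) <= 3.0 * est.std(ddof=1)


class TestEnfaceExtraction:
    def test_constant_volume_gives_constant_map(self):
        vol, surf = kp.synthesize_pr_volume(np.full((4, 5), 45.0))
        cmap = kp.extract_enface_pr(vol, surf)
        assert cmap.mask.all()
        np.testing.assert_allclose(cmap.values, 45.0, atol=1e-12)

    def test_round_trip_recovers_known_field(self):
        rng = np.random.default_rng(8)
        field = rng.uniform(5.0, 85.0, size=(6, 7))
        vol, surf = kp.synthesize_pr_volume(field, noise_sd=0.0)
        cmap = kp.extract_enface_pr(vol, surf)
        np.testing.assert_allclose(cmap.values, field, atol=1e-9)

    def test_all_zero_ascan_masks_only_that_pixel(self):
        vol, surf = kp.synthesize_pr_volume(np.full((3, 3), 30.0))
        vol[1][1] = kp.AScanPair(np.zeros(4), np.zeros(4))
        cmap = kp.extract_enface_pr(vol, surf)
        assert not cmap.mask[1, 1]
        assert cmap.mask.sum() == 8

    def test_out_of_range_surface_index_names_ascan(self):
        vol, surf = kp.synthesize_pr_volume(np.full((2, 2), 30.0), n_depth=4)
        surf[0, 1] = 7
        with pytest.raises(IndexError, match="ix=1"):
            kp.extract_enface_pr(vol, surf)


class TestSmoothing:
    def test_constant_map_unchanged(self, constant_map):
        out = kp.smooth_map(constant_map, (1.0, 1.0))
        np.testing.assert_allclose(out.values, constant_map.values)

    def test_impulse_spreads_to_one_over_k(self):
        """Unit impulse: covered pixels equal 1/k, brute-force enumerated."""
        vals = np.zeros((15, 15))
        vals[7, 7] = 1.0
        cmap = kp.CornealMap(vals, (0.25, 0.25), "phase_retardation")
        out = kp.smooth_map(cmap, (1.0, 1.0))
        k = _window_pixels(1.0, 0.25) ** 2
        # brute force: recompute each pixel as the window mean
        half = _window_pixels(1.0, 0.25) // 2
        for iy in range(15):
            for ix in range(15):
                y0, y1 = max(0, iy - half), min(15, iy + half + 1)
                x0, x1 = max(0, ix - half), min(15, ix + half + 1)
                expected = vals[y0:y1, x0:x1].mean()
                assert out.values[iy, ix] == pytest.approx(expected, abs=1e-12)
        covered = out.values[out.values > 0]
        assert covered.size == k
        np.testing.assert_allclose(covered, 1.0 / k)

    def test_double_smoothing_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        cmap = kp.CornealMap(
            rng.uniform(10, 80, (20, 24)), (0.25, 0.25), "phase_retardation"
        )
        once = kp.smooth_map(cmap, (1.0, 1.0))
        twice = kp.smooth_map(once, (1.0, 1.0))

        # independent oracle: apply the shrink-at-border window mean twice
        def brute(vals, half):
            ny, nx = vals.shape
            out = np.empty_like(vals)
            for iy in range(ny):
                for ix in range(nx):
                    out[iy, ix] = vals[
                        max(0, iy - half) : iy + half + 1,
                        max(0, ix - half) : ix + half + 1,
                    ].mean()
            return out

        half = _window_pixels(1.0, 0.25) // 2
        expected = brute(brute(cmap.values, half), half)
        np.testing.assert_allclose(twice.values, expected, atol=1e-10)

    def test_interior_sum_conserved(self):
        """A signal surrounded by a zero margin wider than the kernel keeps its total."""
        vals = np.zeros((21, 21))
        rng = np.random.default_rng(2)
        vals[8:13, 8:13] = rng.uniform(1, 5, (5, 5))
        cmap = kp.CornealMap(vals, (0.25, 0.25), "phase_retardation")
        out = kp.smooth_map(cmap, (1.0, 1.0))
        assert out.values.sum() == pytest.approx(vals.sum(), rel=1e-12)

    def test_masked_pixels_excluded(self):
        vals = np.full((9, 9), 10.0)
        vals[4, 4] = 500.0  # masked out; must not leak into neighbours
        mask = np.ones((9, 9), bool)
        mask[4, 4] = False
        cmap = kp.CornealMap(vals, (0.25, 0.25), "phase_retardation", mask=mask)
        out = kp.smooth_map(cmap, (1.0, 1.0))
        np.testing.assert_allclose(out.values[mask], 10.0)
        assert not out.mask[4, 4]

    def test_invalid_window_rejected(self, constant_map):
        with pytest.raises(ValueError):
            kp.smooth_map(constant_map, (0.0, 1.0))


class TestCrop:
    def test_crop_to_own_extent_is_identity(self, constant_map):
        out = kp.crop_field(constant_map, constant_map.extent_mm)
        assert out.shape == constant_map.shape
        np.testing.assert_allclose(out.values, constant_map.values)

    def test_ten_by_eight_to_eight_square_symmetric(self):
        vals = np.arange(32 * 40, dtype=float).reshape(32, 40)
        cmap = kp.CornealMap(vals, (0.25, 0.25), "reflectivity")
        out = kp.crop_field(cmap, (8.0, 8.0))
        assert out.shape == (32, 32)
        np.testing.assert_allclose(out.values, vals[:, 4:36])

    def test_crop_twice_equals_single_crop(self):
        rng = np.random.default_rng(4)
        cmap = kp.CornealMap(rng.uniform(1, 2, (32, 40)), (0.25, 0.25), "reflectivity")
        once = kp.crop_field(cmap, (6.0, 6.0))
        twice = kp.crop_field(kp.crop_field(cmap, (8.0, 8.0)), (6.0, 6.0))
        np.testing.assert_allclose(once.values, twice.values)

    def test_oversize_crop_rejected(self, constant_map):
        with pytest.raises(ValueError):
            kp.crop_field(constant_map, (50.0, 50.0))
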