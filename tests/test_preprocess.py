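import numpy as np
import pytest

from hsiprep import preprocess
from hsiprep.hsio import RawCube, ReferencePair, ReflectanceCube


def _refs(bands=6, dark=100.0, white=4000.0):
    return ReferencePair(
        dark=np.full(bands, dark), white=np.full(bands, white)
    )


def _raw(values, wl=None):
    values = np.asarray(values, dtype=np.float32)
    if wl is None:
        wl = np.linspace(500, 1000, values.shape[2])
    return RawCube(values, wl)


class TestCalibration:
    def test_raw_equal_white_gives_100(self):
        refs = _refs()
        raw = _raw(np.broadcast_to(refs.white, (3, 3, 6)).copy())
        cal = preprocess.calibrate(raw, refs)
        np.testing.assert_allclose(cal.values, 100.0, atol=1e-4)

    def test_raw_equal_dark_gives_0(self):
        refs = _refs()
        raw = _raw(np.broadcast_to(refs.dark, (3, 3, 6)).copy())
        cal = preprocess.calibrate(raw, refs)
        np.testing.assert_allclose(cal.values, 0.0, atol=1e-4)

    def test_raw_midway_gives_50(self):
        refs = _refs()
        raw = _raw(np.broadcast_to((refs.white + refs.dark) / 2, (2, 2, 6)).copy())
        cal = preprocess.calibrate(raw, refs)
        np.testing.assert_allclose(cal.values, 50.0, atol=1e-4)

    def test_unusable_references_rejected(self):
        refs = ReferencePair(dark=np.full(6, 500.0), white=np.full(6, 500.0))
        with pytest.raises(preprocess.CalibrationError):
            preprocess.calibrate(_raw(np.ones((2, 2, 6))), refs)

    def test_affine_monotone_in_raw(self):
        """Calibration is affine in R: raising any raw count raises C."""
        refs = _refs()
        rng = np.random.default_rng(0)
        base = rng.uniform(200, 3800, (4, 4, 6))
        cal1 = preprocess.calibrate(_raw(base), refs)
        cal2 = preprocess.calibrate(_raw(base + 10), refs)
        assert np.all(cal2.values > cal1.values)


class TestEdgeBands:
    def test_keep_550_950_on_5nm_axis_gives_81_bands(self):
        wl = np.arange(500.0, 1000.1, 5.0)  # 101 bands
        cube = ReflectanceCube(np.ones((2, 2, len(wl))), wl)
        out = preprocess.remove_edge_bands(cube, 550.0, 950.0)
        assert out.n_bands == 81  # 550, 555, ..., 950
        assert out.wavelengths[0] == 550.0 and out.wavelengths[-1] == 950.0

    def test_covering_range_is_identity(self, toy_cube):
        out = preprocess.remove_edge_bands(toy_cube, 0.0, 2000.0)
        np.testing.assert_array_equal(out.values, toy_cube.values)

    def test_disjoint_range_rejected(self, toy_cube):
        with pytest.raises(ValueError, match="no bands"):
            preprocess.remove_edge_bands(toy_cube, 2000.0, 2100.0)


class TestSubsampling:
    def test_brain_826_to_128_band_spacing(self):
        """826 bands over 400-1000 nm, edge-trimmed to 440-902 nm, then
        subsampled to 128 bands: mean step ~3.61 nm."""
        wl = np.linspace(400.0, 1000.0, 826)
        cube = ReflectanceCube(np.ones((2, 2, 826), dtype=np.float32), wl)
        cube = preprocess.remove_edge_bands(cube, 440.0, 902.0)
        out = preprocess.subsample_bands(cube, 128)
        assert out.n_bands == 128
        mean_step = np.diff(out.wavelengths).mean()
        assert mean_step == pytest.approx(3.61, rel=0.02)

    def test_target_equal_bands_is_identity(self, toy_cube):
        out = preprocess.subsample_bands(toy_cube, toy_cube.n_bands)
        np.testing.assert_array_equal(out.values, toy_cube.values)

    def test_ten_to_five_uniform_indices(self):
        """10 bands -> 5 selects indices round(i*9/4) = {0, 2, 4, 7, 9}."""
        wl = np.arange(10, dtype=float)
        values = np.arange(10, dtype=float).reshape(1, 1, 10)
        cube = ReflectanceCube(values, wl)
        out = preprocess.subsample_bands(cube, 5)
        np.testing.assert_array_equal(out.wavelengths, [0, 2, 4, 7, 9])

    def test_target_below_two_rejected(self, toy_cube):
        with pytest.raises(ValueError):
            preprocess.subsample_bands(toy_cube, 1)


def _brute_force_erode(mask, radius):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            r0, r1 = max(0, r - radius), min(h, r + radius + 1)
            c0, c1 = max(0, c - radius), min(w, c + radius + 1)
            window_full = (r1 - r0) == 2 * radius + 1 and (c1 - c0) == 2 * radius + 1
            out[r, c] = mask[r0:r1, c0:c1].all() and window_full
    return out


def _brute_force_dilate(mask, radius):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            r0, r1 = max(0, r - radius), min(h, r + radius + 1)
            c0, c1 = max(0, c - radius), min(w, c + radius + 1)
            out[r, c] = mask[r0:r1, c0:c1].any()
    return out


class TestGlare:
    def _cube_from_mean(self, mean_image, bands=4):
        values = np.repeat(np.asarray(mean_image, dtype=float)[..., None], bands, axis=2)
        return ReflectanceCube(values, np.linspace(500, 900, bands))

    def test_no_candidates_gives_empty_mask(self):
        cube = self._cube_from_mean(np.full((6, 6), 50.0))
        assert not preprocess.detect_glare(cube, threshold=90.0).any()

    def test_isolated_pixel_removed_by_opening(self):
        mean = np.full((7, 7), 50.0)
        mean[3, 3] = 99.0
        cube = self._cube_from_mean(mean)
        assert not preprocess.detect_glare(cube, 90.0, structuring_radius=1).any()

    def test_block_mask_matches_brute_force_morphology(self):
        """5x5 bright block, radius 1: opening keeps the block, the extra
        dilation adds a 1-pixel border."""
        mean = np.full((11, 11), 50.0)
        mean[3:8, 3:8] = 99.0
        cube = self._cube_from_mean(mean)
        got = preprocess.detect_glare(cube, 90.0, structuring_radius=1)
        candidates = mean >= 90.0
        expected = _brute_force_dilate(
            _brute_force_dilate(_brute_force_erode(candidates, 1), 1), 1
        )
        np.testing.assert_array_equal(got, expected)

    def test_random_masks_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            mean = np.where(rng.random((12, 12)) < 0.3, 99.0, 10.0)
            cube = self._cube_from_mean(mean)
            got = preprocess.detect_glare(cube, 90.0, structuring_radius=1)
            cand = mean >= 90.0
            expected = _brute_force_dilate(
                _brute_force_dilate(_brute_force_erode(cand, 1), 1), 1
            )
            np.testing.assert_array_equal(got, expected)


class TestSpectralSmoothing:
    def test_constant_spectrum_unchanged(self):
        cube = ReflectanceCube(np.full((3, 3, 12), 42.0), np.arange(12.0))
        out = preprocess.gaussian_spectral_smooth(cube, 2.0)
        np.testing.assert_allclose(out.values, 42.0, atol=1e-10)

    def test_linear_ramp_interior_unchanged(self):
        """A symmetric unit-sum kernel leaves a linear function unchanged
        away from the boundary."""
        ramp = np.tile(np.arange(40.0), (2, 2, 1))
        cube = ReflectanceCube(ramp, np.arange(40.0))
        out = preprocess.gaussian_spectral_smooth(cube, 2.0)
        np.testing.assert_allclose(out.values[..., 10:30], ramp[..., 10:30], atol=1e-8)

    def test_symmetric_spectrum_stays_symmetric(self):
        spec = np.concatenate([np.arange(10.0), np.arange(10.0)[::-1]])
        cube = ReflectanceCube(np.tile(spec, (2, 2, 1)), np.arange(20.0))
        out = preprocess.gaussian_spectral_smooth(cube, 1.5)
        np.testing.assert_allclose(out.values, out.values[..., ::-1], atol=1e-10)

    def test_too_few_bands_rejected(self):
        cube = ReflectanceCube(np.ones((2, 2, 2)), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            preprocess.gaussian_spectral_smooth(cube, 1.0)


class TestMedianSmoothing:
    def test_constant_image_unchanged(self):
        cube = ReflectanceCube(np.full((5, 5, 3), 7.0), np.arange(3.0))
        out = preprocess.median_spatial_smooth(cube, 3)
        np.testing.assert_array_equal(out.values, cube.values)

    def test_outlier_replaced_by_background(self):
        values = np.full((5, 5, 2), 10.0)
        values[2, 2, :] = 99.0
        cube = ReflectanceCube(values, np.array([1.0, 2.0]))
        out = preprocess.median_spatial_smooth(cube, 3)
        np.testing.assert_allclose(out.values[2, 2], 10.0)

    def test_center_of_1_to_9_window_is_5(self):
        values = np.arange(1.0, 10.0).reshape(3, 3, 1)
        cube = ReflectanceCube(values, np.array([1.0]))
        out = preprocess.median_spatial_smooth(cube, 3)
        assert out.values[1, 1, 0] == 5.0

    def test_invalid_pixels_excluded_from_windows(self):
        """A glare pixel's (extreme) value must not leak into neighbours."""
        values = np.full((5, 5, 2), 10.0)
        values[2, 2, :] = 1e6
        valid = np.ones((5, 5), dtype=bool)
        valid[2, 2] = False
        cube = ReflectanceCube(values, np.array([1.0, 2.0]), valid_mask=valid)
        out = preprocess.median_spatial_smooth(cube, 3)
        np.testing.assert_allclose(out.values[1, 1], 10.0)
        np.testing.assert_allclose(out.values[2, 1], 10.0)

    def test_kernel_larger_than_image_rejected(self):
        cube = ReflectanceCube(np.ones((3, 3, 2)), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            preprocess.median_spatial_smooth(cube, 5)


class TestMinMax:
    def test_three_values_map_to_0_half_1(self):
        values = np.array([2.0, 4.0, 6.0]).reshape(1, 1, 3)
        cube = ReflectanceCube(values, np.arange(3.0))
        out = preprocess.minmax_scale(cube)
        np.testing.assert_allclose(out.values.ravel(), [0.0, 0.5, 1.0])

    def test_output_attains_0_and_1(self, toy_cube):
        out = preprocess.minmax_scale(toy_cube)
        valid = out.values[out.valid_mask]
        assert valid.min() == 0.0 and valid.max() == 1.0

    def test_reapplication_is_identity(self, toy_cube):
        once = preprocess.minmax_scale(toy_cube)
        twice = preprocess.minmax_scale(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_cube_rejected(self):
        cube = ReflectanceCube(np.full((2, 2, 3), 5.0), np.arange(3.0))
        with pytest.raises(ValueError, match="degenerate"):
            preprocess.minmax_scale(cube)

    def test_glare_pixels_excluded_from_statistics(self):
        values = np.full((2, 2, 3), 10.0)
        values[0, 0] = [0.0, 500.0, 10.0]  # extreme glare pixel
        values[1, 1] = [10.0, 20.0, 30.0]
        valid = np.array([[False, True], [True, True]])
        cube = ReflectanceCube(values, np.arange(3.0), valid_mask=valid)
        out = preprocess.minmax_scale(cube)
        valid_vals = out.values[out.valid_mask]
        assert valid_vals.min() == 0.0 and valid_vals.max() == 1.0

    def test_scale_invariance_under_global_multiplication(self, toy_cube):
        """Min-max scaling cancels a per-cube multiplicative factor."""
        scaled = ReflectanceCube(toy_cube.values * 1.7, toy_cube.wavelengths)
        a = preprocess.minmax_scale(toy_cube)
        b = preprocess.minmax_scale(scaled)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestSNV:
    def test_1_2_3_maps_to_minus1_0_1(self):
        cube = ReflectanceCube(np.array([[[1.0, 2.0, 3.0]]]), np.arange(3.0))
        out = preprocess.snv_normalize(cube)
        np.testing.assert_allclose(out.values.ravel(), [-1.0, 0.0, 1.0])

    def test_every_spectrum_mean0_sd1(self, toy_cube):
        out = preprocess.snv_normalize(toy_cube)
        means = out.values.mean(axis=2)
        sds = out.values.std(axis=2, ddof=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)
        np.testing.assert_allclose(sds, 1.0, atol=1e-9)

    def test_affine_invariance(self, toy_cube):
        """snv(a*x + b) == snv(x) for a > 0: removes per-pixel additive and
        multiplicative distortions."""
        distorted = ReflectanceCube(
            toy_cube.values * 3.5 + 12.0, toy_cube.wavelengths
        )
        a = preprocess.snv_normalize(toy_cube)
        b = preprocess.snv_normalize(distorted)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_idempotent(self, toy_cube):
        once = preprocess.snv_normalize(toy_cube)
        twice = preprocess.snv_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_constant_spectrum_flagged_invalid(self):
        values = np.ones((2, 2, 4))
        values[0, 0] = [1.0, 2.0, 3.0, 4.0]
        cube = ReflectanceCube(values, np.arange(4.0))
        out = preprocess.snv_normalize(cube)
        assert out.valid_mask[0, 0]
        assert not out.valid_mask[0, 1]
        assert not out.valid_mask[1, 1]


class TestChains:
    def _phantom(self):
        from hsiprep import synthgen

        spec = synthgen.PhantomSpec(
            image_height=24, image_width=24, n_bands=24, glare_fraction=0.0, seed=4
        )
        return synthgen.generate_patient_cube(spec, "P01", seed=6)

    def test_calibrated_is_composition_of_steps(self):
        p = self._phantom()
        chain = preprocess.apply_chain(p.raw, p.refs, "calibrated")
        manual = preprocess.remove_edge_bands(
            preprocess.calibrate(p.raw, p.refs), 550.0, 950.0
        )
        np.testing.assert_array_equal(chain.values, manual.values)

    def test_medfilter_ends_with_snv(self):
        p = self._phantom()
        out = preprocess.apply_chain(p.raw, p.refs, "medfilter")
        valid = out.valid_mask
        np.testing.assert_allclose(out.values[valid].mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(
            out.values[valid].std(axis=1, ddof=1), 1.0, atol=1e-9
        )

    def test_unknown_preset_rejected(self):
        p = self._phantom()
        with pytest.raises(ValueError, match="unknown preset"):
            preprocess.apply_chain(p.raw, p.refs, "min-max")

    def test_provenance_records_each_step(self):
        p = self._phantom()
        out = preprocess.apply_chain(p.raw, p.refs, "minmax")
        joined = " ".join(out.history)
        for step in ("calibrate", "remove_edge_bands", "glare_removal",
                     "gaussian_spectral_smooth", "minmax_scale"):
            assert step in joined

    def test_smoothing_never_changes_constant_cube(self):
        cube = ReflectanceCube(np.full((6, 6, 10), 3.0), np.arange(10.0))
        g = preprocess.gaussian_spectral_smooth(cube, 2.0)
        m = preprocess.median_spatial_smooth(cube, 3)
        np.testing.assert_allclose(g.values, 3.0, atol=1e-12)
        np.testing.assert_allclose(m.values, 3.0, atol=1e-12)
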