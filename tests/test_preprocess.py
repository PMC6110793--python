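import numpy as np
import pytest

from benthospec.cube import Stage
from benthospec.preprocess import (
    MovingAverageSmoother,
    PreprocessConfig,
    ReferenceMode,
    compute_reference,
    preprocess_cube,
    pseudo_reflectance,
    smooth_spectra,
    spectral_subset,
)
from benthospec.simulate import SceneConfig, generate_scene, make_band_grid

from conftest import make_cube


class TestSpectralSubset:
    def test_default_grid_keeps_83_bands(self):
        """The 112-band instrument grid reduces to the 83 bands between
        400 and 710 nm."""
        wl = make_band_grid().centers
        cube = make_cube(np.ones((2, 2, len(wl))), wavelengths=wl)
        sub = spectral_subset(cube, 400.0, 710.0)
        assert sub.n_bands == 83
        assert sub.wavelengths[0] >= 400.0 and sub.wavelengths[-1] <= 710.0

    def test_covering_range_is_identity(self, small_cube):
        sub = spectral_subset(small_cube, 0.0, 1e4)
        np.testing.assert_array_equal(sub.data, small_cube.data)

    def test_bounds_inclusive(self):
        cube = make_cube(np.ones((1, 1, 3)), wavelengths=[400.0, 500.0, 600.0])
        sub = spectral_subset(cube, 400.0, 600.0)
        assert sub.n_bands == 3

    def test_empty_selection_rejected(self, small_cube):
        with pytest.raises(ValueError, match="no band"):
            spectral_subset(small_cube, 10.0, 20.0)


class TestReference:
    def test_constant_cube_reference_equals_spectrum(self):
        s = np.array([3.0, 5.0, 7.0])
        cube = make_cube(np.tile(s, (4, 3, 1)))
        for mode in ReferenceMode:
            ref = compute_reference(cube, mode)
            np.testing.assert_allclose(ref.spectra, np.broadcast_to(s, ref.spectra.shape))

    def test_column_mean_oracle(self):
        """Two lines with column-0 spectra (1,1) and (3,3) average to (2,2)."""
        data = np.ones((2, 2, 2))
        data[0, 0] = [1.0, 1.0]
        data[1, 0] = [3.0, 3.0]
        ref = compute_reference(make_cube(data), ReferenceMode.COLUMN_MEAN)
        np.testing.assert_allclose(ref.spectra[0], [2.0, 2.0])

    def test_global_mean_oracle(self, small_cube):
        ref = compute_reference(small_cube, ReferenceMode.GLOBAL_MEAN)
        oracle = small_cube.data.reshape(-1, small_cube.n_bands).mean(axis=0)
        np.testing.assert_allclose(ref.spectra, oracle, rtol=1e-6)

    def test_column_median_resists_outlier_lines(self):
        data = np.full((9, 2, 3), 10.0)
        data[0] = 1000.0  # one anomalous line
        ref = compute_reference(make_cube(data), ReferenceMode.COLUMN_MEDIAN)
        np.testing.assert_allclose(ref.spectra, 10.0)

    def test_dead_band_rejected(self):
        data = np.ones((2, 2, 3))
        data[:, :, 1] = 0.0
        with pytest.raises(ValueError, match=r"band\(s\) \[1\]"):
            compute_reference(make_cube(data), ReferenceMode.GLOBAL_MEAN)

    def test_processed_cube_rejected(self, small_cube):
        pr = pseudo_reflectance(
            small_cube, compute_reference(small_cube, ReferenceMode.GLOBAL_MEAN)
        )
        with pytest.raises(ValueError, match="raw"):
            compute_reference(pr, ReferenceMode.GLOBAL_MEAN)


class TestPseudoReflectance:
    def test_cube_equal_to_reference_gives_ones(self):
        s = np.array([2.0, 4.0, 8.0])
        cube = make_cube(np.tile(s, (3, 3, 1)))
        ref = compute_reference(cube, ReferenceMode.COLUMN_MEAN)
        pr = pseudo_reflectance(cube, ref)
        np.testing.assert_allclose(pr.data, 1.0, rtol=1e-6)
        assert pr.stage == Stage.PSEUDO_REFLECTANCE

    def test_double_reference_gives_flat_two(self):
        s = np.array([2.0, 4.0, 8.0])
        cube = make_cube(np.tile(s, (3, 3, 1)))
        ref = compute_reference(cube, ReferenceMode.GLOBAL_MEAN)
        doubled = cube.with_data(cube.data * 2.0)
        np.testing.assert_allclose(pseudo_reflectance(doubled, ref).data, 2.0, rtol=1e-6)

    def test_matches_elementwise_division_oracle(self, rng):
        data = rng.uniform(1.0, 50.0, size=(4, 4, 5))
        cube = make_cube(data)
        ref = compute_reference(cube, ReferenceMode.COLUMN_MEAN)
        pr = pseudo_reflectance(cube, ref)
        for l, s in [(0, 0), (2, 3), (3, 1)]:
            oracle = data[l, s] / data[:, s].mean(axis=0)
            np.testing.assert_allclose(pr.data[l, s], oracle, rtol=1e-5)

    def test_global_mean_normalization_conservation(self, rng):
        """Dividing by the global mean leaves a per-band global mean of 1."""
        cube = make_cube(rng.uniform(5.0, 80.0, size=(6, 7, 5)))
        pr = pseudo_reflectance(cube, compute_reference(cube, ReferenceMode.GLOBAL_MEAN))
        band_means = pr.data.reshape(-1, 5).astype(np.float64).mean(axis=0)
        np.testing.assert_allclose(band_means, 1.0, atol=1e-6)

    def test_illumination_removed_for_uniform_material(self):
        """A purely multiplicative cross-track illumination field over a
        uniform material divides out exactly under a column reference."""
        s = np.array([10.0, 20.0, 30.0])
        illum = np.array([0.6, 0.8, 1.0, 0.8])
        data = s[np.newaxis, np.newaxis, :] * illum[np.newaxis, :, np.newaxis] * np.ones((5, 1, 1))
        cube = make_cube(data)
        for mode in (ReferenceMode.COLUMN_MEAN, ReferenceMode.COLUMN_MEDIAN):
            pr = pseudo_reflectance(cube, compute_reference(cube, mode))
            np.testing.assert_allclose(pr.data, 1.0, rtol=1e-6)


class TestSmoothing:
    def test_constant_spectrum_unchanged(self):
        cube = make_cube(np.full((2, 2, 15), 4.0))
        np.testing.assert_allclose(smooth_spectra(cube, 11).data, 4.0, rtol=1e-6)

    def test_impulse_spreads_to_window(self):
        data = np.zeros((1, 1, 31))
        data[0, 0, 15] = 1.0
        sm = smooth_spectra(make_cube(data), 11).data[0, 0]
        np.testing.assert_allclose(sm[10:21], 1.0 / 11.0, atol=1e-7)
        np.testing.assert_allclose(sm[:10], 0.0, atol=1e-7)
        np.testing.assert_allclose(sm[21:], 0.0, atol=1e-7)

    def test_linear_ramp_interior_unchanged(self):
        ramp = np.arange(21, dtype=float)
        cube = make_cube(np.tile(ramp, (1, 1, 1)))
        sm = smooth_spectra(cube, 5).data[0, 0]
        np.testing.assert_allclose(sm[2:-2], ramp[2:-2], atol=1e-6)

    def test_band_count_preserved(self, small_cube):
        assert smooth_spectra(small_cube, 5).n_bands == small_cube.n_bands

    def test_commutes_with_scalar_multiplication(self, small_cube):
        a = smooth_spectra(small_cube.with_data(small_cube.data * 3.0), 5).data
        b = smooth_spectra(small_cube, 5).data * 3.0
        np.testing.assert_allclose(a, b, rtol=1e-5)

    @pytest.mark.parametrize("window", [2, 4, 100])
    def test_bad_window_rejected(self, small_cube, window):
        with pytest.raises(ValueError):
            smooth_spectra(small_cube, window)

    def test_shrink_edge_mode_averages_partial_window(self):
        X = np.arange(5.0)[np.newaxis, :]
        out = MovingAverageSmoother(window=3, edge_mode="shrink").fit_transform(X)[0]
        assert out[0] == pytest.approx((0 + 1) / 2)
        assert out[2] == pytest.approx(2.0)


class TestFullChain:
    def test_chain_preserves_nonnegativity_and_stages(self, default_scene):
        cube, _ = default_scene
        out = preprocess_cube(cube, PreprocessConfig())
        assert out.stage == Stage.SMOOTHED
        assert out.n_bands == 83
        assert (out.data >= 0).all()
        assert np.isfinite(out.data).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(smooth_window_bands=4)
        with pytest.raises(ValueError):
            PreprocessConfig(subset_min_nm=700, subset_max_nm=400)
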