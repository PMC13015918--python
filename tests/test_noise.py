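"""Noise-covariance estimators: adjacent differencing and the spatially
invariant silent-region model."""

import numpy as np
import pytest

from imnf import (
    NoiseCovariance,
    SpectralCube,
    estimate_noise_adjacent,
    estimate_noise_imnf,
    noise_profile,
    offdiag_noise_correlation,
    qc_spike_check,
    reference_transmittance,
    select_silent_window,
    sg_base_variance,
    sg_variance_gain,
    shuffle_cube,
    silent_region,
    to_transmittance,
)
from tests.conftest import unit_axis_cube


class TestAdjacentEstimator:
    def test_identical_spectra_give_zero_covariance(self):
        cube = unit_axis_cube(np.ones((4, 3)))
        noise = estimate_noise_adjacent(cube)
        np.testing.assert_array_equal(noise.matrix, np.zeros((3, 3)))

    def test_hand_computed_cross_product(self):
        # N = [[-1, -2]]  →  NᵀN = [[1, 2], [2, 4]]
        cube = unit_axis_cube(np.array([[0.0, 0.0], [1.0, 2.0]]))
        noise = estimate_noise_adjacent(cube)
        np.testing.assert_array_equal(noise.matrix, [[1.0, 2.0], [2.0, 4.0]])
        assert noise.kind == "dense"
        assert noise.provenance == "adjacent"

    def test_order_dependence_under_shuffling(self, qcl_phantom):
        cube = qcl_phantom.noisy
        shuffled, _ = shuffle_cube(cube, seed=9)
        a = estimate_noise_adjacent(cube).matrix
        b = estimate_noise_adjacent(shuffled).matrix
        # the documented flaw: the estimate depends on row order
        assert np.abs(a - b).max() > 1e3 * np.abs(a).max() * 1e-10
        assert not np.allclose(a, b, rtol=1e-3)

    def test_drop_row_boundary_pairs(self):
        # 2×2 image: pair (index 1, index 2) spans the row boundary
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        cube = SpectralCube(X, np.array([1000.0]), shape2d=(2, 2))
        full = estimate_noise_adjacent(cube).matrix
        dropped = estimate_noise_adjacent(cube, drop_row_boundaries=True).matrix
        np.testing.assert_allclose(full, [[1.0 + 81.0 + 1.0]])
        np.testing.assert_allclose(dropped, [[1.0 + 1.0]])

    def test_requires_two_spectra(self):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_noise_adjacent(unit_axis_cube(np.ones((1, 3))))


class TestSGBaseVariance:
    def test_constant_region_gives_zero(self):
        cube = unit_axis_cube(np.full((10, 20), 3.7))
        region = silent_region(cube, 2, 17)
        assert sg_base_variance(cube, region) == 0.0

    def test_linear_ramp_gives_zero(self):
        # SG is exact on polynomials: first derivative of a line is
        # constant, so its column variance vanishes
        cube = unit_axis_cube(np.tile(0.3 * np.arange(20.0), (8, 1)))
        region = silent_region(cube, 2, 17)
        assert sg_base_variance(cube, region) < 1e-12

    def test_white_noise_gain_matches_filter_coefficients(self):
        # closed-form oracle: w5/p2 first-derivative coefficients are
        # [-2,-1,0,1,2]/10, so Σc² = 0.1 and iid σ² noise → 0.1 σ²
        rng = np.random.default_rng(42)
        sigma2 = 0.09
        cube = unit_axis_cube(rng.normal(0, np.sqrt(sigma2), size=(10_000, 40)))
        region = silent_region(cube, 0, 39)
        est = sg_base_variance(cube, region, window=5, polyorder=2)
        assert est == pytest.approx(0.1 * sigma2, rel=0.05)

    def test_variance_gain_closed_form(self):
        assert sg_variance_gain(5, 2, delta=1.0) == pytest.approx(0.1, abs=1e-12)
        # doubling the spacing quarters the derivative variance
        assert sg_variance_gain(5, 2, delta=2.0) == pytest.approx(0.025, abs=1e-12)

    def test_parameter_validation(self):
        cube = unit_axis_cube(np.ones((5, 20)))
        region = silent_region(cube, 2, 17)
        with pytest.raises(ValueError, match="odd"):
            sg_base_variance(cube, region, window=4)
        with pytest.raises(ValueError, match="too small"):
            sg_base_variance(cube, region, window=5, polyorder=4)
        short = silent_region(cube, 2, 5)
        with pytest.raises(ValueError, match="need more than window"):
            sg_base_variance(cube, short, window=5)


class TestTransmittance:
    def test_beer_lambert_values(self):
        np.testing.assert_allclose(
            to_transmittance(np.array([0.0, 1.0, 2.0])), [1.0, 0.1, 0.01]
        )

    def test_clamp_at_saturation(self):
        assert to_transmittance(np.array([9.0]))[0] == 1e-6

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            to_transmittance(np.array([np.nan]))

    def test_reference_is_region_mean(self):
        cube = unit_axis_cube(np.ones((2, 4)))
        region = silent_region(cube, 0, 1)
        assert reference_transmittance(np.array([0.8, 1.0, 5.0, 5.0]), region) == (
            pytest.approx(0.9)
        )
        full = silent_region(cube, 0, 3)
        T = np.array([1.0, 2.0, 3.0, 4.0])
        assert reference_transmittance(T, full) == pytest.approx(T.mean())


class TestNoiseProfile:
    def test_uniform_transmittance_gives_flat_profile(self):
        prof = noise_profile(0.5, np.full(4, 0.9), 0.9)
        np.testing.assert_allclose(prof, 0.5)

    def test_inverse_square_law(self):
        # T̄_ref = 1, T̄ = 0.1 at one band → variance amplified 100×
        prof = noise_profile(2.0, np.array([1.0, 0.1]), 1.0)
        np.testing.assert_allclose(prof, [2.0, 200.0])

    def test_linear_in_base_variance(self):
        T = np.array([1.0, 0.5, 0.25])
        np.testing.assert_allclose(
            noise_profile(2.0, T, 1.0), 2 * noise_profile(1.0, T, 1.0)
        )

    def test_floor_keeps_profile_invertible(self):
        prof = noise_profile(0.0, np.ones(3), 1.0)
        assert np.all(prof == 1e-12)

    def test_rejects_nonpositive_transmittance(self):
        with pytest.raises(ValueError, match="positive"):
            noise_profile(1.0, np.array([1.0, 0.0]), 1.0)


class TestIMNFEstimator:
    def test_permutation_invariance(self, qcl_phantom):
        cube = qcl_phantom.noisy
        shuffled, _ = shuffle_cube(cube, seed=21)
        p1 = estimate_noise_imnf(cube).profile
        p2 = estimate_noise_imnf(shuffled).profile
        assert np.abs(p1 / p2 - 1).max() < 1e-10

    def test_flat_cube_with_white_noise_gives_uniform_profile(self, rng):
        # zero absorbance everywhere → T̄ ≈ 1 at every band → S ≈ 1
        cube = unit_axis_cube(rng.normal(0, 0.01, size=(5000, 60)))
        noise = estimate_noise_imnf(cube, silent_region(cube, 10, 49))
        spread = noise.profile.max() / noise.profile.min()
        assert spread < 1.05

    def test_profile_peaks_at_the_strongest_band(self, qcl_phantom):
        cube = qcl_phantom.noisy
        noise = estimate_noise_imnf(cube)
        peak_band = int(np.argmax(noise.profile))
        amide_band = cube.band_index(1656.0)
        # strongest absorbance (smallest T̄) carries the largest variance
        assert abs(cube.axis[peak_band] - cube.axis[amide_band]) < 20.0

    def test_base_variance_on_physical_scale(self, qcl_phantom):
        # delta-method parameter recovery: in the silent region the clean
        # absorbance is ~0 (T̄≈1), so the absorbance-noise variance is
        # (σ_T / ln 10)²
        noise = estimate_noise_imnf(qcl_phantom.noisy)
        sigma_t = qcl_phantom.spec.sigma_t
        predicted = (sigma_t / np.log(10)) ** 2
        assert noise.base_variance == pytest.approx(predicted, rel=0.2)

    def test_profile_matches_delta_method_prediction(self, qcl_phantom_large):
        cube = qcl_phantom_large.noisy  # 4096 spectra
        noise = estimate_noise_imnf(cube)
        T = noise.transmittance.mean_transmittance
        predicted = (qcl_phantom_large.spec.sigma_t / (T * np.log(10))) ** 2
        rel = np.abs(noise.profile / predicted - 1)
        assert np.median(rel) < 0.2

    def test_auto_region_selection(self, qcl_phantom):
        noise = estimate_noise_imnf(qcl_phantom.noisy, region="auto")
        assert noise.region.auto_selected
        assert noise.region.lo >= 1750.0 and noise.region.hi <= 1800.0


class TestSilentWindowSelection:
    def test_matches_exhaustive_search(self, qcl_phantom):
        cube = qcl_phantom.noisy
        width = 30.0
        chosen = select_silent_window(cube, 1700.0, 1800.0, width=width)
        # brute-force oracle over every candidate start
        from imnf.noise import _band_derivative_variances

        cand = np.flatnonzero((cube.axis >= 1700.0) & (cube.axis <= 1800.0))
        variances = _band_derivative_variances(cube, cand, 5, 2)
        n = int(round(width / 2.0)) + 1
        means = [variances[i : i + n].mean() for i in range(cand.size - n + 1)]
        pos = int(np.flatnonzero(cand == chosen.indices[0])[0])
        assert len(chosen) == n
        assert means[pos] == pytest.approx(min(means), rel=1e-12)

    def test_avoids_contaminated_bands(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 0.01, size=(500, 100))
        # contaminate the first half of the candidate interval
        X[:, 10:40] += rng.normal(0, 0.2, size=(500, 30))
        cube = unit_axis_cube(X)
        region = select_silent_window(cube, 5.0, 95.0, width=20.0)
        assert region.indices[0] > 40
        assert region.auto_selected

    def test_full_width_returns_whole_interval(self, qcl_phantom):
        cube = qcl_phantom.noisy
        region = select_silent_window(cube, 1750.0, 1800.0, width=50.0)
        assert region.lo == 1750.0 and region.hi == 1800.0

    def test_interval_outside_axis(self, qcl_phantom):
        with pytest.raises(ValueError, match="outside the axis"):
            select_silent_window(qcl_phantom.noisy, 3000.0, 3100.0)


class TestQCSpikeCheck:
    def test_clean_white_noise_has_no_flags(self, rng):
        cube = unit_axis_cube(rng.normal(0, 0.01, size=(2000, 30)))
        report = qc_spike_check(cube, silent_region(cube, 0, 29))
        assert report.clean

    def test_single_band_contaminant_is_flagged(self, rng):
        X = rng.normal(0, 0.01, size=(2000, 30))
        # narrow-band sinusoidal contaminant at 10× the noise amplitude
        X[:, 15] += 0.1 * np.sin(np.linspace(0, 40 * np.pi, 2000))
        cube = unit_axis_cube(X)
        report = qc_spike_check(cube, silent_region(cube, 0, 29))
        assert 15 in report.flagged_indices

    def test_clean_report_leaves_estimation_unchanged(self, qcl_phantom):
        cube = qcl_phantom.noisy
        noise = estimate_noise_imnf(cube)
        assert noise.region.qc.clean
        # the QC step is report-only: profile comes out the same either way
        region = silent_region(cube, noise.region.lo, noise.region.hi)
        again = estimate_noise_imnf(cube, region)
        np.testing.assert_array_equal(noise.profile, again.profile)


class TestOffDiagonalCorrelation:
    def test_identity_covariance(self):
        assert offdiag_noise_correlation(
            NoiseCovariance.from_matrix(np.eye(3))
        ) == 0.0

    def test_hand_computed_two_band_case(self):
        noise = NoiseCovariance.from_matrix(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert offdiag_noise_correlation(noise) == pytest.approx(0.5)

    def test_perfectly_correlated_noise(self):
        v = np.array([1.0, 2.0, -1.0])
        noise = NoiseCovariance.from_matrix(np.outer(v, v) + 1e-12 * np.eye(3))
        assert offdiag_noise_correlation(noise) == pytest.approx(1.0, abs=1e-6)

    def test_diagonal_kind_warns_and_returns_zero(self):
        noise = NoiseCovariance.identity(4)
        with pytest.warns(RuntimeWarning, match="diagonal"):
            assert offdiag_noise_correlation(noise) == 0.0
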