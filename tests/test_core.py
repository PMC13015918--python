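"""MNF transform: whitening, eigensystem, truncation, reconstruction."""

import numpy as np
import pytest

from imnf import (
    NoiseCovariance,
    SpectralCube,
    denoise,
    factor_images,
    fit_mnf,
    make_phantom,
    pca_denoise,
    qcl_spec,
    whiten,
)
from tests.conftest import unit_axis_cube


class TestWhiten:
    def test_identity_covariance_is_noop(self, toy_cube):
        W = whiten(toy_cube, NoiseCovariance.identity(toy_cube.n_bands))
        np.testing.assert_array_equal(W, toy_cube.spectra)

    def test_uniform_variance_scales_by_inverse_sigma(self):
        cube = unit_axis_cube(np.ones((3, 4)))
        W = whiten(cube, NoiseCovariance.identity(4, scale=4.0))
        np.testing.assert_allclose(W, 0.5)

    def test_dense_whitening_normalises_the_covariance(self):
        # brute-force oracle: the whitening transform A = V Λ^{-1/2} must
        # satisfy Aᵀ Σ A = I for a hand-built SPD 4×4 covariance
        sigma = np.array(
            [
                [4.0, 1.0, 0.5, 0.0],
                [1.0, 3.0, 0.2, 0.1],
                [0.5, 0.2, 2.0, 0.3],
                [0.0, 0.1, 0.3, 1.0],
            ]
        )
        lam, V = np.linalg.eigh(sigma)  # independent eigendecomposition
        noise = NoiseCovariance.from_matrix(sigma)
        # whitening the identity "cube" returns the transform itself
        A = whiten(unit_axis_cube(np.eye(4)), noise)
        np.testing.assert_allclose(A.T @ sigma @ A, np.eye(4), atol=1e-10)
        # and it spans the same scaling as the oracle eigensystem
        np.testing.assert_allclose(
            np.sort(np.linalg.svd(A, compute_uv=False)),
            np.sort(1.0 / np.sqrt(lam)),
            atol=1e-10,
        )

    def test_nonpositive_diagonal_names_band(self, toy_cube):
        with pytest.raises(ValueError, match="band index 2"):
            NoiseCovariance.from_profile(np.array([1.0, 1.0, 0.0, 1.0, 1.0]))
        noise = NoiseCovariance.identity(5)
        noise.profile[2] = -1.0  # corrupt after validation
        with pytest.raises(ValueError, match="band index 2"):
            whiten(toy_cube, noise)

    def test_non_positive_definite_dense_rejected(self, toy_cube):
        mat = -np.eye(5)
        noise = NoiseCovariance.from_matrix(mat)
        with pytest.raises(ValueError, match="positive definite"):
            whiten(toy_cube, noise)

    def test_dimension_mismatch(self, toy_cube):
        with pytest.raises(ValueError, match="does not match"):
            whiten(toy_cube, NoiseCovariance.identity(7))


class TestFitMNF:
    def test_rank1_signal_recovered_with_one_band(self, rng):
        u = rng.normal(size=20)
        w = rng.normal(size=8)
        cube = unit_axis_cube(np.outer(u, w))
        model = fit_mnf(cube, NoiseCovariance.identity(8), k=1)
        # one dominant SNR eigenvalue, the rest numerically zero
        assert model.signal_eigvals[0] > 1e6 * abs(model.signal_eigvals[1])
        result = denoise(cube, model)
        np.testing.assert_allclose(result.cube.spectra, cube.spectra, atol=1e-8)

    @pytest.mark.parametrize("kind", ["diagonal", "dense"])
    def test_full_rank_reconstruction_is_identity(self, toy_cube, rng, kind):
        if kind == "diagonal":
            noise = NoiseCovariance.from_profile(rng.uniform(0.5, 2.0, 5))
        else:
            A = rng.normal(size=(12, 5))
            noise = NoiseCovariance.from_matrix(A.T @ A + 0.1 * np.eye(5))
        model = fit_mnf(toy_cube, noise, k=5)
        np.testing.assert_allclose(
            model.forward @ model.reconstruction, np.eye(5), atol=1e-8
        )
        out = denoise(toy_cube, model).cube.spectra
        assert np.abs(out - toy_cube.spectra).max() < 1e-8

    def test_white_noise_mnf_matches_truncated_svd_basis(self, rng):
        X = rng.normal(size=(200, 12))
        model = fit_mnf(unit_axis_cube(X), NoiseCovariance.identity(12), k=4)
        # truncated-SVD oracle: compare the rank-4 projectors (sign-free)
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        P_svd = Vt[:4].T @ Vt[:4]
        P_mnf = model.forward @ model.reconstruction
        np.testing.assert_allclose(P_mnf, P_svd, atol=1e-8)

    def test_svd_and_eig_paths_agree(self, qcl_phantom):
        cube = qcl_phantom.noisy
        noise = NoiseCovariance.identity(cube.n_bands)
        m_svd = fit_mnf(cube, noise, k=10, method="svd")
        m_eig = fit_mnf(cube, noise, k=10, method="eig")
        np.testing.assert_allclose(
            m_svd.projector(), m_eig.projector(), atol=1e-7
        )

    def test_signal_eigenvalues_nonincreasing(self, qcl_phantom):
        from imnf import estimate_noise_imnf

        cube = qcl_phantom.noisy
        model = fit_mnf(cube, estimate_noise_imnf(cube), k=30)
        assert np.all(np.diff(model.signal_eigvals) <= 1e-9 * model.signal_eigvals[0])

    def test_sign_convention_deterministic(self, toy_cube):
        noise = NoiseCovariance.identity(5)
        G1 = fit_mnf(toy_cube, noise, k=5).signal_eigvecs
        G2 = fit_mnf(toy_cube, noise, k=5).signal_eigvecs
        np.testing.assert_array_equal(G1, G2)
        idx = np.argmax(np.abs(G1), axis=0)
        assert np.all(G1[idx, np.arange(5)] > 0)

    def test_parameter_validation(self, toy_cube):
        noise = NoiseCovariance.identity(5)
        with pytest.raises(ValueError, match="out of range"):
            fit_mnf(toy_cube, noise, k=0)
        with pytest.raises(ValueError, match="out of range"):
            fit_mnf(toy_cube, noise, k=6)
        single = SpectralCube(np.ones((1, 5)), np.arange(5.0))
        with pytest.raises(ValueError, match="at least 2"):
            fit_mnf(single, noise, k=1)


class TestDenoise:
    def test_scalar_noise_scaling_leaves_output_unchanged(self, qcl_phantom):
        from imnf import estimate_noise_imnf

        cube = qcl_phantom.noisy
        noise = estimate_noise_imnf(cube)
        d1 = denoise(cube, fit_mnf(cube, noise, k=30)).cube.spectra
        d2 = denoise(cube, fit_mnf(cube, noise.scaled(37.0), k=30)).cube.spectra
        assert np.abs(d1 - d2).max() < 1e-6

    def test_projection_is_idempotent(self, toy_cube, rng):
        noise = NoiseCovariance.from_profile(rng.uniform(0.5, 2.0, 5))
        model = fit_mnf(toy_cube, noise, k=3)
        once = denoise(toy_cube, model).cube
        twice = denoise(once, model).cube
        # oracle: the explicit projector is idempotent, so a second pass
        # changes nothing in the retained subspace
        P = model.projector()
        np.testing.assert_allclose(P @ P, P, atol=1e-10)
        assert np.abs(twice.spectra - once.spectra).max() < 1e-8

    def test_row_locality_bitwise_under_permutation(self, qcl_phantom, rng):
        cube = qcl_phantom.noisy
        model = fit_mnf(cube, NoiseCovariance.identity(cube.n_bands), k=10)
        d = denoise(cube, model, keep_scores=False).cube.spectra
        perm = rng.permutation(cube.n_spectra)
        permuted = SpectralCube(cube.spectra[perm], cube.axis)
        d_perm = denoise(permuted, model, keep_scores=False).cube.spectra
        np.testing.assert_array_equal(d_perm[np.argsort(perm)], d)

    def test_dimension_mismatch(self, toy_cube):
        other = unit_axis_cube(np.ones((3, 4)))
        model = fit_mnf(toy_cube, NoiseCovariance.identity(5), k=2)
        with pytest.raises(ValueError, match="does not match"):
            denoise(other, model)

    def test_denoising_reduces_silent_region_variance(self, qcl_phantom):
        from imnf import default_silent_region, estimate_noise_imnf, silent_variance

        cube = qcl_phantom.noisy
        model = fit_mnf(cube, estimate_noise_imnf(cube), k=30)
        out = denoise(cube, model).cube
        region = default_silent_region(cube)
        assert silent_variance(out, region) < silent_variance(cube, region)


class TestPCADenoise:
    def test_full_rank_is_identity(self, toy_cube):
        out = pca_denoise(toy_cube, k=5).cube.spectra
        np.testing.assert_allclose(out, toy_cube.spectra, atol=1e-8)

    def test_exact_on_low_rank_input(self, rng):
        A = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 9))
        cube = unit_axis_cube(A)
        out = pca_denoise(cube, k=2).cube.spectra
        np.testing.assert_allclose(out, A, atol=1e-8)

    @pytest.mark.parametrize("k", [1, 5, 30])
    def test_equals_mnf_under_white_noise(self, qcl_phantom, k):
        cube = qcl_phantom.noisy
        noise = NoiseCovariance.identity(cube.n_bands, scale=0.7)
        d_mnf = denoise(cube, fit_mnf(cube, noise, k=k)).cube.spectra
        d_pca = pca_denoise(cube, k=k).cube.spectra
        assert np.abs(d_mnf - d_pca).max() < 1e-6

    def test_k_out_of_range(self, toy_cube):
        with pytest.raises(ValueError, match="out of range"):
            pca_denoise(toy_cube, k=6)


class TestFactorImages:
    def test_shapes_and_bounds(self, qcl_phantom):
        from imnf import estimate_noise_imnf

        cube = qcl_phantom.noisy
        result = denoise(cube, fit_mnf(cube, estimate_noise_imnf(cube), k=3))
        images = factor_images(result, [0, 1, 2])
        assert len(images) == 3
        assert all(im.shape == cube.shape2d for im in images)
        with pytest.raises(IndexError, match="out of range"):
            factor_images(result, [3])

    def test_requires_2d_shape(self, toy_cube):
        result = denoise(toy_cube, fit_mnf(toy_cube, NoiseCovariance.identity(5), k=2))
        with pytest.raises(ValueError, match="2-D shape"):
            factor_images(result, [0])

    def test_first_factor_tracks_the_class_map(self):
        from imnf import estimate_noise_imnf

        # two spatial classes with distinct chemistry → the leading factor
        # image must correlate with the class layout
        spec = qcl_spec(
            shape=(24, 24),
            style="stripes",
            classes={
                "a": [(1656.0, 18.0, 0.2)],
                "b": [(1656.0, 18.0, 0.9), (1546.0, 16.0, 0.5)],
            },
            seed=5,
        )
        from imnf import add_noise

        phantom = add_noise(make_phantom(spec))
        cube = phantom.noisy
        result = denoise(cube, fit_mnf(cube, estimate_noise_imnf(cube), k=3))
        image = factor_images(result, [0])[0]
        r = np.corrcoef(image.ravel(), phantom.labels.ravel())[0, 1]
        assert abs(r) > 0.5
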