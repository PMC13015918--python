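"""The minimum noise fraction (MNF) transform proper.

MNF denoising re-projects hyperspectral data into a component space ordered
by signal-to-noise ratio, truncates the noisy trailing components and
transforms back.  Given a pixel-spectra matrix ``X`` (m spectra × v
wavenumbers) and a noise covariance estimate ``Σ_δ = V Λ_δ Vᵀ`` the steps are

1. noise whitening            ``W = X V Λ_δ^{-1/2}``
2. signal eigendecomposition  ``Wᵀ W = G Λ_ω Gᵀ`` (done via SVD of ``W``)
3. truncation to ``K`` bands  ``Φ_K = V Λ_δ^{-1/2} G_K``
4. reconstruction             ``D = (X Φ_K) · G_Kᵀ Λ_δ^{1/2} Vᵀ``

Because the noise is whitened first, ordering components by variance is
ordering by SNR — unlike PCA, which orders by raw variance.  With white
(scalar-covariance) noise MNF reduces exactly to uncentred PCA denoising.

This module is agnostic to how the noise covariance was estimated; see
:mod:`imnf.noise` for the adjacent-pixel (order-dependent) and spatially
invariant (iMNF) estimators.

Neither decomposition mean-centres the data: the raw cross-products
``NᵀN`` and ``WᵀW`` are used, matching the fast-MNF reference lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from imnf.noise import NoiseCovariance

__all__ = [
    "SpectralCube",
    "MNFModel",
    "DenoisedResult",
    "whiten",
    "fit_mnf",
    "denoise",
    "pca_denoise",
    "factor_images",
    "DEFAULT_BANDS",
]

#: Default number of retained MNF bands for reconstruction.
DEFAULT_BANDS = 30

#: Eigenvalue floor applied to degenerate noise variances (with a warning).
_VARIANCE_FLOOR = 1e-12


@dataclass
class SpectralCube:
    """A hyperspectral cube unrolled to a pixel-spectra matrix.

    Parameters
    ----------
    spectra
        ``(m, v)`` matrix; each row is one pixel's absorbance spectrum.
    axis
        Length-``v`` strictly monotone wavenumber axis in cm⁻¹.
    shape2d
        Optional ``(height, width)`` of the source image; row-major
        unrolling is assumed, so ``height * width == m``.
    mask
        Optional boolean vector of length ``m`` (e.g. a tissue mask).
    """

    spectra: np.ndarray
    axis: np.ndarray
    shape2d: tuple[int, int] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (m, v) matrix")
        if self.axis.ndim != 1 or self.axis.size != self.spectra.shape[1]:
            raise ValueError(
                f"axis length {self.axis.size} does not match "
                f"band count {self.spectra.shape[1]}"
            )
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber axis must be strictly monotone")
        if self.shape2d is not None:
            y, x = self.shape2d
            if y * x != self.spectra.shape[0]:
                raise ValueError(
                    f"shape2d {self.shape2d} incompatible with m={self.spectra.shape[0]}"
                )
            self.shape2d = (int(y), int(x))
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.spectra.shape[0],):
                raise ValueError("mask must be a boolean vector of length m")

    @property
    def n_spectra(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def with_spectra(self, spectra: np.ndarray, axis: np.ndarray | None = None) -> "SpectralCube":
        """Return a copy carrying new spectra (and optionally a new axis)."""
        return SpectralCube(
            spectra=spectra,
            axis=self.axis if axis is None else axis,
            shape2d=self.shape2d,
            mask=self.mask,
        )

    def band_index(self, wavenumber: float) -> int:
        """Index of the band nearest a query wavenumber (no interpolation)."""
        return int(np.argmin(np.abs(self.axis - wavenumber)))

    def image(self, band: int) -> np.ndarray:
        """Reshape one band to the 2-D image; requires ``shape2d``."""
        if self.shape2d is None:
            raise ValueError("cube has no 2-D shape")
        return self.spectra[:, band].reshape(self.shape2d)


@dataclass
class MNFModel:
    """A fitted MNF eigensystem plus the truncated transform matrices.

    ``forward`` maps spectra to the retained component scores
    (``v × k``); ``reconstruction`` maps scores back to spectra
    (``k × v``).  With ``k == v`` their composition is the identity.
    """

    noise_eigvecs: np.ndarray  # V, v×v orthonormal (identity for diagonal noise)
    noise_eigvals: np.ndarray  # Λ_δ diagonal, > 0
    signal_eigvecs: np.ndarray  # G, v×v orthonormal
    signal_eigvals: np.ndarray  # Λ_ω, nonincreasing (SNR ordering)
    k: int
    forward: np.ndarray  # Φ_K, v×k
    reconstruction: np.ndarray  # k×v
    noise_is_diagonal: bool = False
    noise_provenance: str = "user"

    def __post_init__(self) -> None:
        lam = np.asarray(self.signal_eigvals)
        if np.any(np.diff(lam) > 1e-9 * max(1.0, float(lam[0]) if lam.size else 1.0)):
            raise ValueError("signal eigenvalues must be nonincreasing (SNR order)")
        if not (1 <= self.k <= self.forward.shape[0]):
            raise ValueError(f"band count k={self.k} out of range")

    @property
    def n_bands(self) -> int:
        return self.forward.shape[0]

    def projector(self) -> np.ndarray:
        """The explicit ``v × v`` denoising projector ``Φ_K · reconstruction``."""
        return self.forward @ self.reconstruction


@dataclass
class DenoisedResult:
    """Denoised cube plus the model that produced it.

    ``scores`` holds the retained MNF component scores ``M_K`` (m × k)
    when requested; factor images are cut from these.
    """

    cube: SpectralCube
    model: MNFModel | None
    scores: np.ndarray | None = None


def _sign_fix(G: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Eigenvectors are defined up to sign; fixing the sign makes factor
    images and regression tests reproducible across LAPACK builds.
    """
    idx = np.argmax(np.abs(G), axis=0)
    signs = np.sign(G[idx, np.arange(G.shape[1])])
    signs[signs == 0] = 1.0
    return G * signs


def _noise_eigensystem(noise: "NoiseCovariance", floor: bool):
    """Return ``(V, lam, diagonal)`` for a noise covariance.

    For diagonal noise ``V`` is None (implicitly the identity) and ``lam``
    is the variance profile.  With ``floor=True`` degenerate (nonpositive)
    variances are raised to a tiny floor with a warning instead of erroring.
    """
    if noise.kind == "diagonal":
        lam = np.asarray(noise.profile, dtype=float).copy()
        bad = np.flatnonzero(~(lam > 0))
        if bad.size:
            if not floor:
                raise ValueError(
                    f"noise variance is nonpositive at band index {bad[0]}"
                )
            warnings.warn(
                f"{bad.size} degenerate noise variance(s); flooring at {_VARIANCE_FLOOR}",
                RuntimeWarning,
                stacklevel=3,
            )
            lam[bad] = _VARIANCE_FLOOR
        return None, lam, True
    mat = np.asarray(noise.matrix, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("dense noise covariance must be symmetric")
    lam, V = np.linalg.eigh((mat + mat.T) / 2.0)
    bad = np.flatnonzero(~(lam > 0))
    if bad.size:
        if not floor:
            raise ValueError(
                "dense noise covariance is not positive definite "
                f"(eigenvalue index {bad[0]} is {lam[bad[0]]:.3e})"
            )
        warnings.warn(
            f"{bad.size} degenerate noise eigenvalue(s); flooring at {_VARIANCE_FLOOR}",
            RuntimeWarning,
            stacklevel=3,
        )
        lam = np.maximum(lam, _VARIANCE_FLOOR)
    V = _sign_fix(V)
    return V, lam, False


def whiten(cube: SpectralCube, noise: "NoiseCovariance") -> np.ndarray:
    """Noise-whiten a cube: ``W = X V Λ_δ^{-1/2}``.

    After whitening, the noise component has unit variance in every band
    and is decorrelated.  For a diagonal noise model this is simply a
    column-wise division by the per-band noise standard deviation.

    Raises on singular / non-positive noise covariances, naming the
    offending band (diagonal) or eigenvalue (dense) index.
    """
    _check_noise_dim(cube, noise)
    V, lam, diagonal = _noise_eigensystem(noise, floor=False)
    X = cube.spectra
    if diagonal:
        return X / np.sqrt(lam)
    return X @ (V / np.sqrt(lam))


def _check_noise_dim(cube: SpectralCube, noise: "NoiseCovariance") -> None:
    if noise.dim != cube.n_bands:
        raise ValueError(
            f"noise covariance dimension {noise.dim} does not match "
            f"cube band count {cube.n_bands}"
        )


def fit_mnf(
    cube: SpectralCube,
    noise: "NoiseCovariance",
    k: int = DEFAULT_BANDS,
    method: str = "svd",
) -> MNFModel:
    """Fit the MNF eigensystem: whiten, decompose, truncate to ``k`` bands.

    Parameters
    ----------
    cube
        Input spectra (m ≥ 2).
    noise
        Noise covariance (dense or diagonal); see :mod:`imnf.noise`.
    k
        Number of retained components, ``1 ≤ k ≤ v``.  Default 30.
    method
        ``"svd"`` (default) decomposes the whitened matrix ``W`` by
        singular value decomposition for numerical stability;
        ``"eig"`` eigendecomposes ``WᵀW`` directly and is kept as a
        cross-check path.

    Notes
    -----
    Ties in the signal eigenvalues preserve the decomposition's output
    order; ordering between components separated by less than ~1e-12
    is not guaranteed reproducible.
    """
    m, v = cube.spectra.shape
    if m < 2:
        raise ValueError("need at least 2 spectra to fit an MNF model")
    if not (1 <= k <= v):
        raise ValueError(f"band count k={k} out of range [1, {v}]")
    _check_noise_dim(cube, noise)

    V, lam, diagonal = _noise_eigensystem(noise, floor=True)
    inv_sqrt = 1.0 / np.sqrt(lam)
    X = cube.spectra
    W = X * inv_sqrt if diagonal else X @ (V * inv_sqrt)

    if method == "svd":
        if m >= v:
            _, s, Gt = np.linalg.svd(W, full_matrices=False)
        else:
            _, s, Gt = np.linalg.svd(W, full_matrices=True)
        G = Gt.T
        sig = np.zeros(v)
        sig[: s.size] = s**2
    elif method == "eig":
        w_eig, G = np.linalg.eigh(W.T @ W)
        order = np.argsort(w_eig)[::-1]
        sig = np.clip(w_eig[order], 0.0, None)
        G = G[:, order]
    else:
        raise ValueError(f"unknown method {method!r}")

    G = _sign_fix(G)
    Gk = G[:, :k]
    if diagonal:
        forward = Gk * inv_sqrt[:, None]
        reconstruction = Gk.T * np.sqrt(lam)[None, :]
        V_store = np.eye(v)
    else:
        whiten_t = V * inv_sqrt  # V Λ^{-1/2}
        forward = whiten_t @ Gk
        reconstruction = Gk.T @ (np.sqrt(lam)[:, None] * V.T)
        V_store = V
    # C-contiguity so a serialisation round-trip reproduces the matmul bitwise
    forward = np.ascontiguousarray(forward)
    reconstruction = np.ascontiguousarray(reconstruction)

    return MNFModel(
        noise_eigvecs=V_store,
        noise_eigvals=lam,
        signal_eigvecs=G,
        signal_eigvals=sig,
        k=int(k),
        forward=forward,
        reconstruction=reconstruction,
        noise_is_diagonal=diagonal,
        noise_provenance=getattr(noise, "provenance", "user"),
    )


def _apply_rowwise(X: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Row-local matrix product ``X @ A``.

    Computed as a batched per-row product so that each output row is a
    pure function of its input row alone — bitwise, not just
    numerically.  Blocked BLAS gemm does not guarantee this, and the
    patch-wise and streaming engines rely on exact row locality.
    """
    return (X[:, None, :] @ A).reshape(X.shape[0], A.shape[1])


def denoise(
    cube: SpectralCube, model: MNFModel, keep_scores: bool = True
) -> DenoisedResult:
    """Apply a fitted MNF model: ``D = (X Φ_K) · reconstruction``.

    Row ``i`` of the output depends only on row ``i`` of the input
    (bitwise), so the same model may be applied patch-by-patch, row-by-row
    or to permuted data and recomposed exactly.
    """
    if cube.n_bands != model.n_bands:
        raise ValueError(
            f"model dimension {model.n_bands} does not match cube "
            f"band count {cube.n_bands}"
        )
    scores = _apply_rowwise(cube.spectra, model.forward)
    D = _apply_rowwise(scores, model.reconstruction)
    return DenoisedResult(
        cube=cube.with_spectra(D),
        model=model,
        scores=scores if keep_scores else None,
    )


def pca_denoise(cube: SpectralCube, k: int) -> DenoisedResult:
    """Uncentred truncated-SVD (PCA) reconstruction with ``k`` components.

    This matches the MNF formulation here (no mean-centring) and is the
    exact limit of MNF under white noise (``Σ_δ ∝ I``); it serves as the
    independent oracle for that equivalence.
    """
    m, v = cube.spectra.shape
    if not (1 <= k <= v):
        raise ValueError(f"band count k={k} out of range [1, {v}]")
    U, s, Vt = np.linalg.svd(cube.spectra, full_matrices=False)
    D = (U[:, :k] * s[:k]) @ Vt[:k]
    scores = U[:, :k] * s[:k]
    return DenoisedResult(cube=cube.with_spectra(D), model=None, scores=scores)


def factor_images(result: DenoisedResult, indices: Sequence[int]) -> list[np.ndarray]:
    """Reshape selected MNF score columns to 2-D factor images.

    Factors are ordered by SNR; early factors should carry the coherent
    morphology of the sample and late ones mostly noise, so inspecting
    them is a standard qualitative check of the decomposition.
    """
    if result.cube.shape2d is None:
        raise ValueError("cube has no 2-D shape; factor images undefined")
    if result.scores is None:
        raise ValueError("result does not retain component scores")
    kmax = result.scores.shape[1]
    images = []
    for i in indices:
        if not (0 <= i < kmax):
            raise IndexError(f"factor index {i} out of range [0, {kmax})")
        images.append(result.scores[:, i].reshape(result.cube.shape2d))
    return images
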