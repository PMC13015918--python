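"""Noise-covariance estimation for MNF denoising.

Two estimators are provided:

* :func:`estimate_noise_adjacent` — the standard (fast-MNF) estimator.
  The noise matrix is the difference between spectra of adjacent pixels,
  ``N_i = X_i − X_{i+1}``, and ``Σ_δ = NᵀN``.  It captures inter-band
  noise correlation but is strongly *order-dependent*: shuffling,
  masking or patching the data breaks the adjacency assumption and the
  estimate with it.

* :func:`estimate_noise_imnf` — the spatially invariant estimator
  (iMNF).  A single base noise variance is read off a biologically
  *silent* spectral window (no expected tissue absorbance) via the
  variance of a Savitzky–Golay first derivative, then scaled across the
  axis by the inverse square of the mean transmittance,

      σ²_profile(ν) = σ²_base · (T̄_ref / T̄(ν))²,   T̄ = 10^(−Ā),

  reflecting that noise which is roughly constant in transmittance is
  amplified in absorbance where transmittance is small (strong bands).
  The resulting covariance is the *diagonal* matrix diag(σ²_profile):
  off-diagonal noise correlations are deliberately ignored — that
  trade-off is precisely what makes the estimate depend only on global
  column statistics and hence be invariant to pixel order.

Also here: the automated silent-window selection heuristic, the
narrow-band contaminant QC check, and the off-diagonal correlation
summary used to quantify how correlated the detector noise really is.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from imnf.core import SpectralCube

__all__ = [
    "NoiseCovariance",
    "SilentRegion",
    "TransmittanceProfile",
    "QCReport",
    "DEFAULT_SILENT_REGIONS",
    "silent_region",
    "default_silent_region",
    "estimate_noise_adjacent",
    "sg_base_variance",
    "sg_variance_gain",
    "to_transmittance",
    "reference_transmittance",
    "noise_profile",
    "estimate_noise_imnf",
    "select_silent_window",
    "qc_spike_check",
    "offdiag_noise_correlation",
]

#: Default biologically silent windows (cm⁻¹) per modality.
DEFAULT_SILENT_REGIONS = {"qcl": (1750.0, 1800.0), "ftir": (1750.0, 2200.0)}

#: Transmittance clamp — keeps ``10**(−A)`` away from zero at saturated bands.
TRANSMITTANCE_EPS = 1e-6

#: Floor on profile variances so the diagonal covariance stays invertible.
PROFILE_FLOOR = 1e-12


@dataclass
class QCReport:
    """Narrow-band contaminant check over a silent region."""

    flagged_wavenumbers: np.ndarray
    flagged_indices: np.ndarray
    band_variances: np.ndarray
    median_variance: float
    factor: float

    @property
    def clean(self) -> bool:
        return self.flagged_indices.size == 0


@dataclass
class SilentRegion:
    """A contiguous wavenumber interval assumed free of tissue absorbance."""

    lo: float
    hi: float
    indices: np.ndarray
    qc: QCReport | None = None
    auto_selected: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"silent region requires lo < hi, got [{self.lo}, {self.hi}]")
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError("silent region selects no bands")
        if np.any(np.diff(self.indices) != 1):
            raise ValueError("silent-region indices must be contiguous along the axis")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class TransmittanceProfile:
    """Mean transmittance spectrum and the inverse-square scaling built from it."""

    mean_absorbance: np.ndarray
    mean_transmittance: np.ndarray
    reference: float
    scaling: np.ndarray


@dataclass
class NoiseCovariance:
    """Noise covariance ``Σ_δ`` — dense matrix or diagonal variance profile.

    ``provenance`` records which estimator produced it (``adjacent``,
    ``imnf`` or ``user``); a patch-wise run asserts the same object (by
    content hash) is used for every patch.
    """

    kind: str  # "dense" | "diagonal"
    matrix: np.ndarray | None = None
    profile: np.ndarray | None = None
    base_variance: float = 0.0
    provenance: str = "user"
    region: SilentRegion | None = None
    transmittance: TransmittanceProfile | None = None

    def __post_init__(self) -> None:
        if self.kind == "dense":
            if self.matrix is None:
                raise ValueError("dense noise covariance requires a matrix")
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
                raise ValueError("noise covariance matrix must be square")
            if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
                raise ValueError("noise covariance matrix must be symmetric")
        elif self.kind == "diagonal":
            if self.profile is None:
                raise ValueError("diagonal noise covariance requires a profile")
            self.profile = np.asarray(self.profile, dtype=float)
            bad = np.flatnonzero(~(self.profile > 0))
            if bad.size:
                raise ValueError(
                    f"diagonal noise profile must be positive; band index {bad[0]} "
                    f"is {self.profile[bad[0]]:.3e}"
                )
        else:
            raise ValueError(f"unknown noise covariance kind {self.kind!r}")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0] if self.kind == "dense" else self.profile.size

    @classmethod
    def identity(cls, v: int, scale: float = 1.0) -> "NoiseCovariance":
        """White-noise model with variance ``scale`` in every band."""
        return cls(kind="diagonal", profile=np.full(v, float(scale)), provenance="user")

    @classmethod
    def from_profile(cls, profile: np.ndarray, **kw) -> "NoiseCovariance":
        return cls(kind="diagonal", profile=np.asarray(profile, dtype=float), **kw)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, **kw) -> "NoiseCovariance":
        return cls(kind="dense", matrix=np.asarray(matrix, dtype=float), **kw)

    def scaled(self, c: float) -> "NoiseCovariance":
        """Multiply every variance by ``c > 0`` (eigenvectors are preserved)."""
        if c <= 0:
            raise ValueError("scale must be positive")
        if self.kind == "dense":
            return NoiseCovariance(kind="dense", matrix=self.matrix * c,
                                   base_variance=self.base_variance * c,
                                   provenance=self.provenance, region=self.region)
        return NoiseCovariance(kind="diagonal", profile=self.profile * c,
                               base_variance=self.base_variance * c,
                               provenance=self.provenance, region=self.region,
                               transmittance=self.transmittance)

    def content_hash(self) -> str:
        """SHA-256 of the numeric content; used by the patch-wise static-noise check."""
        h = hashlib.sha256()
        h.update(self.kind.encode())
        arr = self.matrix if self.kind == "dense" else self.profile
        h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# region helpers
# ---------------------------------------------------------------------------

def silent_region(cube: SpectralCube, lo: float, hi: float) -> SilentRegion:
    """Build a :class:`SilentRegion` from a wavenumber interval (inclusive)."""
    idx = np.flatnonzero((cube.axis >= lo) & (cube.axis <= hi))
    if idx.size == 0:
        raise ValueError(f"interval [{lo}, {hi}] cm⁻¹ selects no bands")
    return SilentRegion(lo=float(lo), hi=float(hi), indices=idx)


def default_silent_region(cube: SpectralCube) -> SilentRegion:
    """Default silent window by modality: FTIR-style axes reaching 2200 cm⁻¹
    use 1750–2200, QCL-style fingerprint axes use 1750–1800."""
    lo, hi = (
        DEFAULT_SILENT_REGIONS["ftir"]
        if cube.axis.max() >= DEFAULT_SILENT_REGIONS["ftir"][1]
        else DEFAULT_SILENT_REGIONS["qcl"]
    )
    return silent_region(cube, lo, hi)


def _band_step(cube: SpectralCube, indices: np.ndarray | None = None) -> float:
    ax = cube.axis if indices is None else cube.axis[indices]
    if ax.size < 2:
        return 1.0
    return float(np.abs(np.diff(ax)).mean())


# ---------------------------------------------------------------------------
# standard (order-dependent) estimator
# ---------------------------------------------------------------------------

def estimate_noise_adjacent(
    cube: SpectralCube, drop_row_boundaries: bool = False
) -> NoiseCovariance:
    """Adjacent-pixel difference noise covariance (the standard method).

    ``N_i = X_i − X_{i+1}`` over the row-major unrolled order and
    ``Σ_δ = NᵀN``.  Adjacent rows in the unrolled order are assumed to
    differ only by noise; this holds for contiguous image pixels but
    fails for shuffled, masked or patch-extracted data — the estimate is
    explicitly order-dependent.

    Row-boundary pairs (last pixel of one image row against the first of
    the next, not spatially adjacent) are included by default; for a
    512×512 image they are 511 of 262 143 pairs (< 0.2 %).  Set
    ``drop_row_boundaries=True`` to exclude them (requires ``shape2d``).
    """
    X = cube.spectra
    if X.shape[0] < 2:
        raise ValueError("need at least 2 spectra for adjacent differencing")
    N = X[:-1] - X[1:]
    if drop_row_boundaries:
        if cube.shape2d is None:
            raise ValueError("drop_row_boundaries requires a 2-D shape")
        _, width = cube.shape2d
        keep = (np.arange(N.shape[0]) + 1) % width != 0
        N = N[keep]
        if N.shape[0] == 0:
            raise ValueError("no pairs left after dropping row boundaries")
    return NoiseCovariance(kind="dense", matrix=N.T @ N, provenance="adjacent")


# ---------------------------------------------------------------------------
# iMNF constituents
# ---------------------------------------------------------------------------

def _sg_check(window: int, polyorder: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"Savitzky–Golay window must be odd, got {window}")
    if window < polyorder + 2:
        raise ValueError(
            f"Savitzky–Golay window {window} too small for polynomial order {polyorder}"
        )


def sg_variance_gain(window: int, polyorder: int, delta: float = 1.0) -> float:
    """White-noise variance gain of the SG first-derivative filter, Σcᵢ².

    For window 5 / order 2 / unit spacing the coefficients are
    ``[−2, −1, 0, 1, 2] / 10`` so the gain is 0.1: iid noise of variance
    σ² leaves the filter with variance 0.1 σ².
    """
    _sg_check(window, polyorder)
    c = savgol_coeffs(window, polyorder, deriv=1, delta=delta)
    return float(np.sum(c**2))


def sg_base_variance(
    cube: SpectralCube,
    region: SilentRegion,
    window: int = 5,
    polyorder: int = 2,
) -> float:
    """Base noise variance: mean per-band variance of the SG first
    derivative over the silent region.

    The derivative acts as a high-pass filter: slowly varying residual
    chemistry and baseline survive differentiation as near-constants
    while noise passes through, so the column variances isolate noise.
    Only interior derivative values enter the variance (the filter's
    polynomial edge extrapolation is discarded).  The value is in the
    *derivative* domain — it differs from the raw noise variance by the
    filter's scalar gain (:func:`sg_variance_gain`), which is immaterial
    to the MNF rotation.
    """
    _sg_check(window, polyorder)
    if len(region) <= window:
        raise ValueError(
            f"silent region has {len(region)} bands; need more than window={window}"
        )
    if region.indices.max() >= cube.n_bands:
        raise ValueError("silent-region indices fall outside the axis")
    sub = cube.spectra[:, region.indices]
    delta = _band_step(cube, region.indices)
    deriv = savgol_filter(sub, window, polyorder, deriv=1, delta=delta, axis=1)
    half = window // 2
    interior = deriv[:, half:-half]
    return float(np.mean(np.var(interior, axis=0)))  # population variance


def to_transmittance(mean_absorbance: np.ndarray) -> np.ndarray:
    """Beer–Lambert conversion ``T̄ = 10^(−Ā)``, clamped below at 1e-6."""
    A = np.asarray(mean_absorbance, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("mean absorbance contains non-finite values")
    return np.maximum(10.0 ** (-A), TRANSMITTANCE_EPS)


def reference_transmittance(T: np.ndarray, region: SilentRegion) -> float:
    """Arithmetic mean of the mean-transmittance spectrum over the region."""
    T = np.asarray(T, dtype=float)
    if region.indices.size == 0:
        raise ValueError("empty silent region")
    if region.indices.max() >= T.size:
        raise ValueError("silent-region indices fall outside the transmittance vector")
    return float(np.mean(T[region.indices]))


def noise_profile(
    base_variance: float, T: np.ndarray, T_ref: float
) -> np.ndarray:
    """Inverse-square transmittance scaling of the base variance.

    ``S(ν) = (T̄_ref / T̄(ν))²`` and ``σ²_profile = σ²_base · S``: noise
    that is constant in transmittance appears in absorbance with variance
    inversely proportional to T², so strong bands (small T̄) get large
    noise variances.  Floored at 1e-12 to keep the covariance invertible.
    """
    T = np.asarray(T, dtype=float)
    if base_variance < 0:
        raise ValueError("base variance must be nonnegative")
    if np.any(T <= 0):
        raise ValueError("transmittance must be positive")
    S = (T_ref / T) ** 2
    return np.maximum(base_variance * S, PROFILE_FLOOR)


def estimate_noise_imnf(
    cube: SpectralCube,
    region: SilentRegion | str | None = None,
    window: int = 5,
    polyorder: int = 2,
    gain_correct: bool = True,
    qc_factor: float = 5.0,
) -> NoiseCovariance:
    """Spatially invariant diagonal noise covariance (iMNF).

    Composes silent-region derivative variance → mean spectrum →
    transmittance → reference transmittance → inverse-square profile →
    ``Σ_δ = diag(σ²_profile)``.  Every ingredient is a column-wise mean
    or variance, so the estimate is invariant to any row permutation (up
    to floating-point summation order).

    Parameters
    ----------
    region
        A :class:`SilentRegion`, the string ``"auto"`` to run the
        sliding-window selection heuristic over the default silent
        interval, or None to use the modality default interval as-is.
    window, polyorder
        Savitzky–Golay parameters for the base-variance derivative
        (defaults 5 and 2).
    gain_correct
        Divide the derivative-domain variance by the filter's
        white-noise gain so ``base_variance`` (and the profile) sit on
        the raw absorbance-variance scale.  A pure scalar either way —
        the denoised output is identical — but the corrected profile is
        directly comparable to physical noise variances.
    qc_factor
        Spike-check threshold factor recorded in the region's QC report.
    """
    if region is None:
        reg = default_silent_region(cube)
    elif isinstance(region, str):
        if region != "auto":
            raise ValueError(f"unknown region spec {region!r}")
        lo, hi = default_silent_region(cube).lo, default_silent_region(cube).hi
        reg = select_silent_window(cube, lo, hi, window=window, polyorder=polyorder)
    else:
        reg = region

    base = sg_base_variance(cube, reg, window=window, polyorder=polyorder)
    if gain_correct:
        base /= sg_variance_gain(window, polyorder, _band_step(cube, reg.indices))

    reg.qc = qc_spike_check(cube, reg, factor=qc_factor,
                            window=window, polyorder=polyorder)

    A_mean = np.mean(cube.spectra, axis=0)
    T = to_transmittance(A_mean)
    T_ref = reference_transmittance(T, reg)
    S = (T_ref / T) ** 2
    profile = noise_profile(base, T, T_ref)
    return NoiseCovariance(
        kind="diagonal",
        profile=profile,
        base_variance=float(base),
        provenance="imnf",
        region=reg,
        transmittance=TransmittanceProfile(
            mean_absorbance=A_mean, mean_transmittance=T,
            reference=T_ref, scaling=S,
        ),
    )


def _band_derivative_variances(
    cube: SpectralCube, indices: np.ndarray, window: int, polyorder: int
) -> np.ndarray:
    """Per-band variance of the SG first derivative over selected bands.

    The derivative is computed over the index range extended by half a
    window on each side (clipped to the axis), so bands at the region's
    edge get proper interior filter values.  Bands within half a window
    of the *axis* ends cannot be assessed without the filter's polynomial
    edge extrapolation and are returned as NaN.
    """
    half = window // 2
    lo = max(int(indices[0]) - half, 0)
    hi = min(int(indices[-1]) + half, cube.n_bands - 1)
    ext = np.arange(lo, hi + 1)
    sub = cube.spectra[:, ext]
    delta = _band_step(cube, ext)
    deriv = savgol_filter(sub, window, polyorder, deriv=1, delta=delta, axis=1)
    var_ext = np.var(deriv, axis=0)
    # positions of the requested bands inside the extended range
    var = var_ext[indices - lo]
    edge = (indices < half) | (indices > cube.n_bands - 1 - half)
    var[edge] = np.nan
    return var


def select_silent_window(
    cube: SpectralCube,
    candidate_lo: float,
    candidate_hi: float,
    width: float = 50.0,
    window: int = 5,
    polyorder: int = 2,
) -> SilentRegion:
    """Sliding-window silent-region selection.

    Passes a window of the given width (cm⁻¹) across the candidate
    interval with a stride of one band and returns the window with the
    lowest mean per-band first-derivative variance — the quietest
    stretch of baseline.  Ties keep the first (lowest-index) window.
    """
    _sg_check(window, polyorder)
    cand = np.flatnonzero((cube.axis >= candidate_lo) & (cube.axis <= candidate_hi))
    if cand.size == 0:
        raise ValueError(
            f"candidate interval [{candidate_lo}, {candidate_hi}] is outside the axis"
        )
    step = _band_step(cube, cand)
    n_bands = int(round(width / step)) + 1
    if n_bands > cand.size:
        raise ValueError(
            f"window width {width} cm⁻¹ exceeds candidate interval length"
        )
    variances = _band_derivative_variances(cube, cand, window, polyorder)
    # mean variance of each contiguous window of n_bands, stride one band;
    # NaN (axis-edge) bands are left out of each window's mean
    win_means = np.array(
        [np.nanmean(variances[i : i + n_bands])
         for i in range(cand.size - n_bands + 1)]
    )
    if np.all(np.isnan(win_means)):
        raise ValueError("no assessable bands in the candidate interval")
    best = int(np.nanargmin(win_means))
    idx = cand[best : best + n_bands]
    ax = cube.axis[idx]
    return SilentRegion(
        lo=float(ax.min()), hi=float(ax.max()), indices=idx, auto_selected=True
    )


def qc_spike_check(
    cube: SpectralCube,
    region: SilentRegion,
    factor: float = 5.0,
    window: int = 5,
    polyorder: int = 2,
) -> QCReport:
    """Flag narrow-band contaminants inside a silent region.

    A band whose first-derivative variance exceeds ``factor`` × the
    median band variance of the region is flagged (e.g. an atmospheric
    or instrumental line).  Report-only: flagged bands are surfaced for
    the user, not silently removed.  Bands at the very ends of the axis
    (NaN variance) cannot be assessed and are never flagged.
    """
    variances = _band_derivative_variances(cube, region.indices, window, polyorder)
    med = float(np.nanmedian(variances))
    with np.errstate(invalid="ignore"):
        exceed = variances > factor * med
    # a narrow contaminant perturbs the derivative across the whole filter
    # footprint (the centre tap of the first-derivative kernel is zero), so
    # flag every band within half a window of an exceedance
    half = window // 2
    flagged_mask = np.zeros_like(exceed)
    for pos in np.flatnonzero(exceed):
        flagged_mask[max(pos - half, 0) : pos + half + 1] = True
    flagged = np.flatnonzero(flagged_mask)
    return QCReport(
        flagged_wavenumbers=cube.axis[region.indices[flagged]],
        flagged_indices=region.indices[flagged],
        band_variances=variances,
        median_variance=med,
        factor=float(factor),
    )


def offdiag_noise_correlation(noise: NoiseCovariance) -> float:
    """Mean absolute off-diagonal entry of the noise correlation matrix.

    Quantifies how correlated the noise is across wavenumbers — large
    values mean the diagonal (iMNF) approximation discards real
    structure.  For a diagonal covariance the quantity is 0 by
    construction (a warning is emitted; asking is usually a mistake).
    """
    if noise.kind == "diagonal":
        warnings.warn(
            "off-diagonal correlation of a diagonal covariance is 0 by construction",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    mat = noise.matrix
    d = np.sqrt(np.diag(mat))
    if np.any(d <= 0):
        raise ValueError("covariance has nonpositive diagonal entries")
    corr = mat / np.outer(d, d)
    v = mat.shape[0]
    off = ~np.eye(v, dtype=bool)
    return float(np.mean(np.abs(corr[off])))
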