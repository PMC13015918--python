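"""Tissue-phantom generator with physically modelled noise.

Phantoms are hyperspectral cubes of a few tissue-like classes (stroma-,
epithelium-, blood-like and background), each class a sum of Gaussian
absorbance bands including the protein Amide I (≈1656 cm⁻¹) and Amide II
(≈1546 cm⁻¹) bands, laid out as stripes, smooth blobs or a circular
tissue core.  A biologically silent interval is kept chemically empty by
construction so silent-region noise estimators can be validated against
ground truth.

The crucial generator choice: noise is injected in the *transmittance*
domain, ``T_noisy = 10^(−A) + ε`` with iid Gaussian ε, then converted
back to absorbance.  The inverse-square-transmittance law that the iMNF
noise model assumes then *emerges* from the physics of the logarithm
rather than being baked into the absorbance noise directly — the
estimator is tested against the mechanism, not against itself.  By the
delta method the absorbance-noise standard deviation at a band with mean
transmittance T̄ is ``σ_T / (T̄ · ln 10)``.

Default presets: a QCL-style fingerprint axis (1800–952 cm⁻¹, 2 cm⁻¹
step, 425 bands, silent window 1750–1800 cm⁻¹) and an FTIR-style axis
extending over the 1750–2200 cm⁻¹ silent region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from imnf.core import SpectralCube

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "add_noise",
    "add_correlated_noise",
    "shuffle_cube",
    "shuffle_phantom",
    "qcl_spec",
    "ftir_spec",
    "DEFAULT_CLASSES",
    "DEFAULT_SIGMA_T",
]

#: Default transmittance-domain noise standard deviation.  Chosen so that
#: denoising is visibly nontrivial on default phantoms (silent-region
#: absorbance noise σ ≈ 2.2e-3, i.e. SNR of order tens against the
#: default band peaks) — the instruments themselves publish no figure.
DEFAULT_SIGMA_T = 0.005

#: Per-class absorption bands: (centre cm⁻¹, Gaussian width cm⁻¹, peak
#: absorbance).  Classes have distinct Amide I / Amide II ratios so
#: ratio-preservation metrics have spread to work with.
DEFAULT_CLASSES = {
    "background": [(1656.0, 18.0, 0.04), (1546.0, 16.0, 0.04)],
    "stroma": [
        (1656.0, 18.0, 0.65),
        (1546.0, 16.0, 0.40),
        (1238.0, 14.0, 0.18),
        (1080.0, 16.0, 0.10),
    ],
    "epithelium": [
        (1656.0, 18.0, 0.70),
        (1546.0, 16.0, 0.52),
        (1236.0, 14.0, 0.12),
        (1080.0, 16.0, 0.22),
    ],
    "blood": [
        (1656.0, 18.0, 0.85),
        (1546.0, 16.0, 0.45),
        (1240.0, 12.0, 0.08),
    ],
}

#: Floor applied to noisy transmittance before the log — extreme negative
#: draws would otherwise produce log of a nonpositive number.
T_FLOOR = 1e-6


@dataclass
class PhantomSpec:
    """Recipe for a synthetic tissue phantom."""

    shape: tuple[int, int] = (64, 64)
    axis_spec: tuple[float, float, float] = (952.0, 1800.0, 2.0)  # lo, hi, step
    style: str = "stripes"  # stripes | blobs | cores
    classes: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CLASSES.items()}
    )
    silent: tuple[float, float] = (1750.0, 1800.0)
    #: softmax temperature for partial-volume mixing at blob boundaries
    #: (style "blobs" only; 0 gives hard class edges).  Real tissue pixels
    #: straddle tissue-type boundaries, so adjacent spectra change
    #: gradually rather than jumping between pure class spectra.
    edge_blend: float = 0.02
    sigma_t: float = DEFAULT_SIGMA_T
    correlated: dict | None = None  # {"baseline_amp":, "fringe_period":, "fringe_amp":}
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, step = self.axis_spec
        n = (hi - lo) / step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"step {step} does not divide axis span [{lo}, {hi}]")
        if self.style not in ("stripes", "blobs", "cores"):
            raise ValueError(f"unknown class-map style {self.style!r}")
        if self.sigma_t < 0:
            raise ValueError("sigma_t must be nonnegative")
        s_lo, s_hi = self.silent
        for name, bands in self.classes.items():
            for centre, width, _peak in bands:
                if centre + 3 * width > s_lo and centre - 3 * width < s_hi:
                    raise ValueError(
                        f"class {name!r} band at {centre} cm⁻¹ (±3×{width}) "
                        f"intrudes into the silent interval [{s_lo}, {s_hi}]"
                    )

    @property
    def axis(self) -> np.ndarray:
        lo, hi, step = self.axis_spec
        return np.arange(lo, hi + step / 2, step)

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)


@dataclass
class Phantom:
    """Clean and (optionally) noisy cube plus the class-label image."""

    clean: SpectralCube
    labels: np.ndarray  # (y, x) int class image
    spec: PhantomSpec
    noisy: SpectralCube | None = None

    def class_spectrum(self, name: str) -> np.ndarray:
        """Noise-free spectrum of one class."""
        return _class_spectrum(self.spec.axis, self.spec.classes[name])


def qcl_spec(**overrides) -> PhantomSpec:
    """QCL-style preset: 952–1800 cm⁻¹, 2 cm⁻¹ step (425 bands),
    silent window 1750–1800 cm⁻¹."""
    return PhantomSpec(**overrides)


def ftir_spec(**overrides) -> PhantomSpec:
    """FTIR-style preset: axis extended across the 1750–2200 cm⁻¹ silent
    region at a 4 cm⁻¹ step."""
    kw = dict(axis_spec=(952.0, 2500.0, 4.0), silent=(1750.0, 2200.0))
    kw.update(overrides)
    return PhantomSpec(**kw)


def _class_spectrum(axis: np.ndarray, bands) -> np.ndarray:
    # compactly supported band profiles: a Gaussian shifted and clipped to
    # zero beyond ±3 widths (then rescaled to the stated peak), so the
    # silent interval is *exactly* zero by construction, not merely tiny
    tail = np.exp(-4.5)
    spec = np.zeros_like(axis, dtype=float)
    for centre, width, peak in bands:
        g = np.exp(-0.5 * ((axis - centre) / width) ** 2)
        spec += peak * np.clip(g - tail, 0.0, None) / (1.0 - tail)
    return spec


def _label_image(spec: PhantomSpec):
    """Return ``(labels, abundances)``; abundances is None for hard layouts
    and an (m, n_classes) mixing matrix for blended blob boundaries."""
    y, x = spec.shape
    n = len(spec.classes)
    rng = np.random.default_rng(spec.seed)
    if spec.style == "stripes":
        rows = np.arange(y)
        return np.repeat((rows * n // y)[:, None], x, axis=1).astype(int), None
    if spec.style == "blobs":
        fields = np.stack(
            [
                ndimage.gaussian_filter(rng.standard_normal((y, x)), sigma=min(y, x) / 8)
                for _ in range(n)
            ]
        )
        labels = np.argmax(fields, axis=0).astype(int)
        if spec.edge_blend <= 0:
            return labels, None
        logits = fields.reshape(n, y * x).T / spec.edge_blend
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        return labels, w / w.sum(axis=1, keepdims=True)
    # cores: concentric tissue-core layout, background outside the disc
    yy, xx = np.mgrid[0:y, 0:x]
    r = np.hypot(yy - (y - 1) / 2, xx - (x - 1) / 2)
    r_max = min(y, x) / 2 - 0.5
    labels = np.zeros((y, x), dtype=int)  # class 0 = background
    inner = n - 1
    for i in range(inner):
        lo = r_max * i / inner
        hi = r_max * (i + 1) / inner
        labels[(r >= lo) & (r < hi)] = inner - i  # core centre gets last class
    labels[r >= r_max] = 0
    return labels, None


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the clean phantom: per-class band spectra laid out spatially.

    Blob layouts mix class spectra smoothly across boundaries (partial-
    volume effect); stripe and core layouts use pure class spectra.
    Deterministic given the spec's seed.
    """
    axis = spec.axis
    labels, abundances = _label_image(spec)
    class_spectra = np.stack(
        [_class_spectrum(axis, bands) for bands in spec.classes.values()]
    )
    if abundances is None:
        clean = class_spectra[labels.ravel()]
    else:
        clean = abundances @ class_spectra
    cube = SpectralCube(spectra=clean, axis=axis, shape2d=spec.shape)
    return Phantom(clean=cube, labels=labels, spec=spec)


def add_noise(
    phantom: Phantom, sigma_t: float | None = None, seed: int | None = None
) -> Phantom:
    """Inject iid Gaussian noise in the transmittance domain.

    ``T = 10^(−A_clean)``; ``T_noisy = T + ε`` with ``ε ~ N(0, σ_T²)``;
    ``A_noisy = −log10(max(T_noisy, 1e-6))``.  With ``σ_T = 0`` the noisy
    cube equals the clean one exactly.
    """
    if sigma_t is None:
        sigma_t = phantom.spec.sigma_t
    if sigma_t < 0:
        raise ValueError("sigma_t must be nonnegative")
    if seed is None:
        seed = phantom.spec.seed + 1
    A = phantom.clean.spectra
    if sigma_t == 0:
        noisy = A.copy()
    else:
        rng = np.random.default_rng(seed)
        T = 10.0 ** (-A)
        T_noisy = T + rng.normal(0.0, sigma_t, size=A.shape)
        noisy = -np.log10(np.maximum(T_noisy, T_FLOOR))
    return replace(phantom, noisy=phantom.clean.with_spectra(noisy))


def add_correlated_noise(
    phantom: Phantom,
    baseline_amp: float = 0.0,
    fringe_period: float = 100.0,
    fringe_amp: float = 0.0,
    seed: int | None = None,
) -> Phantom:
    """Add spectrally *correlated* noise: per-pixel random-slope baselines
    and a sinusoidal fringe (random phase per pixel).

    This is the deliberate stressor for the diagonal noise model — both
    components produce strong off-diagonal noise correlation, which the
    iMNF covariance ignores by design while adjacent differencing can
    capture it (when the data are ordered).
    """
    if baseline_amp < 0 or fringe_amp < 0:
        raise ValueError("amplitudes must be nonnegative")
    base_cube = phantom.noisy if phantom.noisy is not None else phantom.clean
    A = base_cube.spectra
    if baseline_amp == 0 and fringe_amp == 0:
        return replace(phantom, noisy=base_cube.with_spectra(A.copy()))
    if seed is None:
        seed = phantom.spec.seed + 2
    rng = np.random.default_rng(seed)
    axis = base_cube.axis
    m = A.shape[0]
    t = (axis - axis.mean()) / (np.ptp(axis) / 2)  # [-1, 1] across the axis
    out = A.copy()
    if baseline_amp > 0:
        slopes = rng.normal(0.0, baseline_amp, size=m)
        out = out + slopes[:, None] * t[None, :]
    if fringe_amp > 0:
        phases = rng.uniform(0.0, 2 * np.pi, size=m)
        out = out + fringe_amp * np.sin(
            2 * np.pi * axis[None, :] / fringe_period + phases[:, None]
        )
    return replace(phantom, noisy=base_cube.with_spectra(out))


def shuffle_cube(cube: SpectralCube, seed: int = 0):
    """Return ``(shuffled_cube, permutation)``; un-permute with
    ``shuffled.spectra[np.argsort(perm)]``.

    The shuffled cube keeps the 2-D shape (it still holds m = y·x
    spectra) — the point is that the *rows no longer correspond* to that
    spatial layout, which is exactly the condition order-dependent noise
    estimation cannot survive.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cube.n_spectra)
    shuffled = SpectralCube(
        spectra=cube.spectra[perm],
        axis=cube.axis,
        shape2d=cube.shape2d,
        mask=None if cube.mask is None else cube.mask[perm],
    )
    return shuffled, perm


def shuffle_phantom(phantom: Phantom, seed: int = 0):
    """Shuffle clean and noisy cubes with the same permutation."""
    shuffled_clean, perm = shuffle_cube(phantom.clean, seed)
    noisy = None
    if phantom.noisy is not None:
        noisy = phantom.noisy.with_spectra(phantom.noisy.spectra[perm])
    return replace(phantom, clean=shuffled_clean, noisy=noisy), perm
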