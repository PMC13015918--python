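"""Evaluation procedures for denoising runs.

Adjacency cosine similarity (how badly sampling breaks the adjacency
assumption), silent-region variance (a proxy for residual noise),
Amide I / Amide II ratio preservation (a biochemical readout), pixel-wise
difference maps (order-(in)dependence made visible) and the edge-transition
combinatorics of row-major unrolling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from imnf.core import SpectralCube
from imnf.noise import SilentRegion

__all__ = [
    "adjacent_cosine",
    "fraction_below",
    "silent_variance",
    "amide_ratio",
    "r_squared",
    "difference_map",
    "DifferenceMap",
    "edge_transitions",
    "EvaluationReport",
    "AMIDE_I",
    "AMIDE_II",
]

#: Protein band centres (cm⁻¹).
AMIDE_I = 1656.0
AMIDE_II = 1546.0


def adjacent_cosine(cube: SpectralCube) -> np.ndarray:
    """Cosine similarity of each consecutive row pair in unrolled order.

    On an ordered image almost all pairs are near 1; on sampled or
    shuffled data many are not — which is why adjacent-difference noise
    estimation fails there.
    """
    X = cube.spectra
    if X.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-norm spectrum at pixel {bad[0]}")
    unit = X / norms[:, None]
    return np.clip(np.sum(unit[:-1] * unit[1:], axis=1), -1.0, 1.0)


def fraction_below(similarities: np.ndarray, threshold: float) -> float:
    """Percentage of similarity values strictly below a threshold
    (conventional thresholds: 0.99 and 0.95)."""
    s = np.asarray(similarities, dtype=float)
    if s.size == 0:
        raise ValueError("empty similarity vector")
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [-1, 1]")
    return float(100.0 * np.count_nonzero(s < threshold) / s.size)


def silent_variance(cube: SpectralCube, region: SilentRegion) -> float:
    """Mean over silent-region bands of the per-band variance across pixels.

    With no chemistry in the region, this is an absolute measure of
    residual noise; denoising should reduce it.
    """
    if region.indices.size == 0:
        raise ValueError("empty silent region")
    if region.indices.max() >= cube.n_bands:
        raise ValueError("silent-region indices fall outside the axis")
    sub = cube.spectra[:, region.indices]
    return float(np.mean(np.var(sub, axis=0)))


def amide_ratio(
    cube: SpectralCube,
    numerator: float = AMIDE_I,
    denominator: float = AMIDE_II,
) -> np.ndarray:
    """Per-pixel Amide I / Amide II absorbance ratio.

    Band lookup is by nearest axis value (no interpolation, matching
    discrete instrument sampling).  Pixels whose denominator absorbance
    is ≤ 0 are excluded: their ratio is NaN, and the number of finite
    entries tells how many survived.
    """
    i_num = cube.band_index(numerator)
    i_den = cube.band_index(denominator)
    num = cube.spectra[:, i_num].astype(float)
    den = cube.spectra[:, i_den].astype(float)
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def r_squared(
    reference: np.ndarray, estimate: np.ndarray, method: str = "pearson"
) -> float:
    """Coefficient of determination of estimate against reference.

    ``pearson`` (default) is the squared Pearson correlation — scale
    insensitive, so a denoiser that rescales but preserves relative
    ratios still scores 1.  ``identity`` measures agreement with the
    y = x line (``1 − SS_res/SS_tot``) and conflates bias with noise.
    NaN pairs (e.g. excluded ratio pixels) are dropped.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("reference and estimate must have equal length")
    ok = np.isfinite(ref) & np.isfinite(est)
    ref, est = ref[ok], est[ok]
    if ref.size < 2:
        raise ValueError("need at least 2 finite pairs")
    if np.var(ref) == 0 or (method == "pearson" and np.var(est) == 0):
        raise ValueError("zero-variance input")
    if method == "pearson":
        r = np.corrcoef(ref, est)[0, 1]
        return float(r * r)
    if method == "identity":
        ss_res = np.sum((est - ref) ** 2)
        ss_tot = np.sum((ref - ref.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot)
    raise ValueError(f"unknown method {method!r}")


class DifferenceMap(NamedTuple):
    image: np.ndarray
    max: float
    mean: float


def difference_map(
    a: SpectralCube, b: SpectralCube, wavenumber: float
) -> DifferenceMap:
    """Pixel-wise absolute difference |a − b| at the band nearest a query
    wavenumber, reshaped to the 2-D image.

    The canonical use: difference between denoising ordered data and
    denoising shuffled-then-unshuffled data — zero everywhere for a
    spatially invariant method, structured error for an order-dependent
    one.
    """
    if a.spectra.shape != b.spectra.shape:
        raise ValueError("cubes have different shapes")
    if not np.array_equal(a.axis, b.axis):
        raise ValueError("cubes have different axes")
    if a.shape2d is None:
        raise ValueError("cube has no 2-D shape")
    band = a.band_index(wavenumber)
    diff = np.abs(a.spectra[:, band] - b.spectra[:, band])
    return DifferenceMap(
        image=diff.reshape(a.shape2d), max=float(diff.max()), mean=float(diff.mean())
    )


def edge_transitions(height: int, width: int) -> tuple[int, int]:
    """Edge-transition count of row-major unrolling.

    Consecutive pairs in the unrolled pixel list that are *not*
    horizontally adjacent in the image: one per row boundary, i.e.
    ``height − 1`` out of ``height·width − 1`` total pairs.  For a
    512×512 image that is 511 of 262 143 (< 0.2 %), which is why
    adjacent differencing tolerates the wrap-around pairs on whole
    images.
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be >= 1")
    return height - 1, height * width - 1


@dataclass
class EvaluationReport:
    """Named scalar metrics plus optional per-pixel vectors and provenance."""

    metrics: dict = field(default_factory=dict)
    vectors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.metrics.items():
            if not np.isfinite(value):
                raise ValueError(f"metric {name!r} is not finite: {value}")

    def to_dict(self) -> dict:
        return {"metrics": dict(self.metrics), "provenance": dict(self.provenance)}
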