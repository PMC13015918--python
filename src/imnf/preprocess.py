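"""Spectral preprocessing for infrared tissue spectra.

The standard pipeline around denoising: linear baseline subtraction,
truncation to the fingerprint region, removal of the paraffin-wax
interval, vector normalisation and Savitzky–Golay smoothing /
differentiation.  All wavenumber intervals are inclusive on both ends —
the field's "1490–1360 cm⁻¹" style is a closed interval, and off-by-one
band counts are a classic source of drift between implementations.

Every operation returns a new :class:`~imnf.core.SpectralCube` and
preserves the number of spectra.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from imnf.core import SpectralCube

__all__ = [
    "sg_filter",
    "baseline_linear",
    "truncate",
    "remove_band",
    "vector_normalise",
    "apply_pipeline",
    "WAX_REGION",
    "FINGERPRINT_REGION",
]

#: Default paraffin-wax interval removed before classification (cm⁻¹).
WAX_REGION = (1360.0, 1490.0)

#: Fingerprint region used for truncation (cm⁻¹).
FINGERPRINT_REGION = (1000.0, 1800.0)


def sg_filter(
    cube: SpectralCube, window: int, polyorder: int, deriv: int = 0
) -> SpectralCube:
    """Per-spectrum Savitzky–Golay convolution.

    ``deriv=0`` smooths; ``deriv=1``/``2`` differentiate (band spacing is
    taken from the axis, so derivatives are per cm⁻¹).  Defaults used in
    the classification pipeline are window 19 / order 4 for the second
    derivative.  ``window=1`` with ``deriv=0`` is the identity
    passthrough.
    """
    if window == 1 and deriv == 0:
        return cube.with_spectra(cube.spectra.copy())
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if deriv > polyorder:
        raise ValueError(f"deriv {deriv} must be <= polyorder {polyorder}")
    delta = float(np.abs(np.diff(cube.axis)).mean()) if cube.n_bands > 1 else 1.0
    out = savgol_filter(
        cube.spectra, window, polyorder, deriv=deriv, delta=delta, axis=1
    )
    return cube.with_spectra(out)


def baseline_linear(cube: SpectralCube, method: str = "endpoints") -> SpectralCube:
    """Subtract a straight baseline from every spectrum.

    ``endpoints`` (default) anchors the line at the first and last
    retained band, so both endpoints map exactly to zero.  ``lstsq``
    subtracts the least-squares line instead.
    """
    if cube.n_bands < 2:
        raise ValueError("need at least 2 bands for a linear baseline")
    X = cube.spectra
    ax = cube.axis
    if method == "endpoints":
        t = (ax - ax[0]) / (ax[-1] - ax[0])
        base = X[:, [0]] + (X[:, [-1]] - X[:, [0]]) * t
    elif method == "lstsq":
        A = np.vstack([ax, np.ones_like(ax)]).T
        coef, *_ = np.linalg.lstsq(A, X.T, rcond=None)
        base = (A @ coef).T
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return cube.with_spectra(X - base)


def _interval_mask(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (axis >= lo) & (axis <= hi)


def truncate(cube: SpectralCube, lo: float, hi: float) -> SpectralCube:
    """Keep bands with ``lo <= wavenumber <= hi`` (inclusive both ends)."""
    keep = _interval_mask(cube.axis, lo, hi)
    if not keep.any():
        raise ValueError(f"truncation to [{lo}, {hi}] cm⁻¹ keeps no bands")
    return cube.with_spectra(cube.spectra[:, keep], axis=cube.axis[keep])


def remove_band(
    cube: SpectralCube, lo: float = WAX_REGION[0], hi: float = WAX_REGION[1]
) -> SpectralCube:
    """Drop bands inside ``[lo, hi]`` inclusive (default: the wax region)."""
    keep = ~_interval_mask(cube.axis, lo, hi)
    if not keep.any():
        raise ValueError(f"removing [{lo}, {hi}] cm⁻¹ would empty the axis")
    return cube.with_spectra(cube.spectra[:, keep], axis=cube.axis[keep])


def vector_normalise(cube: SpectralCube) -> SpectralCube:
    """Scale every spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(cube.spectra, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"cannot normalise all-zero spectrum at pixel {bad[0]}")
    return cube.with_spectra(cube.spectra / norms[:, None])


#: Step registry for declarative pipelines: name -> callable(cube, **params).
_STEPS = {
    "baseline": baseline_linear,
    "truncate": truncate,
    "remove_band": remove_band,
    "normalise": vector_normalise,
    "sg": sg_filter,
}


def apply_pipeline(cube: SpectralCube, steps) -> SpectralCube:
    """Run an ordered list of preprocessing steps.

    Each step is ``(name, params_dict)`` or ``{"op": name, **params}``,
    e.g. ``[("baseline", {}), ("truncate", {"lo": 1000, "hi": 1800})]``.
    """
    for step in steps:
        if isinstance(step, dict):
            params = dict(step)
            name = params.pop("op")
        else:
            name, params = step
        if name not in _STEPS:
            raise ValueError(f"unknown preprocessing step {name!r}")
        cube = _STEPS[name](cube, **params)
    return cube
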