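"""Shared fixtures: small deterministic phantoms and cubes.

Phantom fixtures are session-scoped — they are read-only inputs and
several tests reuse the same noisy cube.
"""

import numpy as np
import pytest

from imnf import SpectralCube, add_noise, make_phantom, qcl_spec


@pytest.fixture(scope="session")
def qcl_phantom():
    """32×32 QCL-style blob phantom with transmittance-domain noise."""
    return add_noise(make_phantom(qcl_spec(shape=(32, 32), style="blobs", seed=3)))


@pytest.fixture(scope="session")
def qcl_phantom_large():
    """64×64 QCL-style blob phantom for patch-wise direction tests."""
    return add_noise(make_phantom(qcl_spec(shape=(64, 64), style="blobs", seed=3)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cube():
    """Tiny 6-spectrum, 5-band cube with a unit-spaced axis."""
    rng = np.random.default_rng(0)
    return SpectralCube(
        spectra=rng.normal(size=(6, 5)), axis=np.arange(5, dtype=float)
    )


def unit_axis_cube(spectra: np.ndarray) -> SpectralCube:
    """Cube with a unit-spaced wavenumber axis (helper, not a fixture)."""
    return SpectralCube(
        spectra=spectra, axis=np.arange(spectra.shape[1], dtype=float)
    )
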