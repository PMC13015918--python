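"""File formats: ENVI header/binary, an HDF5 container, CSV spectra.

The HDF5 container is the package's primary format — one file holding
the cube (``/data``, either ``(m, v)`` or ``(y, x, v)``), the wavenumber
axis (``/axis``), optional ``/labels`` and ``/mask`` images, and a
``/meta`` group whose attributes record modality and a JSON provenance
log of every processing step applied.

ENVI (text header + raw binary, BSQ/BIL/BIP interleaves) is supported
for interchange with other hyperspectral tools; the wavenumber axis
travels in the header's ``wavelength`` field.  CSV carries one header
row of wavenumbers followed by one row per spectrum.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np

from imnf.core import MNFModel, SpectralCube
from imnf.synthetic import Phantom, PhantomSpec

__all__ = [
    "read_envi",
    "write_envi",
    "read_h5",
    "write_h5",
    "read_h5_labels",
    "read_csv_spectra",
    "write_csv_spectra",
    "save_model",
    "load_model",
    "write_phantom_h5",
    "read_phantom_h5",
    "H5PatchSource",
    "H5PatchSink",
    "append_provenance",
]

# ENVI numeric data-type codes (subset: the floating/integer types a
# spectroscopy pipeline actually meets).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _envi_data_path(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem, stem.with_suffix(".img"), stem.with_suffix(".dat"),
                 stem.with_suffix(".raw")):
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(f"no binary file found for ENVI header {header_path}")


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            parts = [value]
            while i < len(lines):
                parts.append(lines[i])
                if "}" in lines[i]:
                    i += 1
                    break
                i += 1
            value = " ".join(parts)
        fields[key] = value
    return fields


def _parse_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def read_envi(header_path: str | os.PathLike) -> SpectralCube:
    """Read an ENVI header + binary pair into a :class:`SpectralCube`.

    Supports BSQ/BIL/BIP interleaves, little/big byte order and the
    common numeric data types; the wavenumber axis is taken from the
    header's ``wavelength`` field.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength field")
    axis = np.asarray(_parse_list(fields["wavelength"]), dtype=float)
    if axis.size != bands:
        raise ValueError(
            f"header band count {bands} does not match wavelength list "
            f"length {axis.size}"
        )
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))

    raw = np.fromfile(_envi_data_path(header_path), dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"binary file holds {raw.size} values, expected {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    spectra = np.ascontiguousarray(data.reshape(lines * samples, bands)).astype(
        dtype.newbyteorder("="), copy=False
    )
    return SpectralCube(spectra=spectra, axis=axis, shape2d=(lines, samples))


def write_envi(
    cube: SpectralCube,
    header_path: str | os.PathLike,
    interleave: str = "bsq",
    dtype=np.float64,
) -> Path:
    """Write a cube as an ENVI header + ``.img`` binary pair (little
    endian); returns the binary path."""
    header_path = Path(header_path)
    dtype = np.dtype(dtype)
    if dtype not in _ENVI_CODES:
        raise ValueError(f"unsupported dtype {dtype} for ENVI output")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    if cube.shape2d is not None:
        lines, samples = cube.shape2d
    else:
        lines, samples = cube.n_spectra, 1
    bands = cube.n_bands
    data = cube.spectra.reshape(lines, samples, bands).astype(dtype)
    if interleave == "bsq":
        arr = data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = data.transpose(0, 2, 1)
    else:
        arr = data
    data_path = header_path.with_suffix(".img")
    np.ascontiguousarray(arr).tofile(data_path)
    wavelengths = ", ".join(f"{w:.6f}" for w in cube.axis)
    header_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = cm-1\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    return data_path


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_h5(
    cube: SpectralCube,
    path: str | os.PathLike,
    labels: np.ndarray | None = None,
    meta: dict | None = None,
    dtype=None,
) -> None:
    """Write a cube (plus optional labels/mask/meta) to the HDF5 container."""
    with h5py.File(path, "w") as fh:
        data = cube.spectra if dtype is None else cube.spectra.astype(dtype)
        if cube.shape2d is not None:
            data = data.reshape(*cube.shape2d, cube.n_bands)
        fh.create_dataset("data", data=data, track_times=False)
        fh.create_dataset("axis", data=cube.axis, track_times=False)
        if cube.mask is not None:
            fh.create_dataset("mask", data=cube.mask, track_times=False)
        if labels is not None:
            fh.create_dataset("labels", data=np.asarray(labels, dtype=np.int32), track_times=False)
        grp = fh.create_group("meta")
        for key, value in (meta or {}).items():
            grp.attrs[key] = value if np.isscalar(value) else json.dumps(value)


def read_h5(path: str | os.PathLike) -> SpectralCube:
    """Read the container back into a :class:`SpectralCube`."""
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        axis = fh["axis"][()]
        mask = fh["mask"][()] if "mask" in fh else None
        if data.ndim == 3:
            shape2d = data.shape[:2]
            data = data.reshape(-1, data.shape[2])
        else:
            shape2d = None
        return SpectralCube(spectra=data, axis=axis, shape2d=shape2d, mask=mask)


def read_h5_labels(path: str | os.PathLike) -> np.ndarray | None:
    with h5py.File(path, "r") as fh:
        return fh["labels"][()] if "labels" in fh else None


def read_h5_meta(path: str | os.PathLike) -> dict:
    with h5py.File(path, "r") as fh:
        if "meta" not in fh:
            return {}
        out = {}
        for key, value in fh["meta"].attrs.items():
            if isinstance(value, (bytes, str)):
                text = value.decode() if isinstance(value, bytes) else value
                try:
                    out[key] = json.loads(text)
                except (json.JSONDecodeError, ValueError):
                    out[key] = text
            else:
                out[key] = value
        return out


def append_provenance(meta: dict | None, step: str, **params) -> dict:
    """Append one processing step to a meta dict's provenance log."""
    meta = dict(meta or {})
    log = list(meta.get("provenance", []))
    log.append({"step": step, **params})
    meta["provenance"] = log
    return meta


# ---------------------------------------------------------------------------
# phantoms and models
# ---------------------------------------------------------------------------

def write_phantom_h5(phantom: Phantom, path: str | os.PathLike) -> None:
    """Container with ``clean``, ``noisy`` and ``labels`` groups plus the
    generation parameters in ``/meta``."""
    spec = phantom.spec
    with h5py.File(path, "w") as fh:
        y, x = spec.shape
        fh.create_dataset("clean", data=phantom.clean.spectra.reshape(y, x, -1), track_times=False)
        if phantom.noisy is not None:
            fh.create_dataset("noisy", data=phantom.noisy.spectra.reshape(y, x, -1), track_times=False)
        fh.create_dataset("labels", data=phantom.labels.astype(np.int32), track_times=False)
        fh.create_dataset("axis", data=spec.axis, track_times=False)
        grp = fh.create_group("meta")
        grp.attrs["shape"] = list(spec.shape)
        grp.attrs["axis_spec"] = list(spec.axis_spec)
        grp.attrs["style"] = spec.style
        grp.attrs["silent"] = list(spec.silent)
        grp.attrs["sigma_t"] = spec.sigma_t
        grp.attrs["seed"] = spec.seed
        grp.attrs["classes"] = json.dumps(spec.classes)


def read_phantom_h5(path: str | os.PathLike) -> Phantom:
    with h5py.File(path, "r") as fh:
        attrs = fh["meta"].attrs
        spec = PhantomSpec(
            shape=tuple(int(v) for v in attrs["shape"]),
            axis_spec=tuple(float(v) for v in attrs["axis_spec"]),
            style=str(attrs["style"]),
            classes={k: [tuple(b) for b in v]
                     for k, v in json.loads(attrs["classes"]).items()},
            silent=tuple(float(v) for v in attrs["silent"]),
            sigma_t=float(attrs["sigma_t"]),
            seed=int(attrs["seed"]),
        )
        axis = fh["axis"][()]
        shape2d = spec.shape
        clean = SpectralCube(
            spectra=fh["clean"][()].reshape(-1, axis.size), axis=axis, shape2d=shape2d
        )
        noisy = None
        if "noisy" in fh:
            noisy = SpectralCube(
                spectra=fh["noisy"][()].reshape(-1, axis.size),
                axis=axis,
                shape2d=shape2d,
            )
        labels = fh["labels"][()]
    return Phantom(clean=clean, labels=labels, spec=spec, noisy=noisy)


def save_model(model: MNFModel, path: str | os.PathLike) -> None:
    """Serialise a fitted MNF model (matrices + k + provenance) to HDF5."""
    with h5py.File(path, "w") as fh:
        for name in ("noise_eigvecs", "noise_eigvals", "signal_eigvecs",
                     "signal_eigvals", "forward", "reconstruction"):
            fh.create_dataset(name, data=getattr(model, name), track_times=False)
        fh.attrs["k"] = model.k
        fh.attrs["noise_is_diagonal"] = model.noise_is_diagonal
        fh.attrs["noise_provenance"] = model.noise_provenance


def load_model(path: str | os.PathLike) -> MNFModel:
    with h5py.File(path, "r") as fh:
        return MNFModel(
            noise_eigvecs=fh["noise_eigvecs"][()],
            noise_eigvals=fh["noise_eigvals"][()],
            signal_eigvecs=fh["signal_eigvecs"][()],
            signal_eigvals=fh["signal_eigvals"][()],
            k=int(fh.attrs["k"]),
            forward=fh["forward"][()],
            reconstruction=fh["reconstruction"][()],
            noise_is_diagonal=bool(fh.attrs["noise_is_diagonal"]),
            noise_provenance=str(fh.attrs["noise_provenance"]),
        )


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_csv_spectra(cube: SpectralCube, path: str | os.PathLike) -> None:
    """CSV with one header row of wavenumbers, then one row per spectrum."""
    header = ",".join(f"{w:.10g}" for w in cube.axis)
    np.savetxt(path, cube.spectra, delimiter=",", header=header,
               comments="", fmt="%.18e")


def read_csv_spectra(path: str | os.PathLike) -> SpectralCube:
    axis = np.loadtxt(path, delimiter=",", max_rows=1)
    spectra = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return SpectralCube(spectra=spectra, axis=np.atleast_1d(axis))


# ---------------------------------------------------------------------------
# streaming endpoints over HDF5
# ---------------------------------------------------------------------------

class H5PatchSource:
    """Patch reader over an HDF5 container written by :func:`write_h5`
    with a 3-D ``(y, x, v)`` data layout; only the requested patch is
    read from disk."""

    def __init__(self, path: str | os.PathLike, dataset: str = "data"):
        self._fh = h5py.File(path, "r")
        self._data = self._fh[dataset]
        if self._data.ndim != 3:
            raise ValueError("H5PatchSource requires a (y, x, v) data layout")
        self.axis = self._fh["axis"][()]
        self.shape2d = self._data.shape[:2]

    def read(self, rect: tuple[int, int, int, int]) -> np.ndarray:
        r_lo, r_hi, c_lo, c_hi = rect
        block = self._data[r_lo:r_hi, c_lo:c_hi, :]
        return block.reshape(-1, block.shape[2])

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class H5PatchSink:
    """Patch writer creating an HDF5 container incrementally."""

    def __init__(
        self,
        path: str | os.PathLike,
        shape2d: tuple[int, int],
        axis: np.ndarray,
        dtype=np.float64,
    ):
        axis = np.asarray(axis, dtype=float)
        self._fh = h5py.File(path, "a")
        if "data" in self._fh:
            self._data = self._fh["data"]
        else:
            self._data = self._fh.create_dataset(
                "data", shape=(*shape2d, axis.size), dtype=dtype,
                track_times=False,
            )
            self._fh.create_dataset("axis", data=axis, track_times=False)
        self.shape2d = tuple(shape2d)

    def write(self, rect: tuple[int, int, int, int], block: np.ndarray) -> None:
        r_lo, r_hi, c_lo, c_hi = rect
        self._data[r_lo:r_hi, c_lo:c_hi, :] = block.reshape(
            r_hi - r_lo, c_hi - c_lo, -1
        )

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
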