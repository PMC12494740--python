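"""Reading and writing hypercubes.

Two on-disk dialects are supported:

* ``envi`` — a classic ENVI header/raw pair. The header is the text file; the
  raw file holds band-sequential (BSQ), little-endian float32 samples. The
  header must carry a ``wavelength`` list, from which the uniform axis is
  reconstructed. Float32 storage means ENVI round-trips are exact only to
  single precision.
* ``container`` — an HDF5 file with one dataset named ``cube`` (float64,
  y * x * lambda) and axis attributes ``start_nm`` / ``step_nm``; ``label`` and
  free-form ``meta.*`` attributes are preserved. Container round-trips are
  bit-exact.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, MetadataError, ValidationError
from .hypercube import Hypercube, WavelengthAxis

__all__ = ["read_cube", "write_cube"]

_ENVI_DTYPE = np.dtype("<f4")  # ENVI data type 4, byte order 0


def _paths_for_envi(path: str | Path) -> tuple[Path, Path]:
    """Resolve (header, raw) from either member of the pair or a stem."""
    p = Path(path)
    if p.suffix == ".hdr":
        return p, p.with_suffix(".raw")
    if p.suffix == ".raw":
        return p.with_suffix(".hdr"), p
    return p.with_suffix(".hdr"), p.with_suffix(".raw")


def write_cube(cube: Hypercube, path: str | Path, format: str = "container") -> Path:
    """Write a cube to disk; returns the path written (header path for ENVI)."""
    if format == "container":
        return _write_container(cube, Path(path))
    if format == "envi":
        return _write_envi(cube, path)
    raise ValueError(f"unknown format {format!r}; expected 'envi' or 'container'")


def read_cube(path: str | Path, format: str = "container") -> Hypercube:
    """Read a cube from disk, validating shape, finiteness and metadata."""
    if format == "container":
        return _read_container(Path(path))
    if format == "envi":
        return _read_envi(path)
    raise ValueError(f"unknown format {format!r}; expected 'envi' or 'container'")


def _write_container(cube: Hypercube, path: Path) -> Path:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("cube", data=cube.values)
        ds.attrs["start_nm"] = cube.axis.start_nm
        ds.attrs["step_nm"] = cube.axis.step_nm
        if cube.label is not None:
            ds.attrs["label"] = int(cube.label)
        for k, v in cube.meta.items():
            ds.attrs[f"meta.{k}"] = v
    return path


def _read_container(path: Path) -> Hypercube:
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "cube" not in f:
            raise FormatError(f"{path}: no dataset named 'cube'")
        ds = f["cube"]
        for key in ("start_nm", "step_nm"):
            if key not in ds.attrs:
                raise MetadataError(f"{path}: missing required attribute {key!r}")
        values = np.asarray(ds)
        if values.ndim != 3:
            raise FormatError(f"{path}: dataset 'cube' is {values.ndim}-D, expected 3-D")
        axis = WavelengthAxis(
            start_nm=float(ds.attrs["start_nm"]),
            step_nm=float(ds.attrs["step_nm"]),
            n_channels=values.shape[2],
        )
        label = int(ds.attrs["label"]) if "label" in ds.attrs else None
        meta = {
            k[len("meta."):]: (v.item() if isinstance(v, np.generic) else v)
            for k, v in ds.attrs.items()
            if k.startswith("meta.")
        }
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: cube contains non-finite values")
    return Hypercube(values=values, axis=axis, label=label, meta=meta)


def _write_envi(cube: Hypercube, path: str | Path) -> Path:
    hdr_path, raw_path = _paths_for_envi(path)
    y, x, n = cube.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.axis.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {x}\n"
        f"lines = {y}\n"
        f"bands = {n}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(header)
    # BSQ: band-major on disk -> (bands, lines, samples)
    bsq = np.ascontiguousarray(cube.values.transpose(2, 0, 1), dtype=_ENVI_DTYPE)
    bsq.tofile(raw_path)
    return hdr_path


_HDR_FIELD = re.compile(r"^\s*([^=]+?)\s*=\s*(.*)$")


def _parse_envi_header(text: str) -> dict[str, str]:
    # Collapse brace-delimited multi-line values onto one line first.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        m = _HDR_FIELD.match(line)
        if m:
            fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _read_envi(path: str | Path) -> Hypercube:
    hdr_path, raw_path = _paths_for_envi(path)
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    if not raw_path.exists():
        raise FileNotFoundError(raw_path)
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        x = int(fields["samples"])
        y = int(fields["lines"])
        n = int(fields["bands"])
    except KeyError as exc:
        raise FormatError(f"{hdr_path}: missing header field {exc.args[0]!r}") from exc
    if fields.get("data type", "4") != "4":
        raise FormatError(f"{hdr_path}: only data type 4 (float32) is supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError(f"{hdr_path}: only BSQ interleave is supported")
    if "wavelength" not in fields:
        raise MetadataError(f"{hdr_path}: missing required key 'wavelength'")
    wl = np.array(
        [float(v) for v in fields["wavelength"].strip("{} ").split(",") if v.strip()]
    )
    if wl.size != n:
        raise FormatError(f"{hdr_path}: {wl.size} wavelengths for {n} declared bands")
    steps = np.diff(wl)
    if wl.size > 1 and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{hdr_path}: wavelength grid is not uniform")
    step = float(steps[0]) if wl.size > 1 else 1.0

    expected = y * x * n
    actual = os.path.getsize(raw_path) // _ENVI_DTYPE.itemsize
    if actual != expected:
        raise FormatError(
            f"{raw_path}: holds {actual} samples but header declares {expected} ({y}x{x}x{n})"
        )
    bsq = np.fromfile(raw_path, dtype=_ENVI_DTYPE).reshape(n, y, x)
    values = bsq.transpose(1, 2, 0).astype(np.float64)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{raw_path}: cube contains non-finite values")
    axis = WavelengthAxis(start_nm=float(wl[0]), step_nm=step, n_channels=n)
    return Hypercube(values=values, axis=axis)
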