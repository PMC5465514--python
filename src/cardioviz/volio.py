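"""Volume file I/O: single-file NRRD (raw encoding) and raw + text sidecar.

The NRRD writer emits NRRD0004 headers with little-endian raw data laid
out fastest-axis-first (Fortran order with respect to the stated sizes),
the convention the wider NRRD ecosystem uses, so volumes written here open
in standard viewers. Only the subset of the format this package produces
is read back: raw encoding, 3D, little endian.
"""

from __future__ import annotations

import pathlib
import time

import numpy as np

__all__ = ["write_nrrd", "read_nrrd", "write_raw", "read_raw"]

_DTYPES = {
    "uint8": np.uint8, "int16": np.int16, "int32": np.int32,
    "float": np.float32, "double": np.float64,
}
_NAMES = {np.dtype(v): k for k, v in _DTYPES.items()}


def write_nrrd(path, array: np.ndarray, spacing=(1.0, 1.0, 1.0),
               content: str = "") -> None:
    """Write a 3D array as a raw-encoded NRRD file."""
    array = np.asarray(array)
    if array.ndim != 3:
        raise ValueError("write_nrrd expects a 3D array")
    dt = np.dtype(array.dtype)
    if dt not in _NAMES:
        array = array.astype(np.float64)
        dt = array.dtype
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    header = [
        "NRRD0004",
        f"# {content}" if content else "# cardioviz volume",
        f"type: {_NAMES[dt]}",
        "dimension: 3",
        f"sizes: {array.shape[0]} {array.shape[1]} {array.shape[2]}",
        f"spacings: {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}",
        "encoding: raw",
        "endian: little",
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(np.asfortranarray(array).tobytes(order="F"))


def read_nrrd(path):
    """Read a raw-encoded NRRD written by :func:`write_nrrd`.

    Returns ``(array, spacing)``.
    """
    data = pathlib.Path(path).read_bytes()
    end = data.find(b"\n\n")
    if end < 0:
        raise ValueError(f"{path}: no NRRD header terminator found")
    fields = {}
    lines = data[:end].decode("ascii").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    for line in lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw":
        raise ValueError(f"{path}: only raw encoding supported")
    if fields.get("endian", "little") != "little":
        raise ValueError(f"{path}: only little-endian supported")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if len(sizes) != 3:
        raise ValueError(f"{path}: expected a 3D volume")
    dtype = _DTYPES[fields["type"]]
    spacing = tuple(float(s) for s in fields.get("spacings", "1 1 1").split())
    raw = np.frombuffer(data[end + 2:], dtype=dtype)
    if raw.size != int(np.prod(sizes)):
        raise ValueError(f"{path}: data size mismatch")
    return raw.reshape(sizes, order="F").copy(), spacing


def write_raw(path_base, array: np.ndarray, spacing=(1.0, 1.0, 1.0),
              time_stamp_ms: float | None = None) -> None:
    """Write ``<base>.raw`` (C-order) plus ``<base>.txt`` sidecar header."""
    array = np.asarray(array)
    base = pathlib.Path(path_base)
    array.tofile(base.with_suffix(".raw"))
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (array.ndim,))
    lines = [
        f"dims: {' '.join(str(s) for s in array.shape)}",
        f"spacing_mm: {' '.join(f'{s:.9g}' for s in spacing)}",
        f"dtype: {array.dtype.name}",
        "order: C",
        f"written: {time.strftime('%Y-%m-%dT%H:%M:%S')}",
    ]
    if time_stamp_ms is not None:
        lines.append(f"time_ms: {time_stamp_ms:.9g}")
    base.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def read_raw(path_base):
    """Read a raw + sidecar pair; returns ``(array, spacing)``."""
    base = pathlib.Path(path_base)
    meta = {}
    for line in base.with_suffix(".txt").read_text().splitlines():
        key, val = line.split(":", 1)
        meta[key.strip()] = val.strip()
    shape = tuple(int(s) for s in meta["dims"].split())
    spacing = tuple(float(s) for s in meta["spacing_mm"].split())
    arr = np.fromfile(base.with_suffix(".raw"), dtype=np.dtype(meta["dtype"]))
    return arr.reshape(shape), spacing
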