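"""Minimal NRRD volume I/O (ASCII encoding).

Reads and writes NRRD0004 files with attached headers and ``encoding: ascii``,
which is all the expression-grid and label-mask interchange here needs.
Values are stored in C (row-major) order over the declared sizes; the axis
order convention is (x, y, z) with 0-based indices, recorded in the header
as a ``space`` comment.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

_TYPE_MAP = {
    "float": np.float32,
    "double": np.float64,
    "int": np.int32,
    "short": np.int16,
    "uchar": np.uint8,
    "unsigned char": np.uint8,
    "int32": np.int32,
    "int16": np.int16,
    "float32": np.float32,
    "float64": np.float64,
}


def write_nrrd(path: str | os.PathLike, array: np.ndarray,
               extra_fields: Mapping[str, str] | None = None) -> None:
    """Write ``array`` as an ASCII-encoded NRRD file."""
    array = np.asarray(array)
    if array.dtype.kind == "f":
        typ = "double"
        fmt = "%.17g"
    elif array.dtype.kind in "iu":
        typ = "int"
        fmt = "%d"
    else:
        raise ValueError(f"unsupported dtype {array.dtype}")
    lines = [
        "NRRD0004",
        "# produced by vtamosaic",
        f"type: {typ}",
        f"dimension: {array.ndim}",
        "sizes: " + " ".join(str(s) for s in array.shape),
        "encoding: ascii",
    ]
    for key, val in (extra_fields or {}).items():
        lines.append(f"{key}: {val}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
        fh.write("\n\n")  # blank line separates header from data
        flat = array.ravel(order="C")
        for start in range(0, flat.size, 8):
            fh.write(" ".join(fmt % v for v in flat[start:start + 8]))
            fh.write("\n")


def read_nrrd(path: str | os.PathLike) -> tuple[np.ndarray, dict[str, str]]:
    """Read an ASCII-encoded NRRD file; returns (array, header fields)."""
    with open(path, "r", encoding="utf-8") as fh:
        magic = fh.readline().strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not a NRRD file (magic {magic!r})")
        fields: dict[str, str] = {}
        for line in fh:
            line = line.rstrip("\n")
            if line == "":
                break
            if line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}: malformed header line {line!r}")
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
        if fields.get("encoding") != "ascii":
            raise ValueError(f"{path}: only ascii encoding is supported")
        shape = tuple(int(s) for s in fields["sizes"].split())
        dtype = _TYPE_MAP.get(fields.get("type", "double"))
        if dtype is None:
            raise ValueError(f"{path}: unsupported type {fields.get('type')!r}")
        data = np.array(fh.read().split(), dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"{path}: expected {int(np.prod(shape))} values, got {data.size}")
    return data.reshape(shape, order="C"), fields
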