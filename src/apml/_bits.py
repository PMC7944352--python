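"""Bit-array plumbing shared across modules.

Conventions (used everywhere in the package): binary objects are numpy
uint8 arrays with entries in {0, 1}; 2-D tensors are (rows, cols) with
row 0 the earliest time step; string keys are most-significant-bit-first
row-major renderings.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_bits",
    "bits_to_str",
    "str_to_bits",
    "ints_to_bits",
    "bits_to_int",
    "pack_rows",
]


def as_bits(obj) -> np.ndarray:
    """Coerce a bit string, list, or array into a uint8 {0,1} ndarray."""
    if isinstance(obj, np.ndarray) and obj.dtype == np.uint8:
        return obj  # hot path: trusted internal representation
    if isinstance(obj, str):
        if not set(obj) <= {"0", "1"}:
            raise ValueError(f"not a binary string: {obj!r}")
        return np.frombuffer(obj.encode(), dtype=np.uint8) - ord("0")
    arr = np.asarray(obj, dtype=np.uint8)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("entries must be 0 or 1")
    return arr


def bits_to_str(arr) -> str:
    """Row-major, MSB-first string rendering of a bit tensor."""
    flat = np.asarray(arr, dtype=np.uint8).ravel()
    return flat.tobytes().translate(_TO_CHAR).decode()


_TO_CHAR = bytes.maketrans(bytes([0, 1]), b"01")


def str_to_bits(s: str, shape=None) -> np.ndarray:
    arr = as_bits(s)
    return arr.reshape(shape) if shape is not None else arr


def ints_to_bits(values, width: int) -> np.ndarray:
    """Vectorized MSB-first binary expansion; shape (len(values), width)."""
    v = np.asarray(values, dtype=np.uint64)
    if v.size and int(v.max()) >= (1 << width):
        raise ValueError(f"value does not fit in {width} bits")
    shifts = np.arange(width - 1, -1, -1, dtype=np.uint64)
    return ((v[..., None] >> shifts) & np.uint64(1)).astype(np.uint8)


def bits_to_int(arr) -> int:
    flat = np.asarray(arr, dtype=np.uint64).ravel()
    out = 0
    for b in flat.tolist():
        out = (out << 1) | int(b)
    return out


def pack_rows(mat: np.ndarray) -> np.ndarray:
    """Pack each row of a (n, w) bit matrix (w <= 64) into a uint64 code."""
    mat = np.asarray(mat, dtype=np.uint64)
    w = mat.shape[-1]
    if w > 64:
        raise ValueError("row wider than 64 bits")
    shifts = np.arange(w - 1, -1, -1, dtype=np.uint64)
    return (mat << shifts).sum(axis=-1, dtype=np.uint64)
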