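"""One-hot encoding of sequences into the fixed 23x175 / 6x175 windows.

A sequence of length ``n`` is placed at a per-sequence deterministic offset
inside the middle 145 columns (columns 15..159, 0-based).  The start code
``J`` occupies the column immediately before the first residue and the end
code ``O`` the column immediately after the last; all remaining columns are
padding ``X``.  The offset is "random but consistent": it is derived from a
stable cryptographic hash of the sequence bytes and a global seed, never
from the interpreter's randomized string hash, so encodings are identical
across processes and runs.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .alphabets import (
    PRIMARY_EM,
    PRIMARY_EM_INDEX,
    SECONDARY,
    SECONDARY_INDEX,
    TOTAL_WIDTH,
    WINDOW_START,
    WINDOW_WIDTH,
)

__all__ = [
    "deterministic_offset",
    "encode_primary",
    "decode_primary",
    "encode_secondary",
    "decode_secondary",
]


def deterministic_offset(primary: str, global_seed: int = 0) -> int:
    """Stable pseudo-random placement offset for *primary*.

    Returns a column index in ``[15, 160 - len]`` (so the whole sequence
    fits in the middle-145 window), uniform over that range with respect to
    the SHA-256 hash of ``(global_seed, sequence)``.
    """
    n = len(primary)
    if n > WINDOW_WIDTH:
        raise ValueError(f"sequence length {n} exceeds window width {WINDOW_WIDTH}")
    span = WINDOW_WIDTH - n + 1  # number of legal placements
    digest = hashlib.sha256(f"{global_seed}:{primary}".encode()).digest()
    value = int.from_bytes(digest[:8], "big")
    return WINDOW_START + value % span


def _encode(seq: str, offset: int, alphabet: str, index: dict) -> np.ndarray:
    n = len(seq)
    if not WINDOW_START <= offset <= WINDOW_START + WINDOW_WIDTH - n:
        raise ValueError(f"offset {offset} illegal for length {n}")
    mat = np.zeros((len(alphabet), TOTAL_WIDTH), dtype=np.float64)
    mat[index["X"], :] = 1.0
    mat[index["X"], offset - 1 : offset + n + 1] = 0.0
    mat[index["J"], offset - 1] = 1.0
    mat[index["O"], offset + n] = 1.0
    for j, ch in enumerate(seq):
        try:
            row = index[ch]
        except KeyError:
            raise ValueError(f"symbol {ch!r} not in alphabet {alphabet}") from None
        mat[row, offset + j] = 1.0
    return mat


def encode_primary(primary: str, offset: int | None = None, global_seed: int = 0) -> tuple[np.ndarray, int]:
    """One-hot encode a primary sequence into a (23, 175) matrix.

    When *offset* is None, the deterministic per-sequence offset is used.
    Returns ``(matrix, offset)``.
    """
    if offset is None:
        offset = deterministic_offset(primary, global_seed)
    return _encode(primary, offset, PRIMARY_EM, PRIMARY_EM_INDEX), offset


def encode_secondary(secondary: str, offset: int) -> np.ndarray:
    """One-hot encode a secondary string over {L,E,H} into a (6, 175)
    matrix aligned column-for-column with its paired primary encoding."""
    return _encode(secondary, offset, SECONDARY, SECONDARY_INDEX)


def _decode(mat: np.ndarray, alphabet: str) -> tuple[str, int]:
    index = {c: i for i, c in enumerate(alphabet)}
    rows = np.argmax(mat, axis=0)
    if not np.allclose(mat.sum(axis=0), 1.0):
        raise ValueError("malformed encoding: columns must sum to 1")
    j_cols = np.flatnonzero(rows == index["J"])
    o_cols = np.flatnonzero(rows == index["O"])
    if len(j_cols) != 1 or len(o_cols) != 1:
        raise ValueError("malformed encoding: need exactly one J and one O column")
    start, end = j_cols[0] + 1, o_cols[0]
    seq = "".join(alphabet[rows[c]] for c in range(start, end))
    return seq, int(start)


def decode_primary(mat: np.ndarray) -> tuple[str, int]:
    """Inverse of :func:`encode_primary`; returns ``(sequence, offset)``."""
    return _decode(mat, PRIMARY_EM)


def decode_secondary(mat: np.ndarray) -> tuple[str, int]:
    """Inverse of :func:`encode_secondary` for binary matrices."""
    return _decode(mat, SECONDARY)
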