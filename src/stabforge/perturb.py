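"""The fourteen-type sequence-perturbation suite.

The perturbations fall into three classes, mirroring a stress test of
sequence-only stability predictors:

* single-site changes — substitution, insertion, deletion, and "central"
  variants of each that never touch the first or last ten residues;
* global rearrangements that preserve amino-acid composition — reversal
  and cyclic shifts by 1, 5, 10 and 20 residues;
* global compositional changes — keeping only the first half, the last
  half, or the even-indexed half of the sequence.

All randomness is drawn from a ``numpy`` generator seeded explicitly, so a
perturbation is reproducible from ``(sequence, type, seed)``.  The registry
is a plain dict so callers can add or replace types.
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np

from .alphabets import AMINO_ACIDS
from .design import ProteinDesign

CENTRAL_MARGIN = 10  # residues spared at each end by central perturbations


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _substitute(seq: str, pos: int, rng: np.random.Generator) -> str:
    choices = [a for a in AMINO_ACIDS if a != seq[pos]]
    return seq[:pos] + str(rng.choice(choices)) + seq[pos + 1 :]


def substitution(seq: str, seed: int) -> str:
    rng = _rng(seed)
    return _substitute(seq, int(rng.integers(len(seq))), rng)


def insertion(seq: str, seed: int) -> str:
    rng = _rng(seed)
    pos = int(rng.integers(len(seq) + 1))
    return seq[:pos] + str(rng.choice(list(AMINO_ACIDS))) + seq[pos:]


def deletion(seq: str, seed: int) -> str:
    rng = _rng(seed)
    pos = int(rng.integers(len(seq)))
    return seq[:pos] + seq[pos + 1 :]


def _central_span(n: int) -> tuple[int, int]:
    if n < 2 * CENTRAL_MARGIN + 1:
        raise ValueError(f"sequence of length {n} too short for a central perturbation")
    return CENTRAL_MARGIN, n - CENTRAL_MARGIN


def central_substitution(seq: str, seed: int) -> str:
    lo, hi = _central_span(len(seq))
    rng = _rng(seed)
    return _substitute(seq, int(rng.integers(lo, hi)), rng)


def central_insertion(seq: str, seed: int) -> str:
    lo, hi = _central_span(len(seq))
    rng = _rng(seed)
    pos = int(rng.integers(lo, hi + 1))
    return seq[:pos] + str(rng.choice(list(AMINO_ACIDS))) + seq[pos:]


def central_deletion(seq: str, seed: int) -> str:
    lo, hi = _central_span(len(seq))
    rng = _rng(seed)
    pos = int(rng.integers(lo, hi))
    return seq[:pos] + seq[pos + 1 :]


def reversal(seq: str, seed: int) -> str:
    return seq[::-1]


def _cyclic(n: int) -> Callable[[str, int], str]:
    def shift(seq: str, seed: int) -> str:
        if len(seq) <= n:
            raise ValueError(f"cyclic shift by {n} needs length > {n}")
        return seq[n:] + seq[:n]

    shift.__name__ = f"cyclic_shift_{n}"
    return shift


def half_first(seq: str, seed: int) -> str:
    return seq[: len(seq) // 2]


def half_last(seq: str, seed: int) -> str:
    return seq[len(seq) - len(seq) // 2 :]


def half_even(seq: str, seed: int) -> str:
    return seq[::2]


#: Registry of the fourteen perturbation types, keyed by name.
PERTURBATIONS: Dict[str, Callable[[str, int], str]] = {
    "substitution": substitution,
    "insertion": insertion,
    "deletion": deletion,
    "central_substitution": central_substitution,
    "central_insertion": central_insertion,
    "central_deletion": central_deletion,
    "reversal": reversal,
    "cyclic_shift_1": _cyclic(1),
    "cyclic_shift_5": _cyclic(5),
    "cyclic_shift_10": _cyclic(10),
    "cyclic_shift_20": _cyclic(20),
    "half_first": half_first,
    "half_last": half_last,
    "half_even": half_even,
}

assert len(PERTURBATIONS) == 14


def perturb(design: ProteinDesign, kind: str, seed: int = 0) -> ProteinDesign:
    """Apply one registered perturbation to *design*.

    Returns a new :class:`ProteinDesign` with provenance ``perturbed`` and
    no secondary string (the perturbed structure is unknown).
    """
    try:
        fn = PERTURBATIONS[kind]
    except KeyError:
        raise ValueError(f"unknown perturbation {kind!r}") from None
    return ProteinDesign(
        id=f"{design.id}|{kind}",
        primary=fn(design.primary, seed),
        secondary=None,
        design_class=design.design_class,
        provenance="perturbed",
    )
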