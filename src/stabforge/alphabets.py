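"""Fixed symbol alphabets for primary and secondary sequences.

Row orders are frozen so that one-hot matrix row indices are stable across
runs and checkpoints.  Three alphabets are used:

* ``PRIMARY_EM`` — 23 symbols consumed by the evaluator / unfolded-state
  models: the 20 amino acids plus ``X`` (padding), ``J`` (start) and ``O``
  (end-of-protein).
* ``SECONDARY`` — 6 symbols: ``L`` (loop), ``E`` (strand), ``H`` (helix)
  and the same ``X``/``J``/``O`` flanking codes.
* ``PRIMARY_GM`` — the generator's output vocabulary: 19 amino acids
  (cysteine excluded, because disulfide bonds confound the protease assay)
  plus a stop token.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"  # 20 canonical residues, sorted
PAD, START, STOP = "X", "J", "O"

PRIMARY_EM: str = AMINO_ACIDS + PAD + START + STOP          # 23 symbols
SECONDARY: str = "LEH" + PAD + START + STOP                  # 6 symbols
GM_STOP = "$"
PRIMARY_GM: str = AMINO_ACIDS.replace("C", "") + GM_STOP     # 19 AAs + stop

PRIMARY_EM_INDEX = {c: i for i, c in enumerate(PRIMARY_EM)}
SECONDARY_INDEX = {c: i for i, c in enumerate(SECONDARY)}
PRIMARY_GM_INDEX = {c: i for i, c in enumerate(PRIMARY_GM)}

#: Hydrophobic residue class; shared by the patterned-scramble generator and
#: the strictest refinement constraint preset.
HYDROPHOBIC = frozenset("AFILMVWY")

#: Encoding geometry: sequences sit inside the middle 145 columns of a
#: 175-column window (columns 15..159, 0-based), flanked by J/O and X padding.
TOTAL_WIDTH = 175
WINDOW_START = 15
WINDOW_WIDTH = 145


def validate_primary(seq: str, allow_cysteine: bool = True) -> str:
    """Check that *seq* contains only canonical residues; return it."""
    allowed = set(AMINO_ACIDS) if allow_cysteine else set(AMINO_ACIDS) - {"C"}
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"illegal primary-sequence symbols: {sorted(bad)}")
    return seq


def validate_secondary(seq: str) -> str:
    """Check that *seq* is a string over {L, E, H}; return it."""
    bad = set(seq) - set("LEH")
    if bad:
        raise ValueError(f"illegal secondary-sequence symbols: {sorted(bad)}")
    return seq
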