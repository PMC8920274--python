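"""Synthetic mini-protein corpus generator.

Emulates the structure of a protease-resistance design corpus so that every
stage of the pipeline — USM training, stability scoring, evaluator and
generator training, refinement, cross-chip calibration — can run offline
with known ground truth:

* designs 25–65 residues long over a handful of secondary-structure
  topologies (orderings of helices and strands joined by loops);
* primary sequences sampled with position-class-dependent residue
  distributions: helix/strand positions hydrophobic-biased, loops
  hydrophilic with glycine/proline enrichment.  A per-design corruption
  rate ``q`` swaps residues to the wrong class, spreading pattern quality;
* full and "patterned" scrambles as controls;
* per-protease EC50 = unfolded baseline (a linear function of
  cleavage-prone residue content) + folded protection (a clipped linear
  function of pattern-match quality; ~0 for scrambles) + Gaussian noise,
  optionally compressed by a soft assay ceiling;
* paired "chip" tables sharing ladder designs, with injected linear
  distortions and ceiling compression for calibration tests.

Everything is reproducible bit-for-bit from ``(SynthConfig, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alphabets import HYDROPHOBIC
from .design import CHYMOTRYPSIN, TRYPSIN, ProteinDesign

__all__ = [
    "SynthConfig", "expand_topology", "generate_design", "make_scramble",
    "pattern_match_fraction", "latent_protection", "simulate_assay",
    "make_ladder_chips", "generate_corpus",
]

# residue pools (no cysteine anywhere: the assay cannot use it and the
# generator vocabulary excludes it)
HYDROPHOBIC_POOL = sorted(HYDROPHOBIC)                    # A F I L M V W Y
HYDROPHILIC_POOL = sorted(set("DEGHKNPQRST"))             # 11 residues
LOOP_WEIGHTS = np.array([3.0 if r in "GP" else 1.0 for r in HYDROPHILIC_POOL])
LOOP_WEIGHTS = LOOP_WEIGHTS / LOOP_WEIGHTS.sum()


@dataclass
class SynthConfig:
    n_designs: int = 2000
    length_range: Tuple[int, int] = (25, 65)
    topologies: Tuple[str, ...] = ("HHH", "EHEE", "HEEH", "EEHEE")
    hydrophobic_bias: float = 0.9     # P(hydrophobic | helix/strand, uncorrupted)
    corruption_max: float = 0.5       # per-design q ~ U(0, corruption_max)
    # unfolded baselines: intercept - slope * cleavage-prone fraction
    trypsin_baseline: Tuple[float, float] = (3.0, 4.0)        # K/R content
    chymotrypsin_baseline: Tuple[float, float] = (3.2, 3.0)   # F/Y/W/L content
    # protection = scale * clip((m - m0) / (1 - m0), 0, 1)
    protection_scale: float = 2.5
    protection_floor: float = 0.70
    noise_sigma: float = 0.1
    ci_sigma: float = 0.55            # log-normal CI widths, ~10% exceed 2
    ceiling: Optional[Tuple[float, float]] = None   # (c, s) soft upper limit
    seed: int = 0


def expand_topology(topology: str, length: int, rng: np.random.Generator) -> str:
    """Random secondary string realizing *topology* at exactly *length*.

    Elements get typical sizes (helices 8–14, strands 5–8) separated and
    flanked by loops of at least two residues; loop lengths absorb the
    remainder.
    """
    sizes = [int(rng.integers(8, 15)) if t == "H" else int(rng.integers(5, 9))
             for t in topology]
    n_loops = len(topology) + 1
    slack = length - sum(sizes) - 2 * n_loops
    while slack < 0:  # shrink the largest element until the length fits
        i = int(np.argmax(sizes))
        minimum = 8 if topology[i] == "H" else 5
        if sizes[i] <= minimum:
            sizes[i] -= 1  # allow going below typical size as a last resort
        else:
            sizes[i] -= 1
        slack = length - sum(sizes) - 2 * n_loops
        if min(sizes) < 3:
            raise ValueError(f"topology {topology} cannot fit length {length}")
    extra = rng.multinomial(slack, np.ones(n_loops) / n_loops)
    loops = [2 + int(e) for e in extra]
    parts = [loops[0] * "L"]
    for t, size, loop in zip(topology, sizes, loops[1:]):
        parts.append(t * size)
        parts.append(loop * "L")
    out = "".join(parts)
    assert len(out) == length
    return out


def _sample_residue(symbol: str, q: float, bias: float,
                    rng: np.random.Generator) -> str:
    prefer_hydrophobic = symbol in "HE"
    if rng.random() < q:  # corrupted position: draw from the wrong class
        prefer_hydrophobic = not prefer_hydrophobic
    if prefer_hydrophobic:
        if rng.random() < bias:
            return str(rng.choice(HYDROPHOBIC_POOL))
        return str(rng.choice(HYDROPHILIC_POOL))
    if symbol == "L":
        return str(rng.choice(HYDROPHILIC_POOL, p=LOOP_WEIGHTS))
    return str(rng.choice(HYDROPHILIC_POOL))


def generate_design(secondary: str, seed: int, design_id: str = "design",
                    corruption: float = 0.0, design_class: str = "",
                    hydrophobic_bias: float = 0.9) -> ProteinDesign:
    """Sample a primary sequence conditioned on *secondary*.

    ``corruption`` is the per-position probability of drawing from the
    wrong residue class; it is the knob that spreads latent stability.
    """
    rng = np.random.default_rng(seed)
    primary = "".join(_sample_residue(s, corruption, hydrophobic_bias, rng)
                      for s in secondary)
    return ProteinDesign(id=design_id, primary=primary, secondary=secondary,
                         design_class=design_class, provenance="expert")


def make_scramble(design: ProteinDesign, mode: str, seed: int) -> ProteinDesign:
    """Scramble a design: ``full`` permutes all residues uniformly;
    ``patterned`` permutes within the hydrophobic and within the
    hydrophilic class, leaving every G and P at its original index."""
    rng = np.random.default_rng(seed)
    residues = list(design.primary)
    if mode == "full":
        rng.shuffle(residues)
    elif mode == "patterned":
        groups = {
            "hydrophobic": [i for i, r in enumerate(residues) if r in HYDROPHOBIC],
            "hydrophilic": [i for i, r in enumerate(residues)
                            if r not in HYDROPHOBIC and r not in "GP"],
        }
        for indices in groups.values():
            perm = rng.permutation(len(indices))
            vals = [residues[i] for i in indices]
            for i, p in zip(indices, perm):
                residues[i] = vals[p]
    else:
        raise ValueError(f"unknown scramble mode {mode!r}")
    return ProteinDesign(id=f"{design.id}|scramble_{mode}",
                         primary="".join(residues), secondary=design.secondary,
                         design_class=design.design_class, provenance="scramble")


def pattern_match_fraction(primary: str, secondary: str) -> float:
    """Fraction of positions whose residue class (hydrophobic vs not)
    matches the class preferred by the secondary symbol at that position."""
    if len(primary) != len(secondary):
        raise ValueError("primary/secondary length mismatch")
    hits = sum((r in HYDROPHOBIC) == (s in "HE")
               for r, s in zip(primary, secondary))
    return hits / len(primary)


def latent_protection(primary: str, secondary: str,
                      config: SynthConfig) -> float:
    """Ground-truth folded protection: a clipped linear map of the
    pattern-match fraction onto [0, protection_scale].

    The onset ``protection_floor`` sits well above the match fraction of a
    fully scrambled sequence (~0.5), emulating the cooperativity of
    folding: incoherent chains live on a wide flat-zero plateau where no
    handful of substitutions can create protection, while designed
    sequences sit on a smooth slope where individual corrections pay off.
    """
    m = pattern_match_fraction(primary, secondary)
    m0 = config.protection_floor
    return config.protection_scale * float(np.clip((m - m0) / (1.0 - m0), 0.0, 1.0))


def _baseline(primary: str, intercept: float, slope: float, residues: str) -> float:
    frac = sum(c in residues for c in primary) / len(primary)
    return intercept - slope * frac


def unfolded_baseline(primary: str, protease: str, config: SynthConfig) -> float:
    """True unfolded-state EC50 used by the simulator, per protease."""
    if protease == TRYPSIN:
        a, b = config.trypsin_baseline
        return _baseline(primary, a, b, "KR")
    a, b = config.chymotrypsin_baseline
    return _baseline(primary, a, b, "FYWL")


def _compress(value: float, ceiling: Optional[Tuple[float, float]]) -> float:
    if ceiling is None:
        return value
    c, s = ceiling
    return value if value <= c else c + s * (value - c)


def simulate_assay(designs: Sequence[ProteinDesign], config: SynthConfig,
                   seed: Optional[int] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-protease EC50 tables for *designs*.

    Returns ``(assay, truth)`` DataFrames indexed by design id.  ``assay``
    has observed EC50s and credible-interval widths per protease; ``truth``
    records the latent baseline and protection per design.  Scrambles get
    exactly zero protection, mirroring the near-zero stability scores of
    assay controls.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    assay_rows, truth_rows = [], []
    for d in designs:
        protection = 0.0 if d.provenance == "scramble" else latent_protection(
            d.primary, d.secondary, config)
        row = {"id": d.id}
        truth = {"id": d.id, "protection": protection,
                 "match_fraction": pattern_match_fraction(d.primary, d.secondary)}
        for protease in (TRYPSIN, CHYMOTRYPSIN):
            base = unfolded_baseline(d.primary, protease, config)
            observed = (_compress(base + protection, config.ceiling)
                        + rng.normal(0.0, config.noise_sigma))
            ci = float(np.exp(rng.normal(0.0, config.ci_sigma)))
            row[f"{protease}_ec50"] = observed
            row[f"{protease}_ci"] = ci
            truth[f"{protease}_baseline"] = base
        assay_rows.append(row)
        truth_rows.append(truth)
    assay = pd.DataFrame(assay_rows).set_index("id")
    truth = pd.DataFrame(truth_rows).set_index("id")
    return assay, truth


def make_ladder_chips(designs: Sequence[ProteinDesign], config: SynthConfig,
                      distortion: Tuple[float, float] = (1.2, -0.4),
                      n_ladder: int = 20,
                      vector_map: Optional[Tuple[float, float]] = None,
                      noise: float = 0.0,
                      seed: Optional[int] = None
                      ) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Two chip tables sharing ladder designs.

    Chip A is the reference assay of *designs*; chip B re-measures the same
    designs through a linear distortion ``slope * value + intercept`` (per
    protease), optionally followed by a piecewise ceiling map ``(c, s)``
    emulating a different expression vector, plus Gaussian noise.  The
    *n_ladder* ladder designs are chosen to span the chip-A EC50 range.
    """
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    chip_a, _ = simulate_assay(designs, config, seed=int(rng.integers(2**31)))
    slope, intercept = distortion
    chip_b = chip_a.copy()
    for protease in (TRYPSIN, CHYMOTRYPSIN):
        col = f"{protease}_ec50"
        vals = slope * chip_a[col].to_numpy() + intercept
        if vector_map is not None:
            c, s = vector_map
            vals = np.where(vals <= c, vals, c + s * (vals - c))
        chip_b[col] = vals + rng.normal(0.0, noise, size=len(vals))
    # ladder: spread across the observed range of chip A
    order = chip_a["trypsin_ec50"].sort_values()
    pick = np.linspace(0, len(order) - 1, num=min(n_ladder, len(order))).astype(int)
    ladder_ids = [str(order.index[i]) for i in pick]
    return chip_a, chip_b, ladder_ids


def generate_corpus(config: SynthConfig, n_scrambles: Optional[int] = None,
                    n_naturals: int = 0) -> Dict[str, object]:
    """Generate a full corpus: designs, scrambles, assay and truth tables.

    Designs are split across topologies; ``design_class`` combines the
    topology and a coarse length band, supplying labels for held-out-class
    evaluation.  ``naturals`` are uncorrupted patterned sequences standing
    in for natural proteins (unlabeled, comparator stream only).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    designs: List[ProteinDesign] = []
    for i in range(config.n_designs):
        topo = config.topologies[i % len(config.topologies)]
        min_len = max(lo, sum(8 if t == "H" else 5 for t in topo)
                      + 2 * (len(topo) + 1) + 1)
        length = int(rng.integers(min_len, hi + 1))
        secondary = expand_topology(topo, length, rng)
        q = float(rng.uniform(0.0, config.corruption_max))
        d = generate_design(
            secondary, seed=int(rng.integers(2**31)), design_id=f"d{i:05d}",
            corruption=q, hydrophobic_bias=config.hydrophobic_bias,
            design_class=f"{topo}/{'short' if length < (lo + hi) // 2 else 'long'}")
        designs.append(d)
    if n_scrambles is None:
        n_scrambles = config.n_designs // 4
    scrambles = []
    for j in range(n_scrambles):
        base = designs[int(rng.integers(len(designs)))]
        mode = "full" if j % 2 == 0 else "patterned"
        scr = make_scramble(base, mode, seed=int(rng.integers(2**31)))
        scr.id = f"s{j:05d}|{scr.id}"
        scrambles.append(scr)
    naturals = []
    for k in range(n_naturals):
        topo = config.topologies[k % len(config.topologies)]
        length = int(rng.integers(max(lo, 30), hi + 1))
        secondary = expand_topology(topo, length, rng)
        nat = generate_design(secondary, seed=int(rng.integers(2**31)),
                              design_id=f"nat{k:05d}", corruption=0.05,
                              hydrophobic_bias=config.hydrophobic_bias)
        nat.provenance = "natural"
        naturals.append(nat)
    assay, truth = simulate_assay(list(designs) + list(scrambles), config,
                                  seed=config.seed + 1)
    return {"designs": designs, "scrambles": scrambles, "naturals": naturals,
            "assay": assay, "truth": truth, "config": config}
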