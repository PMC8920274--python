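"""Beam-search single-site refinement under constraints.

Starting from a sequence, each round enumerates every single-residue
substitution of every current base, filters them through the active
constraints, scores the pool with a pluggable scorer (the evaluator's
combined stability score by default), records the top-1 as that round's
product and carries the top-k forward as new bases.  Ties are broken by
mutation position, then replacement letter, so refinement is reproducible.

Constraint presets mirror increasingly strict refinement regimes:
no constraints; no tryptophan; no hydrophobics (A,F,I,L,M,V,W,Y); each
optionally combined with a requirement that neither protease's
USM-predicted unfolded-state EC50 decreases relative to the reference
(immediate parent by default, or the round-0 original).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .alphabets import AMINO_ACIDS, HYDROPHOBIC
from .design import PROTEASES

__all__ = [
    "RefinementConstraints", "enumerate_substitutions", "beam_refine",
    "random_substitutions", "substitution_effect_matrix", "RefinementResult",
]

Scorer = Callable[[Sequence[str]], np.ndarray]


@dataclass
class RefinementConstraints:
    forbidden_targets: frozenset = frozenset()
    require_usm_nondecrease: bool = False
    usm_reference: str = "parent"       # or "original"

    NO_W = frozenset("W")
    NO_HYDROPHOBIC = frozenset(HYDROPHOBIC)

    def __post_init__(self) -> None:
        if not self.forbidden_targets <= set(AMINO_ACIDS):
            raise ValueError("forbidden targets must be amino acids")
        if self.usm_reference not in ("parent", "original"):
            raise ValueError("usm_reference must be 'parent' or 'original'")


@dataclass
class Candidate:
    sequence: str
    position: int
    replacement: str


def enumerate_substitutions(seq: str,
                            constraints: Optional[RefinementConstraints] = None,
                            usm_model=None,
                            usm_reference_seq: Optional[str] = None
                            ) -> List[Candidate]:
    """All single-site substitutions of *seq* allowed by *constraints*.

    Without constraints this is ``len(seq) * 19`` candidates.  With the
    USM-nondecrease flag, candidates whose predicted unfolded-state EC50
    drops below the reference sequence's prediction for either protease
    are removed (this needs ``usm_model``).
    """
    constraints = constraints or RefinementConstraints()
    cands = [
        Candidate(seq[:i] + aa + seq[i + 1 :], i, aa)
        for i in range(len(seq))
        for aa in AMINO_ACIDS
        if aa != seq[i] and aa not in constraints.forbidden_targets
    ]
    if constraints.require_usm_nondecrease:
        if usm_model is None:
            raise ValueError("USM-nondecrease constraint needs a usm_model")
        ref_seq = usm_reference_seq or seq
        keep = np.ones(len(cands), dtype=bool)
        for protease in PROTEASES:
            ref = usm_model.predict([ref_seq], protease)[0]
            preds = usm_model.predict([c.sequence for c in cands], protease)
            keep &= preds >= ref - 1e-12
        cands = [c for c, k in zip(cands, keep) if k]
    return cands


@dataclass
class RefinementResult:
    products: List[str]                 # best sequence per completed round
    scores: List[float]                 # predicted score of each product
    n_substitutions: List[int]          # Hamming distance to the original
    completed_rounds: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def beam_refine(seq: str, scorer: Scorer, k: int = 50, rounds: int = 5,
                constraints: Optional[RefinementConstraints] = None,
                usm_model=None) -> RefinementResult:
    """Iterative constrained beam search over single-site substitutions.

    Each round pools the constrained substitutions of all current bases,
    deduplicates, and ranks by ``scorer`` (higher is better; ties broken
    by mutation position then replacement letter).  The top sequence is
    the round's product; the top *k* become the next bases.
    """
    constraints = constraints or RefinementConstraints()
    original = seq
    bases = [seq]
    products: List[str] = []
    scores: List[float] = []
    for rnd in range(rounds):
        pool: Dict[str, Tuple[int, str]] = {}
        for base in bases:
            ref = original if constraints.usm_reference == "original" else base
            for c in enumerate_substitutions(base, constraints, usm_model, ref):
                key = (c.position, c.replacement)
                if c.sequence not in pool or key < pool[c.sequence]:
                    pool[c.sequence] = key
        if not pool:
            break
        seqs = list(pool)
        vals = np.asarray(scorer(seqs), dtype=float)
        order = sorted(range(len(seqs)),
                       key=lambda i: (-vals[i], pool[seqs[i]]))
        products.append(seqs[order[0]])
        scores.append(float(vals[order[0]]))
        bases = [seqs[i] for i in order[:k]]
    return RefinementResult(
        products=products, scores=scores,
        n_substitutions=[_hamming(p, original) for p in products],
        completed_rounds=len(products))


def random_substitutions(seq: str, n_rounds: int,
                         constraints: Optional[RefinementConstraints] = None,
                         seed: int = 0, usm_model=None) -> List[str]:
    """Control arm: one uniformly random constrained substitution per
    round; returns the sequence after each round."""
    constraints = constraints or RefinementConstraints()
    rng = np.random.default_rng(seed)
    out: List[str] = []
    current = seq
    for _ in range(n_rounds):
        cands = enumerate_substitutions(current, constraints, usm_model)
        if not cands:
            break
        current = cands[int(rng.integers(len(cands)))].sequence
        out.append(current)
    return out


def substitution_effect_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Compare guided and random substitution effects per (from, to) pair.

    *records* needs columns ``from_aa, to_aa, condition, delta`` with
    condition in {"guided", "random"} and delta the stability-score change.
    Returns one row per (from, to) pair with per-condition means and
    counts, their difference, and a Welch two-sample two-tailed t-test
    p-value (NaN when either condition has fewer than two samples), plus
    per-residue marginal means merged in.
    """
    required = {"from_aa", "to_aa", "condition", "delta"}
    if records.empty or not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    rows = []
    for (f, t), grp in records.groupby(["from_aa", "to_aa"]):
        guided = grp.loc[grp.condition == "guided", "delta"].to_numpy()
        random_ = grp.loc[grp.condition == "random", "delta"].to_numpy()
        mean_g = guided.mean() if len(guided) else np.nan
        mean_r = random_.mean() if len(random_) else np.nan
        if len(guided) >= 2 and len(random_) >= 2:
            p = float(stats.ttest_ind(guided, random_, equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append({"from_aa": f, "to_aa": t,
                     "mean_guided": mean_g, "mean_random": mean_r,
                     "difference": mean_g - mean_r,
                     "n_guided": len(guided), "n_random": len(random_),
                     "p_value": p})
    out = pd.DataFrame(rows)
    from_marginal = out.groupby("from_aa").apply(
        lambda g: np.average(g["difference"].fillna(0),
                             weights=g["n_guided"] + g["n_random"]),
        include_groups=False).rename("from_marginal")
    to_marginal = out.groupby("to_aa").apply(
        lambda g: np.average(g["difference"].fillna(0),
                             weights=g["n_guided"] + g["n_random"]),
        include_groups=False).rename("to_marginal")
    out = out.merge(from_marginal, on="from_aa").merge(to_marginal, on="to_aa")
    return out
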