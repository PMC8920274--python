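"""Constrained beam-search refinement, with brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stabforge.alphabets import AMINO_ACIDS
from stabforge.refine import (
    RefinementConstraints,
    beam_refine,
    enumerate_substitutions,
    random_substitutions,
    substitution_effect_matrix,
)
from stabforge.usm import USMConfig, USMModel


def count_w(seqs):
    return np.array([s.count("W") for s in seqs], dtype=float)


def brute_force_best(seq, scorer, max_subs, constraints=None):
    """Enumerate every sequence within *max_subs* substitutions and return
    the best (scorer, then position/replacement order of first difference)."""
    allowed = [a for a in AMINO_ACIDS
               if constraints is None or a not in constraints.forbidden_targets]
    variants = {seq}
    frontier = {seq}
    for _ in range(max_subs):
        new = set()
        for s in frontier:
            for i, aa in itertools.product(range(len(s)), allowed):
                if aa != s[i]:
                    new.add(s[:i] + aa + s[i + 1 :])
        variants |= new
        frontier = new
    variants.discard(seq)
    ranked = sorted(variants,
                    key=lambda s: (-float(scorer([s])[0]), _mutkey(seq, s)))
    return ranked[0]


def _mutkey(origin, s):
    diffs = [(i, c) for i, (a, c) in enumerate(zip(origin, s)) if a != c]
    return diffs


class TestEnumerate:
    def test_unconstrained_count(self):
        cands = enumerate_substitutions("A" * 40)
        assert len(cands) == 40 * 19

    def test_forbidden_target_excluded(self):
        constraints = RefinementConstraints(forbidden_targets=frozenset("W"))
        cands = enumerate_substitutions("ACDEF", constraints)
        assert all("W" not in c.sequence for c in cands)
        assert len(cands) == 5 * 18

    def test_usm_nondecrease_filters_k_removals(self):
        """With a USM that scores K content, removing a K is filtered."""
        from stabforge.alphabets import PRIMARY_EM_INDEX
        model = USMModel.initialize(USMConfig(n_kernels=1, kernel_width=1))
        for net in model.nets.values():
            net.conv.w.data[:] = 0.0
            net.conv.b.data[:] = 0.0
            net.head.w.data[:] = 0.0
            net.head.b.data[:] = 0.0
            net.conv.w.data[0, PRIMARY_EM_INDEX["K"], 0] = 1.0
            net.head.w.data[0, 0] = 1.0
        constraints = RefinementConstraints(require_usm_nondecrease=True)
        cands = enumerate_substitutions("KAA", constraints, usm_model=model)
        # max-pool of the K indicator: any sequence keeping >= 1 K passes
        assert all("K" in c.sequence for c in cands)
        assert any(c.position != 0 for c in cands)


class TestBeamRefine:
    def test_one_round_tiebreak(self):
        res = beam_refine("AAA", count_w, k=1, rounds=1)
        assert res.products == ["WAA"]  # ties broken by position then letter

    def test_two_rounds(self):
        res = beam_refine("AAA", count_w, k=1, rounds=2)
        assert res.products[1] == "WWA"
        assert res.n_substitutions == [1, 2]

    def test_product_scores_nondecreasing(self):
        rng = np.random.default_rng(0)
        weights = rng.normal(size=(26,))

        def scorer(seqs):
            return np.array([sum(weights[ord(c) - 65] for c in s) for s in seqs])

        res = beam_refine("ACDEFG", scorer, k=3, rounds=4)
        assert all(b >= a - 1e-12 for a, b in zip(res.scores, res.scores[1:]))

    @pytest.mark.parametrize("scorer_id", range(3))
    def test_unbounded_beam_matches_bruteforce(self, scorer_id):
        """With k >= pool size, two beam rounds find the global best
        two-substitution variant under additive scorers (oracle check)."""
        rng = np.random.default_rng(scorer_id)
        table = rng.normal(size=(6, 26))

        def scorer(seqs):
            return np.array([sum(table[i, ord(c) - 65] for i, c in enumerate(s))
                             for s in seqs])

        seq = "ACDEFG"
        res = beam_refine(seq, scorer, k=10**9, rounds=2)
        assert res.products[1] == brute_force_best(seq, scorer, 2)

    def test_constraints_respected_in_every_round(self):
        constraints = RefinementConstraints(
            forbidden_targets=RefinementConstraints.NO_HYDROPHOBIC)
        res = beam_refine("GGGG", count_w, k=5, rounds=3,
                          constraints=constraints)
        for p in res.products:
            assert not (set(p) & set("AFILMVWY"))

    def test_all_filtered_stops_early(self):
        constraints = RefinementConstraints(
            forbidden_targets=frozenset(set(AMINO_ACIDS) - {"G"}))
        res = beam_refine("GGG", count_w, k=2, rounds=4,
                          constraints=constraints)
        assert res.completed_rounds == 0


class TestRandomArm:
    def test_one_change_per_round(self):
        steps = random_substitutions("ACDEFGHIKL", 4, seed=3)
        seqs = ["ACDEFGHIKL"] + steps
        for a, b in zip(seqs, seqs[1:]):
            assert sum(x != y for x, y in zip(a, b)) == 1

    def test_forbidden_targets_never_appear(self):
        constraints = RefinementConstraints(
            forbidden_targets=frozenset(set(AMINO_ACIDS) - {"P"}))
        steps = random_substitutions("GGGGG", 3, constraints, seed=1)
        assert all(set(s) <= {"G", "P"} for s in steps)

    def test_positions_uniform(self):
        counts = np.zeros(8)
        for seed in range(2000):
            step = random_substitutions("ACDEFGHI", 1, seed=seed)[0]
            pos = next(i for i, (a, b) in enumerate(zip("ACDEFGHI", step))
                       if a != b)
            counts[pos] += 1
        chi2 = ((counts - 250.0) ** 2 / 250.0).sum()
        # 3-sigma-ish bound for chi-square with 7 dof
        assert chi2 < 7 + 3 * np.sqrt(14)


class TestEffectMatrix:
    def build(self, mean_g, mean_r, n=30, sigma=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cond, mu in (("guided", mean_g), ("random", mean_r)):
            for _ in range(n):
                rows.append({"from_aa": "K", "to_aa": "W", "condition": cond,
                             "delta": rng.normal(mu, sigma)})
        return pd.DataFrame(rows)

    def test_null_case(self):
        out = substitution_effect_matrix(self.build(0.1, 0.1, seed=4))
        row = out.iloc[0]
        assert abs(row.difference) < 0.05
        assert row.p_value > 0.05

    def test_constructed_separation(self):
        out = substitution_effect_matrix(self.build(0.3, -0.1))
        row = out.iloc[0]
        assert row.difference == pytest.approx(0.4, abs=0.05)
        assert row.p_value < 0.001

    def test_small_cells_flagged_nan(self):
        df = pd.DataFrame([
            {"from_aa": "A", "to_aa": "V", "condition": "guided", "delta": 0.1},
            {"from_aa": "A", "to_aa": "V", "condition": "random", "delta": 0.2},
        ])
        out = substitution_effect_matrix(df)
        assert np.isnan(out.iloc[0].p_value)

    def test_marginal_is_weighted_mean_of_cells(self):
        df = pd.concat([self.build(0.3, 0.0, n=10, seed=1),
                        self.build(0.1, 0.0, n=10, seed=2)])
        df.loc[df.index[-20:], "to_aa"] = "F"
        out = substitution_effect_matrix(df)
        expected = np.average(out["difference"],
                              weights=out["n_guided"] + out["n_random"])
        assert out["from_marginal"].iloc[0] == pytest.approx(expected)
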