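"""Generator model: perplexity calibration, beam decoding, CER, subsets."""

import numpy as np
import pytest

from stabforge.design import ProteinDesign
from stabforge.generator import (
    GMConfig,
    OraclePredictor,
    TranslationPair,
    UniformPredictor,
    beam_decode,
    cer,
    greedy_decode,
    perplexity,
    select_by_secondary_agreement,
    stability_weighted_subset,
    train_gm,
    train_reverse_gm,
)

MAPPING = {"L": "G", "E": "V", "H": "A"}


def toy_pairs(n, seed=0, lengths=(10, 20)):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        sec = "".join(rng.choice(list("LEH"), int(rng.integers(*lengths))))
        out.append(TranslationPair(sec, "".join(MAPPING[s] for s in sec)))
    return out


@pytest.fixture(scope="module")
def toy_model():
    model, losses = train_gm(toy_pairs(300), GMConfig(iterations=12, seed=0))
    return model, losses


class TestPerplexityCalibration:
    PAIRS = toy_pairs(5, seed=9)

    def test_uniform_predictor_scores_vocabulary_size(self):
        assert perplexity(UniformPredictor(), self.PAIRS) == pytest.approx(19.0)

    def test_perfect_predictor_scores_one(self):
        assert perplexity(OraclePredictor(), self.PAIRS) == pytest.approx(1.0)

    def test_half_probability_scores_two(self):
        class Half(UniformPredictor):
            def forced_log_probs(self, src, tgt):
                return np.full(len(tgt), np.log(0.5))

        assert perplexity(Half(), self.PAIRS) == pytest.approx(2.0)

    def test_empty_pair_set_raises(self):
        with pytest.raises(ValueError):
            perplexity(UniformPredictor(), [])


class TestTraining:
    def test_loss_decreases_and_memorizes_toy_rule(self, toy_model):
        model, losses = toy_model
        assert losses[-1] < losses[0]
        # positional rule over a 4-symbol sub-vocabulary: chance would be 19
        assert perplexity(model, toy_pairs(40, seed=5)) < 4.0

    def test_positional_rule_learned(self):
        """Residue = f(symbol, position mod 2): needs position awareness."""
        rng = np.random.default_rng(1)
        pools = {"L": "GN", "E": "VI", "H": "AK"}
        pairs = []
        for _ in range(400):
            sec = "".join(rng.choice(list("LEH"), int(rng.integers(10, 16))))
            pri = "".join(pools[s][i % 2] for i, s in enumerate(sec))
            pairs.append(TranslationPair(sec, pri))
        model, _ = train_gm(pairs, GMConfig(iterations=15, seed=1))
        assert perplexity(model, pairs[:40]) < 4.0

    def test_cysteine_pairs_rejected(self):
        with pytest.raises(ValueError):
            TranslationPair("LL", "CC")


class TestBeamDecode:
    def test_width_and_lengths(self, toy_model):
        model, _ = toy_model
        out = beam_decode(model, "LLEEHHLL", width=5)
        assert len(out) == 5
        assert all(len(s) == 8 for s, _ in out)

    def test_log_probs_non_increasing_and_nonpositive(self, toy_model):
        model, _ = toy_model
        out = beam_decode(model, "LEHLEH", width=5)
        lps = [lp for _, lp in out]
        assert all(a >= b for a, b in zip(lps, lps[1:]))
        assert all(lp <= 0 for lp in lps)

    def test_beam_one_equals_greedy(self, toy_model):
        model, _ = toy_model
        assert beam_decode(model, "LLEEHH", width=1)[0][0] == \
            greedy_decode(model, "LLEEHH")

    def test_no_cysteine_or_stop_in_outputs(self, toy_model):
        model, _ = toy_model
        for s, _ in beam_decode(model, "LEHHEL", width=5):
            assert "C" not in s and "$" not in s

    def test_unbounded_width_matches_exhaustive_enumeration(self, toy_model):
        """On a length-2 input, a beam wider than |V|^2 must equal the
        brute-force top-k of all two-residue sequences."""
        model, _ = toy_model
        sec = "LE"
        vocab = model.tgt_vocab.replace("$", "")
        scored = []
        for a in vocab:
            for b in vocab:
                lp = model.forced_log_probs(sec, a + b).sum()
                scored.append((a + b, float(lp)))
        scored.sort(key=lambda x: (-x[1], x[0]))
        beam = beam_decode(model, sec, width=len(vocab) ** 2 + 1)
        assert [s for s, _ in beam[:10]] == [s for s, _ in scored[:10]]
        np.testing.assert_allclose([lp for _, lp in beam[:10]],
                                   [lp for _, lp in scored[:10]], atol=1e-9)

    def test_empty_secondary_raises(self, toy_model):
        model, _ = toy_model
        with pytest.raises(ValueError):
            beam_decode(model, "", width=5)


class TestReverseGM:
    @pytest.fixture(scope="class")
    def reverse(self):
        model, losses = train_reverse_gm(toy_pairs(300, seed=2),
                                         GMConfig(iterations=12, seed=2))
        return model, losses

    def test_loss_decreases(self, reverse):
        _, losses = reverse
        assert losses[-1] < losses[0]

    def test_predicts_secondary_of_held_out_primaries(self, reverse):
        model, _ = reverse
        errors = [cer(greedy_decode(model, p.primary), p.secondary)
                  for p in toy_pairs(20, seed=7)]
        assert np.mean(errors) < 0.05

    def test_selection_recovers_planted_agreement(self, reverse):
        model, _ = reverse
        good = toy_pairs(5, seed=11)
        bad = [TranslationPair(p.secondary, p.primary[::-1]) for p in
               toy_pairs(5, seed=12, lengths=(12, 16))]
        labeled = [(f"good{i}", p) for i, p in enumerate(good)] + \
                  [(f"bad{i}", p) for i, p in enumerate(bad)]
        top = select_by_secondary_agreement(labeled, model, n=5)
        assert {i for i, _ in top} == {f"good{i}" for i in range(5)}

    def test_n_larger_than_set_warns_and_returns_all(self, reverse):
        model, _ = reverse
        labeled = [("a", toy_pairs(1, seed=13)[0])]
        with pytest.warns(UserWarning):
            out = select_by_secondary_agreement(labeled, model, n=5)
        assert len(out) == 1


class TestCER:
    def test_single_substitution(self):
        assert cer("LLHH", "LLHE") == pytest.approx(0.25)

    def test_identity(self):
        assert cer("LEH", "LEH") == 0.0

    def test_empty_prediction_is_all_deletions(self):
        assert cer("", "LLHH") == 1.0

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            cer("LL", "")


class TestStabilityWeightedSubset:
    def designs(self):
        return [ProteinDesign(id="lo", primary="ACDEF" * 5),
                ProteinDesign(id="hi", primary="GHIKL" * 5)]

    def test_representation_proportional_to_score(self):
        subset = stability_weighted_subset(
            self.designs(), {"lo": 1.0, "hi": 3.0}, n=10_000, seed=0)
        counts = np.array([sum(d.id == "lo" for d in subset),
                           sum(d.id == "hi" for d in subset)])
        ratio = counts[1] / counts[0]
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_equal_scores_uniform(self):
        subset = stability_weighted_subset(
            self.designs(), {"lo": 2.0, "hi": 2.0}, n=10_000, seed=1)
        frac = sum(d.id == "lo" for d in subset) / len(subset)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_output_mean_stability_exceeds_input_mean(self):
        scores = {"lo": 0.2, "hi": 2.0}
        subset = stability_weighted_subset(self.designs(), scores,
                                           n=5000, seed=2)
        out_mean = np.mean([scores[d.id] for d in subset])
        assert out_mean > np.mean(list(scores.values()))

    def test_all_scores_below_floor_degenerate(self):
        with pytest.raises(ValueError):
            stability_weighted_subset(self.designs(), {"lo": -1.0, "hi": 0.0})
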