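"""Evaluator model: architecture contracts, batched losses, training."""

import numpy as np
import pandas as pd
import pytest

from stabforge.design import ProteinDesign
from stabforge.evaluator import (
    EMConfig,
    build_em,
    class_holdout_eval,
    predict_designs,
    score_sequences,
    secondary_loss_batch,
    train_em,
)
from stabforge.grammar import kernel_bank
from stabforge.losses import loss_secondary
from stabforge.metrics import evaluate
from stabforge.nn import Tensor, softmax
from stabforge.synth import SynthConfig, generate_corpus

TINY = EMConfig(conv_channels=(16, 8, 8), dense_sizes=(16, 8),
                batch_size=32, max_epochs=4, patience=3, seed=0)


def small_corpus(n=160, seed=0):
    corpus = generate_corpus(SynthConfig(n_designs=n, seed=seed),
                             n_scrambles=0, n_naturals=40)
    designs, assay, truth = corpus["designs"], corpus["assay"], corpus["truth"]
    scores = {
        d.id: (
            assay.loc[d.id, "chymotrypsin_ec50"] - truth.loc[d.id, "chymotrypsin_baseline"],
            assay.loc[d.id, "trypsin_ec50"] - truth.loc[d.id, "trypsin_baseline"],
        )
        for d in designs
    }
    return corpus, scores


class TestArchitecture:
    def test_default_config_first_conv_shape(self):
        model = build_em()  # full-scale configuration
        assert model.first_conv_output_shape() == (171, 400)

    def test_min_head_is_architectural(self):
        model = build_em(TINY)
        x = np.random.default_rng(0).random((5, 175, 23))
        out = model.forward(x)
        stab = out["stability"].data
        assert np.array_equal(stab[:, 2], np.minimum(stab[:, 0], stab[:, 1]))

    def test_secondary_head_is_column_stochastic(self):
        model = build_em(TINY)
        x = np.random.default_rng(1).random((3, 175, 23))
        sec = model.forward(x)["secondary"].data
        assert sec.shape == (3, 6, 175)
        assert np.allclose(sec.sum(axis=1), 1.0)

    def test_trunk_length_follows_kernel_widths(self):
        model = build_em(TINY)
        assert model.trunk_len == 175 - 4 - 8 - 16


class TestBatchedSecondaryLoss:
    def test_matches_per_design_loss(self):
        rng = np.random.default_rng(2)
        bank = kernel_bank()
        z = np.zeros((4, 6, 12))
        rows = rng.integers(0, 6, size=(4, 12))
        for b in range(4):
            z[b, rows[b], np.arange(12)] = 1.0
        z_hat = softmax(Tensor(rng.normal(size=(4, 6, 12))), axis=1)
        batched = secondary_loss_batch(z, z_hat, bank).item()
        singles = [loss_secondary(z[b], Tensor(z_hat.data[b]), bank).item()
                   for b in range(4)]
        assert batched == pytest.approx(np.mean(singles), rel=1e-9)


class TestMetrics:
    def test_perfect_and_mean_predictors(self):
        obs = np.array([1.0, 2.0, 4.0, 0.5])
        assert evaluate(obs, obs).r2_fit == pytest.approx(1.0)
        mean_pred = np.full_like(obs, obs.mean())
        assert evaluate(mean_pred, obs).r2_fit == pytest.approx(0.0)

    def test_anticorrelated_fit_negative_r2_but_unit_r2_pearson(self):
        obs = np.array([-1.0, 0.0, 1.0, 2.0])
        m = evaluate(-obs, obs)
        assert m.r2_fit < 0 and m.r2_pearson == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            evaluate(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self):
        corpus, scores = small_corpus()
        model, log = train_em(corpus["designs"], scores, TINY,
                              naturals=corpus["naturals"])
        return corpus, scores, model, log

    def test_validation_loss_improves(self, trained):
        _, _, _, log = trained
        assert log["val_loss"].iloc[-1] < log["val_loss"].iloc[0] or \
            log["val_loss"].min() < log["val_loss"].iloc[0]

    def test_best_snapshot_restored(self, trained):
        _, _, _, log = trained
        assert log.attrs["restored_val_loss"] == pytest.approx(
            log["val_loss"].min(), rel=1e-9)

    def test_prediction_table_shape(self, trained):
        corpus, _, model, _ = trained
        preds = predict_designs(model, corpus["designs"][:10])
        assert list(preds.columns) == ["score_chymotrypsin", "score_trypsin",
                                       "score_min", "secondary_pred"]
        assert np.array_equal(
            preds["score_min"],
            np.minimum(preds["score_chymotrypsin"], preds["score_trypsin"]))

    def test_scorer_matches_prediction_table(self, trained):
        corpus, _, model, _ = trained
        designs = corpus["designs"][:5]
        direct = score_sequences(model, [d.primary for d in designs])
        table = predict_designs(model, designs)["score_min"].to_numpy()
        assert np.allclose(direct, table)

    def test_deterministic_given_seed(self):
        corpus, scores = small_corpus(n=64, seed=3)
        cfg = EMConfig(conv_channels=(8, 8, 8), dense_sizes=(8, 8),
                       batch_size=32, max_epochs=2, patience=2, seed=7)
        m1, _ = train_em(corpus["designs"], scores, cfg)
        m2, _ = train_em(corpus["designs"], scores, cfg)
        x = np.random.default_rng(0).random((2, 175, 23))
        assert np.array_equal(m1.forward(x)["stability"].data,
                              m2.forward(x)["stability"].data)

    def test_corpus_smaller_than_minibatch_raises(self):
        corpus, scores = small_corpus(n=30, seed=5)
        with pytest.raises(ValueError):
            train_em(corpus["designs"], scores, TINY)


class TestClassHoldout:
    def test_one_row_per_class_and_singletons_skipped(self):
        corpus, scores = small_corpus(n=140, seed=8)
        designs = list(corpus["designs"])
        lone = ProteinDesign(id="lone", primary=designs[0].primary,
                             secondary=designs[0].secondary,
                             design_class="singleton")
        scores[lone.id] = scores[designs[0].id]
        designs.append(lone)
        cfg = EMConfig(conv_channels=(8, 8, 8), dense_sizes=(8, 8),
                       batch_size=32, max_epochs=1, patience=1, seed=0)
        out = class_holdout_eval(designs, scores, cfg, n_repeats=1)
        assert set(out.index) == {d.design_class for d in designs}
        assert bool(out.loc["singleton", "skipped"])
        live = out[~out["skipped"]]
        assert len(live) >= 2 and live["r2_fit"].notna().all()
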