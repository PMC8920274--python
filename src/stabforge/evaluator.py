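"""The Evaluator Model (EM): a multi-task convolutional stability predictor.

The EM maps a one-hot primary-sequence window (23 x 175, randomized but
per-sequence-consistent placement) to

* per-protease stability scores (chymotrypsin, trypsin) through three
  valid convolutions and a small dense stack, with a third output defined
  architecturally as the minimum of the two; and
* a secondary-structure prediction (6 x 175 softmax columns) through a
  dense layer off the final convolution layer.

Training consumes triplets — a labeled design, an unlabeled natural
sequence, and a scramble of that natural — under the combined loss
``0.2*Ls + 0.1*Lc + 2*Ld`` (see :mod:`stabforge.losses`), optimized with
Adadelta, early-stopped on validation loss with the best snapshot restored.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alphabets import TOTAL_WIDTH
from .design import ProteinDesign
from .encoding import encode_primary, encode_secondary
from .grammar import kernel_bank
from .losses import W_COMPARATOR, W_SECONDARY, W_STABILITY, loss_comparator, loss_stability
from .metrics import evaluate
from .nn import (
    Adadelta,
    Conv1d,
    Dense,
    Module,
    Tensor,
    dropout,
    minimum,
    softmax,
    stack,
)

__all__ = ["EMConfig", "EMModel", "build_em", "train_em", "predict_designs",
           "class_holdout_eval", "secondary_loss_batch"]

_EPS = 1e-12


@dataclass
class EMConfig:
    """Architecture and training hyperparameters.

    Defaults reproduce the full-scale network (400/200/100 convolution
    kernels of widths 5/9/17, dense 80-40-2, 20% dropout, minibatches of
    64 triplets, early-stop patience 5).  :meth:`desk_scale` returns a
    reduced configuration suitable for CPU-only training on synthetic
    corpora of a few thousand designs.
    """

    conv_channels: Tuple[int, int, int] = (400, 200, 100)
    conv_widths: Tuple[int, int, int] = (5, 9, 17)
    dense_sizes: Tuple[int, int] = (80, 40)
    dropout: float = 0.20
    batch_size: int = 64
    patience: int = 5
    max_epochs: int = 60
    learning_rate: float = 1.0          # Adadelta
    use_naturals: bool = True
    comparator_printed_sign: bool = False
    permissive_start: bool = False
    val_fraction: float = 0.10          # capped at 10,000 samples
    global_seed: int = 0                # placement hash seed
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "EMConfig":
        base = cls(conv_channels=(32, 16, 12), dense_sizes=(32, 16),
                   max_epochs=25)
        return replace(base, **overrides)


class EMModel(Module):
    def __init__(self, config: EMConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.conv_channels
        w1, w2, w3 = config.conv_widths
        self.conv1 = Conv1d(w1, 23, c1, rng)
        self.conv2 = Conv1d(w2, c1, c2, rng)
        self.conv3 = Conv1d(w3, c2, c3, rng)
        self.trunk_len = TOTAL_WIDTH - (w1 - 1) - (w2 - 1) - (w3 - 1)
        flat = self.trunk_len * c3
        d1, d2 = config.dense_sizes
        self.dense1 = Dense(flat, d1, rng)
        self.dense2 = Dense(d1, d2, rng)
        self.dense_out = Dense(d2, 2, rng)
        self.dense_secondary = Dense(flat, 6 * TOTAL_WIDTH, rng)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None,
                want_secondary: bool = True) -> Dict[str, Tensor]:
        """Run a batch of encoded windows (B, 175, 23).

        Returns ``{"stability": (B, 3) Tensor, "secondary": (B, 6, 175)}``;
        stability columns are (chymotrypsin, trypsin, min) and the third is
        the elementwise minimum of the first two by construction.
        """
        h = Tensor(x)
        p = self.config.dropout
        for conv in (self.conv1, self.conv2, self.conv3):
            h = conv(h).relu()
            if training:
                h = dropout(h, p, rng)
        flat = h.reshape(h.shape[0], -1)
        s = self.dense1(flat).relu()
        s = self.dense2(s).relu()
        pair = self.dense_out(s)                       # (B, 2): (c, t)
        m = minimum(pair[:, 0], pair[:, 1])
        stability = stack([pair[:, 0], pair[:, 1], m], axis=1)
        out = {"stability": stability}
        if want_secondary:
            logits = self.dense_secondary(flat).reshape(-1, 6, TOTAL_WIDTH)
            out["secondary"] = softmax(logits, axis=1)
        return out

    def first_conv_output_shape(self) -> Tuple[int, int]:
        return (TOTAL_WIDTH - self.config.conv_widths[0] + 1,
                self.config.conv_channels[0])


def build_em(config: Optional[EMConfig] = None) -> EMModel:
    """Construct an (untrained) EM from a config."""
    return EMModel(config or EMConfig())


# ---------------------------------------------------------------------------
# batched secondary loss (vectorized version of losses.loss_secondary)

def secondary_loss_batch(z: np.ndarray, z_hat: Tensor,
                         bank: np.ndarray) -> Tensor:
    """Mean over a batch of the per-design secondary loss Ld.

    ``z``: binary targets (B, 6, W); ``z_hat``: softmax Tensor (B, 6, W).
    Matches :func:`stabforge.losses.loss_secondary` applied per design and
    averaged.
    """
    n, _, width = z.shape
    ce = -(Tensor(z) * (z_hat + _EPS).log()).sum(axis=(1, 2)) * (1.0 / width)

    def violations(mat) -> Tensor:
        left = mat[:, :, :-1]
        right = mat[:, :, 1:]
        per_kernel = []
        for k in range(bank.shape[0]):
            val = ((left * bank[k, :, 0].reshape(1, 6, 1)).sum(axis=1)
                   + (right * bank[k, :, 1].reshape(1, 6, 1)).sum(axis=1))
            per_kernel.append(val.clip01())
        return stack(per_kernel, axis=0).max(axis=0)   # (B, W-1)

    # binarization (no gradient path, by definition)
    z01 = np.zeros_like(z_hat.data)
    arg = np.argmax(z_hat.data, axis=1)
    b_idx = np.arange(n)[:, None]
    w_idx = np.arange(z.shape[2])[None, :]
    z01[b_idx, arg, w_idx] = 1.0

    v01 = violations(Tensor(z01))
    vsm = violations(z_hat)
    per_design = (ce + 0.8 * v01.mean(axis=1) + 0.4 * v01.max(axis=1)
                  + 0.1 * vsm.mean(axis=1) + 0.05 * vsm.max(axis=1))
    return per_design.mean()


# ---------------------------------------------------------------------------
# encoding caches

def _encode_designs(designs: Sequence[ProteinDesign], global_seed: int,
                    with_secondary: bool) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    xs = np.zeros((len(designs), TOTAL_WIDTH, 23))
    zs = np.zeros((len(designs), 6, TOTAL_WIDTH)) if with_secondary else None
    for i, d in enumerate(designs):
        mat, off = encode_primary(d.primary, global_seed=global_seed)
        xs[i] = mat.T
        if with_secondary:
            if d.secondary is None:
                raise ValueError(f"design {d.id} lacks a secondary string")
            zs[i] = encode_secondary(d.secondary, off)
    return xs, zs


def predict_designs(model: EMModel, designs: Sequence[ProteinDesign],
                    batch_size: int = 64) -> pd.DataFrame:
    """Predicted stability scores (and argmax secondary strings) per design."""
    from .grammar import binarize
    from .alphabets import SECONDARY

    xs, _ = _encode_designs(designs, model.config.global_seed, with_secondary=False)
    rows = []
    for start in range(0, len(designs), batch_size):
        chunk = xs[start : start + batch_size]
        out = model.forward(chunk, training=False)
        stab = out["stability"].data
        sec = out["secondary"].data
        for j in range(chunk.shape[0]):
            d = designs[start + j]
            hard = binarize(sec[j])
            labels = "".join(SECONDARY[r] for r in np.argmax(hard, axis=0))
            rows.append({
                "id": d.id,
                "score_chymotrypsin": stab[j, 0],
                "score_trypsin": stab[j, 1],
                "score_min": stab[j, 2],
                "secondary_pred": labels.strip("X"),
            })
    gc.collect()
    return pd.DataFrame(rows).set_index("id")


def score_sequences(model: EMModel, seqs: Sequence[str],
                    batch_size: int = 128) -> np.ndarray:
    """Combined (min) predicted stability score per sequence — the default
    scorer for beam-search refinement."""
    xs = np.zeros((len(seqs), TOTAL_WIDTH, 23))
    for i, s in enumerate(seqs):
        mat, _ = encode_primary(s, global_seed=model.config.global_seed)
        xs[i] = mat.T
    out = np.empty(len(seqs))
    for start in range(0, len(seqs), batch_size):
        chunk = xs[start : start + batch_size]
        res = model.forward(chunk, training=False, want_secondary=False)
        out[start : start + chunk.shape[0]] = res["stability"].data[:, 2]
    gc.collect()  # forward graphs are cyclic too
    return out


# ---------------------------------------------------------------------------
# training

def train_em(designs: Sequence[ProteinDesign],
             scores: Dict[str, Tuple[float, float]],
             config: Optional[EMConfig] = None,
             naturals: Sequence[ProteinDesign] = (),
             verbose: bool = False) -> Tuple[EMModel, pd.DataFrame]:
    """Train an EM on labeled designs (plus an optional natural stream).

    ``scores`` maps design id to (chymotrypsin, trypsin) stability scores.
    Returns ``(model, log)`` where *log* holds per-epoch train/validation
    losses; the returned model is the best-validation snapshot.
    Deterministic given ``config.seed``.
    """
    config = config or EMConfig()
    if len(designs) < config.batch_size:
        raise ValueError("corpus smaller than one minibatch")
    rng = np.random.default_rng(config.seed)
    bank = kernel_bank(config.permissive_start)

    xs, zs = _encode_designs(designs, config.global_seed, with_secondary=True)
    y = np.array([[scores[d.id][0], scores[d.id][1]] for d in designs])
    targets = np.column_stack([y, y.min(axis=1)])      # (n, 3): c, t, min

    n_val = min(10_000, max(config.batch_size,
                            int(len(designs) * config.val_fraction)))
    order = rng.permutation(len(designs))
    val_idx, train_idx = order[:n_val], order[n_val:]

    use_nat = config.use_naturals and len(naturals) > 0
    if use_nat:
        nat_xs, _ = _encode_designs(naturals, config.global_seed, False)
        scr_designs = []
        for d in naturals:
            perm = rng.permutation(len(d.primary))
            scr_designs.append(ProteinDesign(
                id=f"{d.id}|scr", primary="".join(d.primary[i] for i in perm),
                provenance="scramble"))
        scr_xs, _ = _encode_designs(scr_designs, config.global_seed, False)

    model = EMModel(config)
    opt = Adadelta(model.parameters(), lr=config.learning_rate)
    drop_rng = np.random.default_rng(config.seed + 1)

    def validation_loss() -> float:
        total, count = 0.0, 0
        for start in range(0, len(val_idx), 64):
            idx = val_idx[start : start + 64]
            out = model.forward(xs[idx], training=False)
            ls = loss_stability(targets[idx], out["stability"]).item()
            ld = secondary_loss_batch(zs[idx], out["secondary"], bank).item()
            total += (W_STABILITY * ls + W_SECONDARY * ld) * len(idx)
            count += len(idx)
        return total / count

    log_rows = []
    best = np.inf
    best_state = model.state_dict()
    stale = 0
    nat_cursor = 0
    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(train_idx))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(perm) - config.batch_size + 1, config.batch_size):
            idx = train_idx[perm[start : start + config.batch_size]]
            opt.zero_grad()
            # gradients accumulate across the two backward passes; freeing
            # the design graph before building the comparator graph halves
            # peak memory
            out = model.forward(xs[idx], training=True, rng=drop_rng)
            ls = loss_stability(targets[idx], out["stability"])
            ld = secondary_loss_batch(zs[idx], out["secondary"], bank)
            design_loss = W_STABILITY * ls + W_SECONDARY * ld
            design_loss.backward()
            batch_loss = design_loss.item()
            del out, ls, ld, design_loss
            if use_nat:
                take = [(nat_cursor + j) % len(nat_xs)
                        for j in range(config.batch_size)]
                nat_cursor = (nat_cursor + config.batch_size) % len(nat_xs)
                nat_out = model.forward(nat_xs[take], training=True,
                                        rng=drop_rng, want_secondary=False)
                scr_out = model.forward(scr_xs[take], training=True,
                                        rng=drop_rng, want_secondary=False)
                lc = (W_COMPARATOR
                      * loss_comparator(nat_out["stability"], scr_out["stability"],
                                        printed_sign=config.comparator_printed_sign))
                lc.backward()
                batch_loss += lc.item()
                del nat_out, scr_out, lc
            opt.step()
            epoch_loss += batch_loss
            n_batches += 1
            gc.collect()  # autodiff graphs are cyclic; reclaim promptly
        val = validation_loss()
        log_rows.append({"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
                         "val_loss": val})
        if verbose:
            print(f"[em] epoch {epoch} train={log_rows[-1]['train_loss']:.4f} "
                  f"val={val:.4f}")
        if val < best - 1e-6:
            best, best_state, stale = val, model.state_dict(), 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.load_state_dict(best_state)
    log = pd.DataFrame(log_rows)
    log.attrs["restored_val_loss"] = validation_loss()
    return model, log


def class_holdout_eval(designs: Sequence[ProteinDesign],
                       scores: Dict[str, Tuple[float, float]],
                       config: Optional[EMConfig] = None,
                       n_repeats: int = 3,
                       verbose: bool = False) -> pd.DataFrame:
    """Held-out-class generalization: for each design class, train on the
    other classes (*n_repeats* times with different seeds) and report the
    mean R^2 of the combined score on the held-out class."""
    config = config or EMConfig.desk_scale()
    classes = sorted({d.design_class for d in designs})
    if len(classes) < 2:
        raise ValueError("need at least 2 design classes")
    rows = []
    for cls in classes:
        held = [d for d in designs if d.design_class == cls]
        rest = [d for d in designs if d.design_class != cls]
        if len(held) < 2:
            rows.append({"design_class": cls, "r2_fit": np.nan,
                         "n": len(held), "skipped": True})
            continue
        r2s = []
        for rep in range(n_repeats):
            cfg = replace(config, seed=config.seed + 1000 * rep)
            model, _ = train_em(rest, scores, cfg, verbose=verbose)
            preds = predict_designs(model, held)["score_min"]
            obs = [min(scores[d.id]) for d in held]
            r2s.append(evaluate(preds.to_numpy(), obs).r2_fit)
        rows.append({"design_class": cls, "r2_fit": float(np.mean(r2s)),
                     "n": len(held), "skipped": False})
    return pd.DataFrame(rows).set_index("design_class")
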