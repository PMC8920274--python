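"""Generator Model (GM): secondary-structure to primary-sequence translation.

The GM treats design as machine translation: the source sentence is a
secondary-structure string over {L, E, H}, the target a primary sequence of
the same length over a 19-amino-acid vocabulary (no cysteine — disulfides
confound the protease assay) plus a stop token.  A convolutional encoder
embeds the secondary string, a convolutional attention network scores
encoder positions against the decoder state, and an LSTM decoder emits
residues left to right; because source and target are aligned 1:1, the
decoder also sees the encoder feature at the position being emitted.

The same architecture with the vocabularies swapped is the Reverse GM
(primary -> secondary), used to check that a generated sequence encodes the
secondary structure that was requested.

Quality metrics: perplexity (antilog of mean per-residue cross-entropy;
1 = perfect, vocabulary size = chance) and character error rate (CER,
Levenshtein distance / reference length, via edlib).
"""

from __future__ import annotations

import gc
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .alphabets import GM_STOP, PRIMARY_GM, validate_secondary
from .design import ProteinDesign
from .nn import (
    Adam,
    Dense,
    LSTMCell,
    Module,
    Tensor,
    concat,
    log_softmax,
    softmax,
    stack,
)

__all__ = [
    "GMConfig", "GMModel", "TranslationPair", "train_gm", "train_reverse_gm",
    "beam_decode", "greedy_decode", "perplexity", "cer",
    "select_by_secondary_agreement", "stability_weighted_subset",
    "UniformPredictor", "OraclePredictor",
]

SECONDARY_SRC = "LEH"
SECONDARY_TGT = "LEH" + GM_STOP      # Reverse-GM output vocabulary

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TranslationPair:
    secondary: str
    primary: str

    def __post_init__(self):
        if len(self.secondary) != len(self.primary):
            raise ValueError("secondary/primary must have equal length")
        validate_secondary(self.secondary)
        if "C" in self.primary:
            raise ValueError("cysteine is outside the generator vocabulary")


@dataclass
class GMConfig:
    """Desk-scale by default; production-scale translation models use far
    larger parameter budgets, which changes capacity but not mechanics."""

    embed_dim: int = 16
    encoder_channels: int = 32
    encoder_width: int = 5
    attention_dim: int = 24
    hidden_size: int = 48
    beam_width: int = 5
    iterations: int = 65          # training epochs
    learning_rate: float = 5e-3
    batch_size: int = 32
    seed: int = 0


def _onehot(seq: str, vocab: Dict[str, int]) -> np.ndarray:
    out = np.zeros((len(seq), len(vocab)))
    for i, ch in enumerate(seq):
        out[i, vocab[ch]] = 1.0
    return out


class GMModel(Module):
    """Encoder/attention/decoder translation model over arbitrary aligned
    vocabularies (used for both the GM and the Reverse GM)."""

    def __init__(self, src_vocab: str, tgt_vocab: str, config: GMConfig):
        self.config = config
        self.src_vocab = src_vocab
        self.tgt_vocab = tgt_vocab
        self.src_index = {c: i for i, c in enumerate(src_vocab)}
        self.tgt_index = {c: i for i, c in enumerate(tgt_vocab)}
        rng = np.random.default_rng(config.seed)
        d = config.encoder_channels
        w = config.encoder_width
        from .nn import glorot

        self.enc_w = glorot(rng, w, len(src_vocab), d)     # same-padded conv
        self.enc_b = Tensor(np.zeros(d), requires_grad=True)
        self.att_key = Dense(d, config.attention_dim, rng)
        self.att_query = Dense(config.hidden_size, config.attention_dim, rng)
        self.att_v = glorot(rng, config.attention_dim, 1)
        self.embed = glorot(rng, len(tgt_vocab), config.embed_dim)
        self.cell = LSTMCell(config.embed_dim + 2 * d, config.hidden_size, rng)
        self.out = Dense(config.hidden_size + d, len(tgt_vocab), rng)

    # -- encoder --------------------------------------------------------
    def encode(self, batch_onehot: np.ndarray) -> Tensor:
        """Same-padded valid convolution over (B, L, |src|) -> (B, L, d)."""
        w = self.config.encoder_width
        pad = w // 2
        b, length, v = batch_onehot.shape
        padded = np.zeros((b, length + 2 * pad, v))
        padded[:, pad : pad + length, :] = batch_onehot
        from .nn import conv1d_valid

        return conv1d_valid(Tensor(padded), self.enc_w, self.enc_b).tanh()

    # -- one decoder step ----------------------------------------------
    def _step(self, enc: Tensor, keys: Tensor, prev_embed: Tensor,
              pos_feat: Tensor, h: Tensor, c: Tensor,
              mask: Optional[np.ndarray] = None):
        q = self.att_query(h)                          # (B, A)
        scores = (keys + q.reshape(q.shape[0], 1, -1)).tanh() @ self.att_v
        scores = scores.reshape(scores.shape[0], -1)   # (B, L)
        if mask is not None:
            scores = scores + Tensor(np.where(mask, 0.0, -1e9))
        alpha = softmax(scores, axis=1)
        context = (enc * alpha.reshape(alpha.shape[0], -1, 1)).sum(axis=1)
        x = concat([prev_embed, pos_feat, context], axis=1)
        h, c = self.cell(x, h, c)
        logits = self.out(concat([h, context], axis=1))
        return logits, h, c

    def _init_state(self, batch: int) -> Tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.config.hidden_size))
        return Tensor(z), Tensor(z.copy())

    # -- teacher-forced pass --------------------------------------------
    def forced_log_probs(self, src: str, tgt: str) -> np.ndarray:
        """Log probability of each reference token under teacher forcing."""
        dists = self.step_distributions(src, tgt)
        idx = [self.tgt_index[ch] for ch in tgt]
        return np.log(np.maximum(dists[np.arange(len(tgt)), idx], _PROB_FLOOR))

    def step_distributions(self, src: str, tgt: str) -> np.ndarray:
        """Per-position output distributions (len, |tgt vocab|) under
        teacher forcing of *tgt*."""
        x = _onehot(src, self.src_index)[None]
        enc = self.encode(x)
        keys = self.att_key(enc)
        h, c = self._init_state(1)
        prev = Tensor(np.zeros((1, self.config.embed_dim)))
        dists = np.zeros((len(tgt), len(self.tgt_vocab)))
        for t in range(len(tgt)):
            logits, h, c = self._step(enc, keys, prev, enc[:, t, :], h, c)
            dists[t] = softmax(logits, axis=1).data[0]
            prev = Tensor(self.embed.data[self.tgt_index[tgt[t]]][None])
        return dists


def _batch_by_length(pairs: Sequence[TranslationPair], batch_size: int,
                     rng: np.random.Generator):
    by_len: Dict[int, List[TranslationPair]] = {}
    for p in pairs:
        by_len.setdefault(len(p.secondary), []).append(p)
    batches = []
    for group in by_len.values():
        idx = rng.permutation(len(group))
        for start in range(0, len(group), batch_size):
            batches.append([group[i] for i in idx[start : start + batch_size]])
    rng.shuffle(batches)
    return batches


def _train(model: GMModel, pairs: Sequence[TranslationPair],
           src_of, tgt_of, config: GMConfig, verbose: bool) -> List[float]:
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    losses = []
    for epoch in range(config.iterations):
        total, count = 0.0, 0
        for batch in _batch_by_length(pairs, config.batch_size, rng):
            b = len(batch)
            length = len(src_of(batch[0]))
            x = np.stack([_onehot(src_of(p), model.src_index) for p in batch])
            tgt_idx = np.array([[model.tgt_index[ch] for ch in tgt_of(p)]
                                for p in batch])           # (B, L)
            opt.zero_grad()
            enc = model.encode(x)
            keys = model.att_key(enc)
            h, c = model._init_state(b)
            prev = Tensor(np.zeros((b, config.embed_dim)))
            step_losses = []
            for t in range(length):
                logits, h, c = model._step(enc, keys, prev, enc[:, t, :], h, c)
                logp = log_softmax(logits, axis=1)
                nll = -logp[np.arange(b), tgt_idx[:, t]].mean()
                step_losses.append(nll)
                prev = Tensor(model.embed.data[tgt_idx[:, t]])
            loss = stack(step_losses, axis=0).mean()
            loss.backward()
            opt.step()
            total += loss.item() * b * length
            count += b * length
        losses.append(total / count)
        gc.collect()  # reclaim cyclic autodiff graphs
        if verbose:
            print(f"[gm] epoch {epoch} nll/residue={losses[-1]:.4f}")
    return losses


def train_gm(pairs: Sequence[TranslationPair],
             config: Optional[GMConfig] = None,
             verbose: bool = False) -> Tuple[GMModel, List[float]]:
    """Fit the secondary -> primary translator by cross-entropy descent."""
    config = config or GMConfig()
    if not pairs:
        raise ValueError("empty training pair set")
    model = GMModel(SECONDARY_SRC, PRIMARY_GM, config)
    losses = _train(model, pairs, lambda p: p.secondary, lambda p: p.primary,
                    config, verbose)
    return model, losses


def train_reverse_gm(pairs: Sequence[TranslationPair],
                     config: Optional[GMConfig] = None,
                     verbose: bool = False) -> Tuple[GMModel, List[float]]:
    """Fit the primary -> secondary model (architecture equivalent to the
    GM with source and target swapped)."""
    config = config or GMConfig()
    if not pairs:
        raise ValueError("empty training pair set")
    model = GMModel(PRIMARY_GM.replace(GM_STOP, ""), SECONDARY_SRC, config)
    losses = _train(model, pairs, lambda p: p.primary, lambda p: p.secondary,
                    config, verbose)
    return model, losses


# ---------------------------------------------------------------------------
# decoding

def beam_decode(model: GMModel, secondary: str, width: int = 5,
                forbid: str = GM_STOP) -> List[Tuple[str, float]]:
    """Beam search for the *width* likeliest primary sequences.

    Output sequences have exactly the length of *secondary*; the stop
    token (and anything in *forbid*) is masked out.  Returns
    ``(sequence, total log probability)`` pairs in descending order.
    """
    if not secondary:
        raise ValueError("empty source string")
    banned = [model.tgt_index[ch] for ch in forbid if ch in model.tgt_index]
    x = _onehot(secondary, model.src_index)[None]
    enc = model.encode(x)
    keys = model.att_key(enc)
    h0, c0 = model._init_state(1)
    # hypotheses: (neg logprob is implicit via sort) prefix, logprob, h, c
    hyps: List[Tuple[str, float, Tensor, Tensor]] = [("", 0.0, h0, c0)]
    for t in range(len(secondary)):
        candidates: List[Tuple[float, str, int, Tensor, Tensor]] = []
        for prefix, lp, h, c in hyps:
            if prefix:
                prev = Tensor(model.embed.data[model.tgt_index[prefix[-1]]][None])
            else:
                prev = Tensor(np.zeros((1, model.config.embed_dim)))
            logits, h2, c2 = model._step(enc, keys, prev, enc[:, t, :], h, c)
            logp = log_softmax(logits, axis=1).data[0]
            for tok, ch in enumerate(model.tgt_vocab):
                if tok in banned:
                    continue
                candidates.append((lp + logp[tok], prefix + ch, tok, h2, c2))
        candidates.sort(key=lambda item: (-item[0], item[1]))
        hyps = [(pre, lp, h, c) for lp, pre, _, h, c in candidates[:width]]
    return [(prefix, lp) for prefix, lp, _, _ in hyps]


def greedy_decode(model: GMModel, src: str) -> str:
    """Beam of width 1."""
    return beam_decode(model, src, width=1, forbid=GM_STOP)[0][0]


# ---------------------------------------------------------------------------
# metrics and reference predictors

class UniformPredictor:
    """Assigns uniform probability over the amino-acid vocabulary (stop
    token excluded) at every position — the chance baseline."""

    def __init__(self, vocab: str = PRIMARY_GM):
        self.tgt_vocab = vocab
        self.tgt_index = {c: i for i, c in enumerate(vocab)}
        self.n_symbols = len(vocab.replace(GM_STOP, ""))

    def step_distributions(self, src: str, tgt: str) -> np.ndarray:
        dist = np.zeros((len(tgt), len(self.tgt_vocab)))
        for i, ch in enumerate(self.tgt_vocab):
            if ch != GM_STOP:
                dist[:, i] = 1.0 / self.n_symbols
        return dist

    def forced_log_probs(self, src: str, tgt: str) -> np.ndarray:
        dists = self.step_distributions(src, tgt)
        idx = [self.tgt_index[ch] for ch in tgt]
        return np.log(np.maximum(dists[np.arange(len(tgt)), idx], _PROB_FLOOR))


class OraclePredictor(UniformPredictor):
    """Assigns probability one to the reference residue at each position —
    the perfect-prediction bound."""

    def step_distributions(self, src: str, tgt: str) -> np.ndarray:
        dist = np.zeros((len(tgt), len(self.tgt_vocab)))
        for t, ch in enumerate(tgt):
            dist[t, self.tgt_index[ch]] = 1.0
        return dist


def perplexity(model, pairs: Sequence[TranslationPair]) -> float:
    """Antilog of the mean per-residue cross-entropy over *pairs*.

    Zero-probability reference tokens are floored at 1e-12.  Always >= 1;
    equals the vocabulary size for a chance-level predictor and 1 for a
    perfect one.
    """
    if not pairs:
        raise ValueError("empty pair set")
    total_nll, total_res = 0.0, 0
    for p in pairs:
        lp = model.forced_log_probs(p.secondary, p.primary)
        total_nll -= lp.sum()
        total_res += len(p.primary)
    return float(np.exp(total_nll / total_res))


def cer(predicted: str, reference: str) -> float:
    """Character error rate: Levenshtein distance / reference length."""
    if not reference:
        raise ValueError("empty reference string")
    if not predicted:
        return 1.0
    dist = edlib.align(predicted, reference)["editDistance"]
    return dist / len(reference)


def select_by_secondary_agreement(pairs: Sequence[Tuple[str, TranslationPair]],
                                  reverse_model: GMModel,
                                  n: int) -> List[Tuple[str, float]]:
    """Rank generated designs by Reverse-GM secondary agreement.

    *pairs* is ``(design_id, TranslationPair)`` where the pair holds the
    requested secondary and generated primary.  Designs are ranked by
    ascending ``cer(reverse_prediction(primary), requested_secondary)``
    with ties broken by id; the best *n* are returned as (id, cer).
    """
    import warnings

    scored = []
    for design_id, pair in pairs:
        pred = greedy_decode(reverse_model, pair.primary)
        scored.append((design_id, cer(pred, pair.secondary)))
    scored.sort(key=lambda item: (item[1], item[0]))
    if n > len(scored):
        warnings.warn(f"requested {n} designs but only {len(scored)} available")
    return scored[:n]


# ---------------------------------------------------------------------------
# stability-weighted training subsets

def stability_weighted_subset(designs: Sequence[ProteinDesign],
                              scores: Dict[str, float],
                              n: Optional[int] = None,
                              floor: float = 0.05,
                              seed: int = 0) -> List[ProteinDesign]:
    """Resample designs in proportion to (floored) stability score.

    Weighted sampling with replacement; a design's expected multiplicity is
    proportional to ``max(score, floor)``, so stable designs dominate the
    generator's training diet.  Raises if every score is at or below the
    floor (degenerate weighting).
    """
    weights = np.array([max(scores[d.id], floor) for d in designs], dtype=float)
    if np.all(np.array([scores[d.id] for d in designs]) <= floor):
        raise ValueError("all stability scores at or below the floor")
    if n is None:
        n = len(designs)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(designs), size=n, replace=True, p=weights / weights.sum())
    return [designs[i] for i in idx]
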