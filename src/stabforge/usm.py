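"""Unfolded-state model (USM) and stability scores.

Observed protease resistance (EC50, log units) mixes two effects: intrinsic
cleavage susceptibility of the unfolded chain, and protection conferred by
folding.  The USM predicts the former from sequence alone; it is trained on
scrambled sequences, which are assumed never to fold.  The stability score
of a design is then

    score_p = EC50_observed(p) - EC50_USM(p)          per protease p,
    score   = min(score_trypsin, score_chymotrypsin).

One model is trained per protease.  Each model convolves the one-hot
sequence (with start/end flanks) with 100 learned kernels, takes every
kernel's maximum activation over the valid convolution positions of the
sequence, and combines the maxima through a learned linear head.  Because
the maximum is restricted to windows overlapping the sequence itself,
predictions do not depend on how much padding surrounds the placement
window — a sequence has one deterministic prediction.
"""

from __future__ import annotations

import gc
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .alphabets import PRIMARY_EM_INDEX
from .design import CHYMOTRYPSIN, PROTEASES, TRYPSIN, ProteaseAssay, StabilityRecord
from .nn import Adam, Conv1d, Dense, Module, Tensor, conv1d_valid

__all__ = [
    "USMConfig", "USMModel", "train_usm", "usm_predict",
    "stability_score", "compare_usm_bias", "encode_usm_batch",
]


@dataclass
class USMConfig:
    n_kernels: int = 100
    kernel_width: int = 5
    learning_rate: float = 3e-3
    max_epochs: int = 80
    batch_size: int = 64
    patience: int = 8          # early stop on validation MSE
    val_fraction: float = 0.1
    seed: int = 0


def encode_usm_batch(seqs: Sequence[str], width: int) -> Tuple[np.ndarray, np.ndarray]:
    """One-hot encode sequences as (B, maxlen+2, 23) with J/O flanks and a
    validity mask over convolution positions (padding windows masked out)."""
    lens = [len(s) for s in seqs]
    if min(lens) + 2 < width:
        raise ValueError(f"sequence shorter than kernel width {width}")
    maxlen = max(lens) + 2
    x = np.zeros((len(seqs), maxlen, 23))
    n_pos = maxlen - width + 1
    mask = np.zeros((len(seqs), n_pos), dtype=bool)
    x[:, :, PRIMARY_EM_INDEX["X"]] = 1.0
    for i, s in enumerate(seqs):
        x[i, 0, :] = 0.0
        x[i, 0, PRIMARY_EM_INDEX["J"]] = 1.0
        for j, ch in enumerate(s):
            try:
                row = PRIMARY_EM_INDEX[ch]
            except KeyError:
                raise ValueError(f"illegal residue {ch!r}") from None
            x[i, j + 1, :] = 0.0
            x[i, j + 1, row] = 1.0
        x[i, len(s) + 1, :] = 0.0
        x[i, len(s) + 1, PRIMARY_EM_INDEX["O"]] = 1.0
        mask[i, : len(s) + 3 - width] = True  # windows within J..O span
    return x, mask


class _ProteaseNet(Module):
    def __init__(self, config: USMConfig, rng: np.random.Generator):
        self.conv = Conv1d(config.kernel_width, 23, config.n_kernels, rng)
        # max-pooling over ~50 positions amplifies initial activation
        # variance; start the kernels small so the bias-only solution is
        # reachable quickly when the data demand it
        self.conv.w.data *= 0.1
        self.head = Dense(config.n_kernels, 1, rng)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> Tensor:
        act = conv1d_valid(Tensor(x), self.conv.w, self.conv.b)  # (B, P, K)
        gate = np.where(mask, 0.0, -1e9)[:, :, None]
        pooled = (act + Tensor(gate)).max(axis=1)                # (B, K)
        return self.head(pooled)[:, 0]


@dataclass
class USMModel:
    """Two independent per-protease networks plus their config."""

    config: USMConfig
    nets: Dict[str, _ProteaseNet] = field(default_factory=dict)

    @classmethod
    def initialize(cls, config: USMConfig) -> "USMModel":
        rng = np.random.default_rng(config.seed)
        return cls(config=config,
                   nets={p: _ProteaseNet(config, rng) for p in PROTEASES})

    def predict(self, seqs: Sequence[str], protease: str) -> np.ndarray:
        """Predicted unfolded-state EC50 for each sequence."""
        if protease not in self.nets:
            raise ValueError(f"no model for protease {protease!r}")
        out = np.empty(len(seqs))
        for start in range(0, len(seqs), 256):  # bound peak memory
            chunk = list(seqs[start : start + 256])
            x, mask = encode_usm_batch(chunk, self.config.kernel_width)
            out[start : start + len(chunk)] = self.nets[protease].forward(x, mask).data
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for p, net in self.nets.items():
            for k, v in net.state_dict().items():
                out[f"{p}.{k}"] = v
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for p, net in self.nets.items():
            net.load_state_dict({k[len(p) + 1:]: v for k, v in state.items()
                                 if k.startswith(p + ".")})


def usm_predict(model: USMModel, primary: str, protease: str) -> float:
    """Unfolded-state EC50 prediction for a single sequence."""
    return float(model.predict([primary], protease)[0])


def train_usm(scrambles: Dict[str, List[Tuple[str, float]]],
              config: USMConfig | None = None,
              verbose: bool = False) -> USMModel:
    """Fit the two per-protease networks on scramble EC50 data.

    *scrambles* maps protease name to a list of ``(sequence, ec50_obs)``.
    Training minimizes mean squared EC50 error with Adam, early-stopping on
    a held-out validation split and restoring the best snapshot.
    Deterministic given ``config.seed``.
    """
    config = config or USMConfig()
    for p in PROTEASES:
        if not scrambles.get(p):
            raise ValueError(f"no training scrambles for protease {p!r}")
    model = USMModel.initialize(config)
    for protease in PROTEASES:
        data = scrambles[protease]
        rng = np.random.default_rng(config.seed + 1)
        order = rng.permutation(len(data))
        n_val = max(1, int(len(data) * config.val_fraction))
        val_idx, train_idx = order[:n_val], order[n_val:]
        seqs = [data[i][0] for i in train_idx]
        y = np.array([data[i][1] for i in train_idx])
        vseqs = [data[i][0] for i in val_idx]
        vy = np.array([data[i][1] for i in val_idx])
        net = model.nets[protease]
        # centre the head bias on the target mean so early epochs are sane
        net.head.b.data[:] = y.mean()
        opt = Adam(net.parameters(), lr=config.learning_rate)
        xv, mv = encode_usm_batch(vseqs, config.kernel_width)
        best, best_state, stale = np.inf, None, 0
        for epoch in range(config.max_epochs):
            perm = rng.permutation(len(seqs))
            for start in range(0, len(seqs), config.batch_size):
                idx = perm[start : start + config.batch_size]
                xb, mb = encode_usm_batch([seqs[i] for i in idx],
                                          config.kernel_width)
                opt.zero_grad()
                pred = net.forward(xb, mb)
                loss = ((pred - Tensor(y[idx])) ** 2).mean()
                loss.backward()
                opt.step()
            gc.collect()  # reclaim cyclic autodiff graphs
            val_mse = float(np.mean((net.forward(xv, mv).data - vy) ** 2))
            if verbose:
                print(f"[usm:{protease}] epoch {epoch} val_mse={val_mse:.4f}")
            if val_mse < best - 1e-6:
                best, best_state, stale = val_mse, net.state_dict(), 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        if best_state is not None:
            net.load_state_dict(best_state)
    return model


def stability_score(design_id: str, primary: str,
                    assays: Iterable[ProteaseAssay],
                    model: USMModel) -> StabilityRecord:
    """Observed minus USM-predicted EC50 per protease; combined = min."""
    by_protease = {a.protease: a for a in assays}
    missing = set(PROTEASES) - set(by_protease)
    if missing:
        raise ValueError(f"missing protease assays: {sorted(missing)}")
    rec = StabilityRecord(design_id=design_id)
    for p in PROTEASES:
        rec.ec50_obs[p] = by_protease[p].ec50_obs
        rec.ec50_usm[p] = usm_predict(model, primary, p)
    return rec


def compare_usm_bias(designs: Sequence[str], scrambles: Sequence[str],
                     model: USMModel, protease: str | None = None) -> float:
    """Median predicted design EC50 minus median predicted scramble EC50.

    A diagnostic for USM bias: designs and their scrambles share residue
    composition, so an unbiased unfolded-state predictor should give the
    two sets similar medians.  With ``protease=None`` the gap is averaged
    over both proteases.
    """
    if not len(designs) or not len(scrambles):
        raise ValueError("both sequence sets must be nonempty")
    proteases = PROTEASES if protease is None else (protease,)
    gaps = []
    for p in proteases:
        d = np.median(model.predict(list(designs), p))
        s = np.median(model.predict(list(scrambles), p))
        gaps.append(d - s)
    return float(np.mean(gaps))
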