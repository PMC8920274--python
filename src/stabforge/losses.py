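"""The evaluator's training objective.

Four pieces, combined linearly:

* ``loss_stability`` (Ls) — mean squared error on the stability-score
  triple (chymotrypsin, trypsin, min) minus 5x the minibatch coefficient of
  determination of the combined score and 1x that of the per-protease
  scores.  A perfect fit on a non-constant minibatch scores exactly -6.
* ``loss_comparator`` (Lc) — a bounded sigmoid penalty pushing predicted
  stability of natural sequences above their scrambles, plus a mild pull
  keeping the two per-protease predictions of naturals similar.  Equal
  predictions give exactly 1.25.
* ``loss_secondary`` (Ld) — categorical cross-entropy of the secondary
  softmax against the one-hot target plus four grammar-invalidity
  estimates (mean and worst position, on both the binarized and the raw
  softmax output).
* ``loss_total`` (L) — ``0.2*Ls + 0.1*Lc + 2*Ld``.

All functions accept numpy arrays or autodiff Tensors and return a Tensor,
so the same code path serves analytic unit checks and training.
"""

from __future__ import annotations

import numpy as np

from .grammar import binarize, grammar_violations, kernel_bank
from .nn import Tensor, as_tensor

#: Printed coefficients of the combined objective.
W_STABILITY, W_COMPARATOR, W_SECONDARY = 0.2, 0.1, 2.0

_EPS = 1e-12


def _r2_term(target: Tensor, pred: Tensor):
    """1 - SSres/SStot over the minibatch; 0 when the targets are constant
    (zero-variance guard, avoids a division by zero)."""
    sstot = ((target - target.data.mean()) ** 2).sum().item()
    if sstot < _EPS:
        return Tensor(0.0)
    ssres = ((target - pred) ** 2).sum()
    return 1.0 - ssres * (1.0 / sstot)


def loss_stability(x, x_hat):
    """Ls over a minibatch.

    ``x`` and ``x_hat`` are (n, 3) arrays/Tensors with columns
    (chymotrypsin, trypsin, min).  Requires n >= 2.
    """
    x, x_hat = as_tensor(x), as_tensor(x_hat)
    if x.shape != x_hat.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("stability batches must both have shape (n, 3)")
    if x.shape[0] < 2:
        raise ValueError("minibatch of at least 2 needed for the R^2 terms")
    mse = ((x - x_hat) ** 2).mean()
    r2_min = _r2_term(x[:, 2], x_hat[:, 2])
    r2_ct = _r2_term(x[:, 0:2].reshape(-1), x_hat[:, 0:2].reshape(-1))
    return mse - 5.0 * r2_min - r2_ct


def loss_comparator(y_nat, y_scr, printed_sign: bool = False):
    """Lc for paired batches of natural / scrambled-natural predictions.

    Batches are (n, 3) with columns (chymotrypsin, trypsin, min).  The
    sigmoid term is low when naturals out-score their scrambles; with
    ``printed_sign=True`` the exponent sign is flipped (rewarding the
    opposite ordering), kept as an ablation switch.
    """
    y_nat, y_scr = as_tensor(y_nat), as_tensor(y_scr)
    if y_nat.shape != y_scr.shape or y_nat.shape[1] != 3:
        raise ValueError("comparator batches must both have shape (n, 3)")
    gap = y_scr[:, 2] - y_nat[:, 2]
    if printed_sign:
        gap = -gap
    cap = 2.5 * gap.sigmoid().mean()
    similarity = 0.001 * ((y_nat[:, 0] - y_nat[:, 1]) ** 2).mean()
    return cap + similarity


def loss_secondary(z, z_hat, bank: np.ndarray | None = None):
    """Ld for one design: cross-entropy plus four invalidity estimates.

    ``z`` is the binary (6, width) target, ``z_hat`` the softmax output.
    Cross-entropy is averaged over columns so the term is width-invariant.
    """
    z_np = z.data if isinstance(z, Tensor) else np.asarray(z)
    z_hat = as_tensor(z_hat)
    if z_np.shape != z_hat.shape:
        raise ValueError("secondary target/prediction shape mismatch")
    if bank is None:
        bank = kernel_bank()
    log_probs = (z_hat + _EPS).log()
    ce = -(Tensor(z_np) * log_probs).sum() * (1.0 / z_np.shape[1])
    z01 = binarize(z_hat)
    v01 = grammar_violations(z01, bank)
    vsm = grammar_violations(z_hat, bank)
    return (ce + 0.8 * v01.mean() + 0.4 * v01.max()
            + 0.1 * vsm.mean() + 0.05 * vsm.max())


def loss_total(ls, lc, ld):
    """L = 0.2*Ls + 0.1*Lc + 2*Ld."""
    return (W_STABILITY * as_tensor(ls) + W_COMPARATOR * as_tensor(lc)
            + W_SECONDARY * as_tensor(ld))
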