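"""Grammar kernels encoding legal secondary-structure symbol successions.

Six 6x2 convolution kernels, one per secondary symbol in row order
(L, E, H, X, J, O).  Column 1 carries a +1 at the focal symbol; column 2
carries -1 at each symbol permitted to follow it:

==========  =================
focal       allowed successors
==========  =================
L (loop)    L, E, H, O
E (strand)  L, E
H (helix)   L, H
X (pad)     X, J
J (start)   L
O (end)     X
==========  =================

Convolving a kernel with a one-hot secondary encoding gives, at each
adjacent pair, ``1[left == focal] - 1[right allowed]``; clipping to [0, 1]
and taking the maximum over the six kernels yields 1 exactly when the pair
violates the successor table.  On a softmax (row-stochastic) encoding the
same expression is a differentiable invalidity estimate.

Note the table above implies a protein can only begin with a loop
(J -> L); ``permissive_start=True`` additionally allows J -> E and J -> H.
"""

from __future__ import annotations

import numpy as np

from .alphabets import SECONDARY, SECONDARY_INDEX
from .nn import Tensor, as_tensor, stack

SUCCESSORS = {
    "L": "LEHO",
    "E": "LE",
    "H": "LH",
    "X": "XJ",
    "J": "L",
    "O": "X",
}


def kernel_bank(permissive_start: bool = False) -> np.ndarray:
    """Return the six grammar kernels as an array of shape (6, 6, 2)."""
    successors = dict(SUCCESSORS)
    if permissive_start:
        successors["J"] = "LEH"
    bank = np.zeros((6, 6, 2))
    for k, focal in enumerate(SECONDARY):
        bank[k, SECONDARY_INDEX[focal], 0] = 1.0
        for succ in successors[focal]:
            bank[k, SECONDARY_INDEX[succ], 1] = -1.0
    return bank


def grammar_violations(z, bank: np.ndarray | None = None):
    """Per-pair violation values for a secondary encoding.

    ``z`` is a (6, width) one-hot or column-stochastic matrix (numpy array
    or Tensor).  Returns a Tensor of length ``width - 1`` whose entry at
    position ``i`` is ``max_k clip(sum(K_k * z[:, i:i+2]), 0, 1)`` — for a
    binary ``z`` this is 1 iff the pair (i, i+1) is an illegal succession.
    """
    z = as_tensor(z)
    if z.ndim != 2 or z.shape[0] != 6:
        raise ValueError("secondary encoding must have shape (6, width)")
    if not np.allclose(z.data.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("secondary encoding columns must sum to 1")
    if bank is None:
        bank = kernel_bank()
    left = z[:, :-1]    # (6, width-1)
    right = z[:, 1:]
    per_kernel = []
    for k in range(bank.shape[0]):
        val = (left * bank[k, :, 0:1]).sum(axis=0) + (right * bank[k, :, 1:2]).sum(axis=0)
        per_kernel.append(val.clip01())
    return stack(per_kernel, axis=0).max(axis=0)


def binarize(z) -> np.ndarray:
    """Per-column argmax one-hot binarization; ties break to the lowest
    row index (L first) for determinism."""
    data = z.data if isinstance(z, Tensor) else np.asarray(z)
    out = np.zeros_like(data)
    out[np.argmax(data, axis=0), np.arange(data.shape[1])] = 1.0
    return out


def violates(left: str, right: str) -> bool:
    """Plain successor-table check for a single symbol pair."""
    return right not in SUCCESSORS[left]
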