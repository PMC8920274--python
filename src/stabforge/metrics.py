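"""Prediction-quality metrics.

``R^2`` here is the goodness-of-fit coefficient ``1 - SSres/SStot`` — more
stringent than the squared Pearson correlation because it does not allow a
re-fit of scale or offset, and can be negative when predictions are worse
than the sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class Metrics:
    r2_fit: float        # 1 - SSres/SStot
    r2_pearson: float    # squared Pearson correlation
    spearman: float      # Spearman rho
    n: int


def evaluate(predictions, observations) -> Metrics:
    """Compute R^2, squared Pearson r^2 and Spearman rho for paired vectors."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("need two paired 1-D vectors of length >= 2")
    if not (np.isfinite(p).all() and np.isfinite(o).all()):
        raise ValueError("non-finite values in inputs")
    sstot = float(((o - o.mean()) ** 2).sum())
    if sstot == 0.0:
        raise ValueError("observations have zero variance; R^2 undefined")
    ssres = float(((o - p) ** 2).sum())
    r2_fit = 1.0 - ssres / sstot
    if np.std(p) == 0.0:
        r2_pearson = 0.0
        rho = 0.0
    else:
        r2_pearson = float(stats.pearsonr(p, o)[0] ** 2)
        rho = float(stats.spearmanr(p, o)[0])
    return Metrics(r2_fit=r2_fit, r2_pearson=r2_pearson, spearman=rho, n=len(p))
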