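"""Cross-chip EC50 reconciliation.

Different assay runs (chips) measure EC50 on shifted, rescaled scales, and
a change of expression vector compresses high values below a soft ceiling.
Two tools put all chips on one scale:

* :func:`fit_orthogonal` — total-least-squares (orthogonal / Deming with
  error-variance ratio 1) regression between ladder proteins measured on
  two chips; the resulting :class:`LinearMap` moves new-chip values onto
  the reference scale.
* :func:`fit_piecewise_vector_map` — a two-parameter piecewise-linear
  orthogonal regression between expression vectors: identity (y = x) up to
  an inflection ``c``, slope ``s`` beyond it.  Inverting this map undoes
  the ceiling compression of the newer vector.

:func:`reconcile_chip` chains the two per protease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .design import CHYMOTRYPSIN, TRYPSIN

__all__ = [
    "LinearMap", "PiecewiseVectorMap", "fit_orthogonal",
    "fit_piecewise_vector_map", "invert_map", "reconcile_chip",
]


@dataclass
class LinearMap:
    slope: float
    intercept: float

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def inverse(self) -> "LinearMap":
        if self.slope == 0:
            raise ValueError("zero slope is not invertible")
        return LinearMap(1.0 / self.slope, -self.intercept / self.slope)


@dataclass
class PiecewiseVectorMap:
    """Identity below the inflection ``c``; slope ``s`` above it.

    ``f(x) = x`` for ``x <= c`` and ``f(x) = c + s (x - c)`` otherwise;
    continuous at ``c`` and invertible iff ``s > 0``.
    """

    c: float
    s: float
    flat_fit: bool = False   # set when the data showed no curvature

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x <= self.c, x, self.c + self.s * (x - self.c))

    def inverse(self, y):
        if self.s <= 0:
            raise ValueError("non-invertible piecewise map (s <= 0)")
        y = np.asarray(y, dtype=float)
        return np.where(y <= self.c, y, self.c + (y - self.c) / self.s)


def invert_map(vmap: PiecewiseVectorMap, y):
    """Exact functional inverse of the piecewise map at *y*."""
    return vmap.inverse(y)


def fit_orthogonal(x: Sequence[float], y: Sequence[float]) -> LinearMap:
    """Total-least-squares line through (x, y), error-variance ratio 1.

    Minimizes summed squared perpendicular distances; the slope is the
    direction of the leading principal component of the centered data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate spread: zero variance in x or y")
    xc, yc = x - x.mean(), y - y.mean()
    cov = np.cov(np.vstack([xc, yc]))
    _, vecs = np.linalg.eigh(cov)
    direction = vecs[:, -1]  # leading eigenvector
    if direction[0] == 0:
        raise ValueError("vertical TLS line: slope undefined")
    slope = direction[1] / direction[0]
    intercept = y.mean() - slope * x.mean()
    return LinearMap(float(slope), float(intercept))


def _piecewise_residual(params, x, y):
    c, s = params
    # orthogonal distance of each point to the two-segment curve
    # segment 1: y = x for x <= c; segment 2: through (c, c) with slope s
    d1 = np.abs(y - x) / np.sqrt(2.0)
    foot1 = (x + y) / 2.0
    d1 = np.where(foot1 <= c, d1,
                  np.sqrt((x - c) ** 2 + (y - c) ** 2))
    dx, dy = x - c, y - c
    t = (dx + s * dy) / (1.0 + s * s)
    d2_perp = np.abs(dy - s * dx) / np.sqrt(1.0 + s * s)
    d2 = np.where(t >= 0, d2_perp, np.sqrt(dx**2 + dy**2))
    return np.minimum(d1, d2)


def fit_piecewise_vector_map(x_old: Sequence[float], y_new: Sequence[float],
                             flat_tol: float = 0.05) -> PiecewiseVectorMap:
    """Fit (c, s) minimizing summed squared orthogonal distances.

    A grid over candidate inflection points (the x-quantiles) with an inner
    1-D slope optimization seeds a Nelder-Mead polish, making the search
    reproducible and robust to local minima.  If the fitted slope is within
    *flat_tol* of 1 the data showed no curvature; ``c`` is reported as
    ``max(x)`` with the ``flat_fit`` flag raised.
    """
    x = np.asarray(x_old, dtype=float)
    y = np.asarray(y_new, dtype=float)
    if len(x) < 10 or len(x) != len(y):
        raise ValueError("need at least 10 paired points")

    def cost(params):
        return float((_piecewise_residual(params, x, y) ** 2).sum())

    best = None
    for c0 in np.quantile(x, np.linspace(0.05, 0.95, 19)):
        res = optimize.minimize_scalar(lambda s: cost((c0, s)),
                                       bounds=(1e-3, 2.0), method="bounded")
        if best is None or res.fun < best[1]:
            best = ((c0, float(res.x)), res.fun)
    polish = optimize.minimize(cost, best[0], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-14,
                                        "maxiter": 4000})
    c, s = float(polish.x[0]), float(polish.x[1])
    if abs(s - 1.0) < flat_tol:
        return PiecewiseVectorMap(c=float(x.max()), s=1.0, flat_fit=True)
    return PiecewiseVectorMap(c=c, s=s)


def reconcile_chip(new_chip: pd.DataFrame, reference_chip: pd.DataFrame,
                   ladder_ids: Sequence[str],
                   vector_map: Optional[dict] = None) -> tuple[pd.DataFrame, dict]:
    """Map a new chip's EC50 table onto the reference chip's scale.

    Per protease: optionally undo the expression-vector compression with
    ``invert(vector_map[protease])``, then fit a ladder
    :class:`LinearMap` (new -> reference, total least squares) on the shared
    ladder designs and apply it to every row.  Returns the calibrated table
    and a report with fit parameters and ladder residuals.
    """
    ladder = [i for i in ladder_ids if i in new_chip.index
              and i in reference_chip.index]
    if len(ladder) < 3:
        raise ValueError("need at least 3 ladder designs present on both chips")
    out = new_chip.copy()
    report: dict = {"n_ladder": len(ladder)}
    for protease in (TRYPSIN, CHYMOTRYPSIN):
        col = f"{protease}_ec50"
        values = new_chip[col].to_numpy(dtype=float)
        if vector_map is not None and protease in vector_map:
            values = vector_map[protease].inverse(values)
        ladder_new = pd.Series(values, index=new_chip.index).loc[ladder]
        ladder_ref = reference_chip.loc[ladder, col]
        lmap = fit_orthogonal(ladder_new.to_numpy(), ladder_ref.to_numpy())
        out[col] = lmap(values)
        residuals = lmap(ladder_new.to_numpy()) - ladder_ref.to_numpy()
        report[protease] = {"slope": lmap.slope, "intercept": lmap.intercept,
                            "rmse": float(np.sqrt((residuals**2).mean()))}
    return out, report
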