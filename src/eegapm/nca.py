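"""Neighborhood component analysis with a diagonal (per-feature) metric.

Learns one nonnegative weight per feature by maximizing the regularized
expected leave-one-out classification objective

    F(v) = sum_i sum_{j : y_j = y_i, j != i} p_ij  -  lambda * sum_f v_f**2

with soft-neighbor probabilities

    p_ij = exp(-d_ij) / sum_{k != i} exp(-d_ik),
    d_ij = sum_f v_f**2 * |x_if - x_jf|        (weighted Manhattan kernel).

The raw parameters v are unconstrained; the reported weight of feature f is
v_f**2, which is nonnegative by construction.  Features are z-scored before
fitting (distance kernels are scale-sensitive); optimization uses L-BFGS-B
on -F with an analytic gradient.  The pairwise per-feature difference
tensor does not depend on v and is precomputed once when it fits in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fusion import FeatureMatrix

logger = logging.getLogger(__name__)

#: Precompute the (n, n, p) |x_if - x_jf| tensor below this many bytes.
_PRECOMPUTE_LIMIT = 1_500_000_000
_CHUNK = 64


@dataclass
class FeatureWeights:
    """Learned per-feature weights and the induced descending ranking."""

    w: np.ndarray
    ranking: np.ndarray
    lam: float
    seed: int
    feature_names: list = field(default_factory=list)
    objective_history: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(self.w.size)]
        rank_of = np.empty(self.w.size, dtype=int)
        rank_of[self.ranking] = np.arange(1, self.w.size + 1)
        return pd.DataFrame(
            {"feature_name": names, "weight": self.w, "rank": rank_of}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


class _DiffTensor:
    """Pairwise per-feature absolute differences, materialized or chunked."""

    def __init__(self, X: np.ndarray):
        self.X = X
        n, p = X.shape
        self.D = None
        if n * n * p * 8 <= _PRECOMPUTE_LIMIT:
            self.D = np.abs(X[:, None, :] - X[None, :, :])

    def distances(self, w: np.ndarray) -> np.ndarray:
        if self.D is not None:
            return self.D @ w
        n, p = self.X.shape
        d = np.zeros((n, n))
        for s in range(0, p, _CHUNK):
            blk = slice(s, min(s + _CHUNK, p))
            d += np.abs(self.X[:, None, blk] - self.X[None, :, blk]) @ w[blk]
        return d

    def weighted_sum(self, A: np.ndarray) -> np.ndarray:
        """g_f = sum_ij A_ij |x_if - x_jf| for every feature f."""
        if self.D is not None:
            return np.einsum("ij,ijk->k", A, self.D)
        n, p = self.X.shape
        g = np.zeros(p)
        for s in range(0, p, _CHUNK):
            blk = slice(s, min(s + _CHUNK, p))
            D = np.abs(self.X[:, None, blk] - self.X[None, :, blk])
            g[blk] = np.einsum("ij,ijk->k", A, D)
        return g


def _objective_and_grad(v, diffs: _DiffTensor, same_class, lam):
    """(-F, -dF/dv) for the regularized NCA objective."""
    w = v * v
    d = diffs.distances(w)
    np.fill_diagonal(d, np.inf)
    d_min = d.min(axis=1, keepdims=True)
    E = np.exp(-(d - d_min))
    np.fill_diagonal(E, 0.0)
    Z = E.sum(axis=1, keepdims=True)
    P = E / np.where(Z > 0, Z, 1.0)
    p_i = (P * same_class).sum(axis=1)
    F = p_i.sum() - lam * w.sum()
    # dF/dw_f = sum_ij A_ij |x_if - x_jf|,  A_ij = (p_i - [same]) * p_ij
    A = (p_i[:, None] - same_class) * P
    grad_w = diffs.weighted_sum(A)
    grad_v = 2.0 * v * (grad_w - lam)
    return -F, -grad_v


def _same_class_matrix(y: np.ndarray) -> np.ndarray:
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    return same


def nca_objective(v, X, y, lam) -> float:
    """Value of the regularized NCA objective F at raw parameters v."""
    diffs = _DiffTensor(np.asarray(X, dtype=float))
    same = _same_class_matrix(np.asarray(y))
    neg_f, _ = _objective_and_grad(np.asarray(v, dtype=float), diffs, same, lam)
    return -neg_f


def nca_gradient(v, X, y, lam) -> np.ndarray:
    """Analytic gradient dF/dv at raw parameters v."""
    diffs = _DiffTensor(np.asarray(X, dtype=float))
    same = _same_class_matrix(np.asarray(y))
    _, neg_g = _objective_and_grad(np.asarray(v, dtype=float), diffs, same, lam)
    return -neg_g


def nca_fit(
    features: FeatureMatrix,
    lam: float | None = None,
    seed: int = 0,
    standardize: bool = True,
    max_iter: int = 200,
) -> FeatureWeights:
    """Fit diagonal NCA weights and rank features by descending weight.

    ``lam`` defaults to 1/n (n = number of rows).  Ties in weight are broken
    toward the lower feature index so the ranking is stable.  With a single
    class present only the penalty term remains; the fit returns near-zero
    weights with a warning.
    """
    X = np.asarray(features.values, dtype=float)
    y = np.asarray(features.labels)
    n, p = X.shape
    if lam is None:
        lam = 1.0 / n
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if np.unique(y).size < 2:
        logger.warning("single-class input: NCA objective is penalty-only")
    same = _same_class_matrix(y)
    diffs = _DiffTensor(X)

    rng = np.random.default_rng(seed)
    v0 = 1.0 / np.sqrt(p) + 0.01 * rng.standard_normal(p)

    history = []

    def record(vk):
        neg_f, _ = _objective_and_grad(vk, diffs, same, lam)
        history.append(-neg_f)

    record(v0)
    res = minimize(
        _objective_and_grad,
        v0,
        args=(diffs, same, lam),
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_iter},
    )
    v = res.x
    w = v * v
    # Stable argsort on (-w, index): descending weight, lower index first.
    ranking = np.lexsort((np.arange(p), -w))
    return FeatureWeights(
        w=w,
        ranking=ranking,
        lam=lam,
        seed=seed,
        feature_names=list(features.feature_names),
        objective_history=history,
    )


def select_top(
    features: FeatureMatrix, weights: FeatureWeights, k: int
) -> FeatureMatrix:
    """Keep the k best-ranked feature columns (row order unchanged)."""
    p = features.n_features
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}")
    cols = weights.ranking[:k]
    return FeatureMatrix(
        values=features.values[:, cols],
        feature_names=[features.feature_names[c] for c in cols],
        labels=features.labels,
        subject_ids=features.subject_ids,
    )
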