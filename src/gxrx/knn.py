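"""k-nearest-neighbor regression of ln(IC50) and its squared-error loss.

The prediction rule: the predicted ln(IC50) of a sample is the arithmetic
mean of the observed ln(IC50) values of its k nearest neighbors in the
d-dimensional Euclidean space spanned by a gene set, the sample itself
never being eligible as its own neighbor.  Distances are compared on the
squared Euclidean scale (a monotone equivalent); ties are broken by the
lowest pool column index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "NeighborQuery",
    "InsufficientNeighborsError",
    "knn_regress",
    "knn_predict_pool",
    "loo_predictions",
    "squared_error_loss",
]


class InsufficientNeighborsError(ValueError):
    """k exceeds the number of eligible neighbor-pool columns."""


@dataclass
class NeighborQuery:
    """One kNN regression query against a neighbor pool.

    pool_matrix: d x n matrix (gene-subset rows, neighbor-pool columns)
    pool_values: length-n observed ln(IC50)
    query_vector: length-d coordinates of the sample to predict
    k: neighbor count
    exclude_index: optional pool column that is never eligible (self)
    """

    pool_matrix: np.ndarray
    pool_values: np.ndarray
    query_vector: np.ndarray
    k: int
    exclude_index: Optional[int] = None


def knn_regress(q: NeighborQuery) -> float:
    """Mean observed value over the k nearest eligible pool columns."""
    pool = np.asarray(q.pool_matrix, dtype=float)
    if pool.ndim == 1:
        pool = pool[None, :]
    values = np.asarray(q.pool_values, dtype=float)
    query = np.atleast_1d(np.asarray(q.query_vector, dtype=float))
    n = pool.shape[1]
    eligible = n - (1 if q.exclude_index is not None else 0)
    if q.k < 1 or q.k > eligible:
        raise InsufficientNeighborsError(f"k={q.k} with only {eligible} eligible neighbors")
    diff = pool - query[:, None]
    dist = np.einsum("ij,ij->j", diff, diff)
    if q.exclude_index is not None:
        dist[q.exclude_index] = np.inf
    # stable argsort implements the lowest-index tie rule
    nearest = np.argsort(dist, kind="stable")[: q.k]
    return float(values[nearest].mean())


def _pairwise_sq_dists(pool: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, queries (rows) x pool columns."""
    pn = np.einsum("ij,ij->j", pool, pool)
    qn = np.einsum("ij,ij->j", queries, queries)
    return np.maximum(qn[:, None] + pn[None, :] - 2.0 * (queries.T @ pool), 0.0)


def _k_nearest_mean(dist: np.ndarray, values: np.ndarray, k: int) -> np.ndarray:
    """Row-wise mean of ``values`` over the k smallest entries of ``dist``.

    Implements the lowest-column-index tie rule exactly: all columns strictly
    below the kth-smallest distance are taken, and the remainder is filled
    from the columns equal to it in increasing index order.
    """
    kth = np.partition(dist, k - 1, axis=1)[:, k - 1:k]
    lt = dist < kth
    eq = dist == kth
    chosen = lt | eq
    # rows with more than k candidates have ties at the boundary: keep the
    # tied columns with the lowest indices only
    excess = chosen.sum(axis=1) - k
    for i in np.flatnonzero(excess > 0):
        tied = np.flatnonzero(eq[i])
        chosen[i, tied[len(tied) - excess[i]:]] = False
    return (chosen @ values) / k


def knn_predict_pool(pool: np.ndarray, pool_values: np.ndarray, queries: np.ndarray, k: int) -> np.ndarray:
    """Vectorized kNN regression of many query columns against one pool.

    pool: d x n, queries: d x m.  Returns length-m predictions.  No
    exclusion: meant for test-set / external samples disjoint from the pool.
    """
    pool = np.asarray(pool, dtype=float)
    queries = np.asarray(queries, dtype=float)
    values = np.asarray(pool_values, dtype=float)
    if k < 1 or k > pool.shape[1]:
        raise InsufficientNeighborsError(f"k={k} with pool of {pool.shape[1]}")
    dist = _pairwise_sq_dists(pool, queries)
    return _k_nearest_mean(dist, values, k)


def loo_predictions(X_sub: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Leave-one-out kNN predictions for every column of X_sub.

    Element i equals ``knn_regress`` with query = column i and column i
    excluded from the pool.
    """
    X_sub = np.asarray(X_sub, dtype=float)
    if X_sub.ndim == 1:
        X_sub = X_sub[None, :]
    y = np.asarray(y, dtype=float)
    n = X_sub.shape[1]
    if n <= k:
        raise InsufficientNeighborsError(f"leave-one-out with n={n} cannot supply k={k} neighbors")
    dist = _pairwise_sq_dists(X_sub, X_sub)
    np.fill_diagonal(dist, np.inf)
    return _k_nearest_mean(dist, y, k)


def squared_error_loss(obs: np.ndarray, pred: np.ndarray) -> float:
    """Sum of squared deviations between observed and predicted values."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    d = obs - pred
    return float(d @ d)
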