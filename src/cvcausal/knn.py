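"""Shared k-nearest-neighbor machinery.

Distances between embedding vectors use the maximum norm (largest absolute
difference between corresponding components).  Neighbor searches exclude a
temporal band around the query (Theiler window) so serially correlated
vectors cannot masquerade as dynamical neighbors.  The forward-selection
estimators exploit the max-norm identity

    d_{S + c}(a, b) = max(d_S(a, b), |c_a - c_b|)

to grow a cached pairwise distance matrix one component at a time instead
of recomputing it from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingMatrix
from .exceptions import InsufficientDataError

DEFAULT_K = 30


@dataclass(frozen=True)
class NeighborSet:
    """k nearest admissible rows of a query, distances ascending.

    Ties in distance are broken toward the smaller row index.
    """

    query: int
    indices: np.ndarray
    distances: np.ndarray

    @property
    def k(self) -> int:
        return self.indices.size


def _as_design(matrix) -> np.ndarray:
    if isinstance(matrix, EmbeddingMatrix):
        return matrix.X
    return np.atleast_2d(np.asarray(matrix, dtype=float))


def knn_search(matrix, query: int, k: int = DEFAULT_K,
               exclusion: int = 0) -> NeighborSet:
    """Exact k-NN of one row under the maximum norm.

    Parameters
    ----------
    matrix : EmbeddingMatrix or (N, q) array
    query : int
        Row index of the query vector.
    k : int
        Number of neighbors.
    exclusion : int
        Theiler half-width ``T``: rows with ``|m - query| <= T`` are
        inadmissible (the query itself always is).
    """
    X = _as_design(matrix)
    n = X.shape[0]
    if X.ndim != 2 or not 0 <= query < n:
        raise InsufficientDataError(f"query row {query} outside matrix")
    if X.shape[1] == 0:
        dist = np.zeros(n)
    else:
        dist = np.abs(X - X[query]).max(axis=1)
    admissible = np.abs(np.arange(n) - query) > exclusion
    if admissible.sum() < k:
        raise InsufficientDataError(
            f"only {int(admissible.sum())} admissible rows for k={k}"
        )
    cand = np.nonzero(admissible)[0]
    # sort by (distance, row index): lexsort uses the last key as primary
    order = np.lexsort((cand, dist[cand]))[:k]
    chosen = cand[order]
    return NeighborSet(query, chosen, dist[chosen])


def zero_order_predict(neighbors, images) -> float:
    """Inverse-distance weighted mean of the neighbor images.

    A zero-distance neighbor is an exact match in the embedding space;
    in the limit of inverse-distance weights exact matches dominate, so
    the prediction is then the unweighted mean of the zero-distance
    images.
    """
    if isinstance(neighbors, NeighborSet):
        dist = neighbors.distances
    else:
        dist = np.asarray(neighbors, dtype=float)
    images = np.asarray(images, dtype=float)
    if dist.size == 0:
        raise InsufficientDataError("empty neighbor set")
    zero = dist == 0.0
    if zero.any():
        return float(images[zero].mean())
    # weights are scale-invariant; normalizing by the smallest distance
    # keeps 1/d finite even for subnormal distances
    w = dist.min() / dist
    return float((w * images).sum() / w.sum())


def pair_within_eps_probability(values, eps: float) -> float:
    """Fraction of unordered distinct pairs closer than the tolerance.

    Closed inequality (``|v_a - v_b| <= eps``); self-pairs excluded.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need at least 2 values")
    diffs = np.abs(v[:, None] - v[None, :])
    iu = np.triu_indices(v.size, k=1)
    return float((diffs[iu] <= eps).mean())


# ---------------------------------------------------------------------------
# vectorized engine used by the forward-selection estimators


def pairwise_maxnorm(X) -> np.ndarray:
    """Full pairwise max-norm distance matrix of the rows of X."""
    X = _as_design(X)
    n, q = X.shape
    D = np.zeros((n, n))
    for c in range(q):
        D = np.maximum(D, np.abs(X[:, c, None] - X[None, :, c]))
    return D

def update_maxnorm(D: np.ndarray, column: np.ndarray) -> np.ndarray:
    """Distance matrix after appending one component column."""
    return np.maximum(D, np.abs(column[:, None] - column[None, :]))


def exclusion_infmask(n: int, exclusion: int) -> np.ndarray:
    """Additive mask: +inf inside the Theiler band |i-j| <= T, else 0."""
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= exclusion
    mask = np.zeros((n, n))
    mask[band] = np.inf
    return mask


def neighbor_table(D: np.ndarray, k: int, infmask: np.ndarray,
                   ordered: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """k-NN of every row at once from a pairwise distance matrix.

    Returns ``(indices, distances)`` of shape (N, k).  With
    ``ordered=True`` rows are sorted by (distance, index) — the stable
    argsort reproduces the smaller-index tie-break of :func:`knn_search`.
    ``ordered=False`` returns the same k-sets in arbitrary order via a
    partial partition, an order-of-magnitude faster on long series;
    every selection score (inverse-distance prediction, within-eps pair
    counts) is permutation-invariant over the neighbor set, so the
    estimators use this path.
    """
    n = D.shape[0]
    masked = D + infmask
    admissible = n - (np.isinf(infmask)).sum(axis=1)
    if admissible.min() < k:
        raise InsufficientDataError(
            f"row with only {int(admissible.min())} admissible neighbors for k={k}"
        )
    if ordered or k >= n:
        order = np.argsort(masked, axis=1, kind="stable")[:, :k]
    else:
        order = np.argpartition(masked, k - 1, axis=1)[:, :k]
    return order, np.take_along_axis(masked, order, axis=1)


def predict_all(neighbor_idx: np.ndarray, neighbor_dist: np.ndarray,
                target: np.ndarray) -> np.ndarray:
    """Zero-order prediction of every row from its neighbor table."""
    images = target[neighbor_idx]
    zero = neighbor_dist == 0.0
    any_zero = zero.any(axis=1)
    # per-row scaling by the smallest distance keeps weights finite
    dmin = neighbor_dist.min(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(zero, 0.0, dmin / np.where(zero, 1.0, neighbor_dist))
    pred = np.empty(neighbor_idx.shape[0])
    ok = ~any_zero
    pred[ok] = (w[ok] * images[ok]).sum(axis=1) / w[ok].sum(axis=1)
    if any_zero.any():
        counts = zero[any_zero].sum(axis=1)
        pred[any_zero] = (images[any_zero] * zero[any_zero]).sum(axis=1) / counts
    return pred


def conditional_entropy_from_images(images: np.ndarray, eps: float) -> float:
    """Mean per-point Shannon entropy of k-NN image samples.

    ``images`` has one row per query (the images of its k neighbors); the
    per-point entropy is -ln of the within-eps pair probability among the
    row, floored at 1/(number of pairs) so the estimate stays finite.
    """
    n, k = images.shape
    if k < 2:
        raise InsufficientDataError("need k >= 2 images per point")
    diffs = np.abs(images[:, :, None] - images[:, None, :])
    iu = np.triu_indices(k, k=1)
    within = diffs[:, iu[0], iu[1]] <= eps
    n_pairs = k * (k - 1) // 2
    prob = np.maximum(within.mean(axis=1), 1.0 / n_pairs)
    return float(-np.log(prob).mean())
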