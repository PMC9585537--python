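"""K-means clustering and a distance-threshold noise filter.

Lloyd iteration with seeded uniform-random initialization over distinct
points (k-means++ available behind a flag), best of ``n_restarts`` by
inertia.  Noise filtering removes rows whose distance to their assigned
centroid exceeds a quantile of all such distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from cardiodx.datakit import FeatureTable

__all__ = ["DEFAULT_K", "ClusterModel", "kmeans_fit", "assign", "filter_noise", "default_k"]

logger = logging.getLogger(__name__)

#: Default cluster count when none is requested and n is large enough.
DEFAULT_K = 256


@dataclass
class ClusterModel:
    """Fitted K-means state.

    centroids : (k, J) cluster centers.
    assignments : (n,) cluster index per training point.
    counts : (k,) points per cluster, summing to n.
    inertia : total within-cluster squared Euclidean distance.
    n_iter : Lloyd iterations executed by the winning restart.
    """

    centroids: np.ndarray
    assignments: np.ndarray
    counts: np.ndarray
    inertia: float
    k: int
    n_iter: int
    inertia_history: list[float] | None = None  # per-iteration, winning restart


def default_k(n: int) -> int:
    """Default cluster count: 256, clamped to floor(n/2) when n < 512."""
    if n < 2 * DEFAULT_K:
        k = max(1, n // 2)
        logger.warning("n=%d cannot support %d clusters; clamping k to %d", n, DEFAULT_K, k)
        return k
    return DEFAULT_K


def _lloyd(points: np.ndarray, k: int, rng: np.random.Generator, max_iter: int,
           init: str) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n = points.shape[0]
    if init == "kmeans++":
        centroids = _kmeanspp_init(points, k, rng)
    else:
        centroids = points[rng.choice(n, size=k, replace=False)].copy()

    labels = np.full(n, -1, dtype=int)
    n_iter = 0
    history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        d2 = cdist(points, centroids, "sqeuclidean")
        new_labels = np.argmin(d2, axis=1)  # argmin ties break to lowest index
        history.append(float(d2[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = points[labels == c]
            if members.shape[0] > 0:
                centroids[c] = members.mean(axis=0)
            else:
                # empty-cluster repair: re-seed at the globally farthest point
                far = np.argmax(np.min(cdist(points, centroids, "sqeuclidean"), axis=1))
                centroids[c] = points[far]
    d2 = cdist(points, centroids, "sqeuclidean")
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    return centroids, labels, inertia, n_iter, history


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    closest = cdist(points, centroids[:1], "sqeuclidean")[:, 0]
    for c in range(1, k):
        probs = closest / closest.sum() if closest.sum() > 0 else np.full(n, 1.0 / n)
        centroids[c] = points[rng.choice(n, p=probs)]
        closest = np.minimum(closest, cdist(points, centroids[c : c + 1], "sqeuclidean")[:, 0])
    return centroids


def kmeans_fit(
    points: np.ndarray,
    k: int | None = None,
    seed: int = 0,
    max_iter: int = 300,
    n_restarts: int = 10,
    init: str = "random",
) -> ClusterModel:
    """Fit K-means by Lloyd iteration; return the best of ``n_restarts``.

    Each restart assigns every point to its nearest centroid by Euclidean
    distance, recomputes each centroid as the mean of its assigned points,
    and stops when no point is reassigned (or at ``max_iter``).  ``k``
    defaults to 256, clamped to floor(n/2) for small inputs.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if not np.isfinite(points).all():
        raise ValueError("points contain non-finite values")
    n = points.shape[0]
    if k is None:
        k = default_k(n)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n={n}")
    if max_iter < 1 or n_restarts < 1:
        raise ValueError("max_iter and n_restarts must be positive")
    if init not in ("random", "kmeans++"):
        raise ValueError(f"unknown init {init!r}")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        result = _lloyd(points, k, rng, max_iter, init)
        if best is None or result[2] < best[2]:
            best = result
    centroids, labels, inertia, n_iter, history = best
    counts = np.bincount(labels, minlength=k)
    return ClusterModel(
        centroids=centroids,
        assignments=labels,
        counts=counts,
        inertia=inertia,
        k=k,
        n_iter=n_iter,
        inertia_history=history,
    )


def assign(points: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Nearest-centroid labels; ties break to the lowest centroid index."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"feature dimension {points.shape[-1]} does not match centroids "
            f"({model.centroids.shape[1]})"
        )
    return np.argmin(cdist(points, model.centroids, "sqeuclidean"), axis=1)


def filter_noise(
    table: FeatureTable, model: ClusterModel, quantile: float = 0.95
) -> tuple[FeatureTable, np.ndarray]:
    """Drop rows far from their assigned centroid.

    A row is removed when its Euclidean distance to its assigned centroid
    strictly exceeds the given quantile of all such distances.  Returns the
    filtered table and the removed row indices (original order).
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    labels = assign(table.X, model)
    dist = np.linalg.norm(table.X - model.centroids[labels], axis=1)
    threshold = np.quantile(dist, quantile)
    removed = np.flatnonzero(dist > threshold)
    kept = np.flatnonzero(dist <= threshold)
    return table.take(kept), removed
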