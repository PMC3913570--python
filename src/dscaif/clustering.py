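"""K-means (Lloyd) and fuzzy c-means clustering of concentration time series.

Both algorithms treat each curve as a point in R^T (raw concentration samples,
no area normalization by default) and initialize centroids as ``k`` distinct
curves drawn uniformly at random from the data. A single seeded run is
performed per call; run-to-run variability under different seeds is exactly
what the repeatability experiment measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ClusterConfig", "ClusterResult", "kmeans_cluster", "fcm_cluster", "cluster_mean_curves"]


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering configuration shared by both algorithms."""

    n_clusters: int = 5
    algorithm: str = "kmeans"
    fuzziness_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int | None = None
    normalize_area: bool = False

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
        if self.algorithm not in ("kmeans", "fcm"):
            raise ValueError("algorithm must be 'kmeans' or 'fcm'")
        if not self.fuzziness_m > 1:
            raise ValueError("fuzziness exponent must exceed 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class ClusterResult:
    """Outcome of one clustering run.

    ``assignments`` are hard labels (for FCM, the argmax of each membership
    row, ties to the lowest cluster index). ``memberships`` is ``None`` for
    K-means. ``mean_curves[j]`` is the mean of cluster ``j``'s raw member
    curves, or ``None`` if the cluster is empty. ``objective_trace`` is the
    per-iteration objective (WCSS or the fuzzy objective), non-increasing.
    """

    assignments: np.ndarray
    centroids: np.ndarray
    mean_curves: list
    objective_trace: np.ndarray
    n_iter: int
    memberships: np.ndarray | None = None


def _prepare(X: np.ndarray, cfg: ClusterConfig) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (curves x features) matrix")
    if X.shape[0] < cfg.n_clusters:
        raise ValueError(f"need at least {cfg.n_clusters} curves, got {X.shape[0]}")
    if cfg.normalize_area:
        areas = X.sum(axis=1, keepdims=True)
        if np.any(areas == 0):
            raise ValueError("cannot area-normalize a zero-area curve")
        X = X / areas
    return X


def _init_centroids(X: np.ndarray, cfg: ClusterConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(X.shape[0], size=cfg.n_clusters, replace=False)
    return X[idx].copy()


def cluster_mean_curves(X: np.ndarray, assignments: np.ndarray, n_clusters: int) -> list:
    """Per-cluster mean of the raw member curves; ``None`` for an empty cluster."""
    X = np.asarray(X, dtype=float)
    means = []
    for j in range(n_clusters):
        members = X[assignments == j]
        means.append(members.mean(axis=0) if members.shape[0] else None)
    return means


def kmeans_cluster(X: np.ndarray, cfg: ClusterConfig) -> ClusterResult:
    """Lloyd's K-means with seeded random data-point initialization.

    Converges when the assignments stop changing (or ``max_iter`` is hit).
    An emptied cluster is repaired by reseeding its centroid to the point
    currently farthest from its own centroid.
    """
    X = _prepare(X, cfg)
    k = cfg.n_clusters
    centroids = _init_centroids(X, cfg)
    assignments = np.full(X.shape[0], -1, dtype=int)
    trace: list[float] = []
    n_iter = 0

    for n_iter in range(1, cfg.max_iter + 1):
        d2 = cdist(X, centroids, "sqeuclidean")
        new_assign = np.argmin(d2, axis=1)

        # repair empty clusters: move their centroid onto the farthest point
        for j in range(k):
            if not np.any(new_assign == j):
                cost = d2[np.arange(X.shape[0]), new_assign]
                far = int(np.argmax(cost))
                centroids[j] = X[far]
                new_assign[far] = j
                d2 = cdist(X, centroids, "sqeuclidean")

        converged = np.array_equal(new_assign, assignments)
        assignments = new_assign
        for j in range(k):
            members = X[assignments == j]
            if members.shape[0]:  # degenerate data can defeat the repair; keep the old centroid
                centroids[j] = members.mean(axis=0)
        wcss = float(((X - centroids[assignments]) ** 2).sum())
        trace.append(wcss)
        if converged:
            break

    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        mean_curves=cluster_mean_curves(X, assignments, k),
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
    )


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; coincident points get full membership."""
    n, k = d2.shape
    u = np.zeros((n, k))
    zero_rows = np.any(d2 <= 0, axis=1)
    if np.any(zero_rows):
        hit = np.argmax(d2[zero_rows] <= 0, axis=1)
        u[np.where(zero_rows)[0], hit] = 1.0
    ok = ~zero_rows
    if np.any(ok):
        power = 1.0 / (m - 1.0)
        inv = d2[ok] ** -power
        u[ok] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fcm_cluster(X: np.ndarray, cfg: ClusterConfig) -> ClusterResult:
    """Fuzzy c-means: alternating membership/centroid updates.

    Objective ``sum_ij u_ij^m ||x_i - c_j||^2``; stops when the largest
    absolute membership change drops below ``tol``. Membership rows sum to 1.
    """
    X = _prepare(X, cfg)
    k = cfg.n_clusters
    m = cfg.fuzziness_m
    centroids = _init_centroids(X, cfg)
    u_prev = None
    trace: list[float] = []
    n_iter = 0

    for n_iter in range(1, cfg.max_iter + 1):
        d2 = cdist(X, centroids, "sqeuclidean")
        u = _fcm_memberships(d2, m)
        trace.append(float((u**m * d2).sum()))
        if u_prev is not None and float(np.max(np.abs(u - u_prev))) < cfg.tol:
            break
        u_prev = u
        um = u**m
        weights = um.sum(axis=0)
        # a cluster with vanishing total membership keeps its old centroid
        nonzero = weights > 0
        centroids[nonzero] = (um.T @ X)[nonzero] / weights[nonzero, None]

    assignments = np.argmax(u, axis=1)
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        mean_curves=cluster_mean_curves(X, assignments, k),
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        memberships=u,
    )
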