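"""K-means and PAM clustering of probes in curve-feature space.

Features mix units (times, log2 levels, slopes), so columns are standardized
before clustering by default.  Both algorithms run under Euclidean or
Manhattan distance and are deterministic given a seed; quality is reported as
per-item silhouettes, homogeneity (mean distance to the cluster
representative; lower is tighter) and separation (size-weighted mean distance
between representatives; higher is better).  The number of clusters is chosen
by scanning k and keeping the highest average silhouette.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, UsageError
from .features import FeatureMatrix

__all__ = [
    "ClusterConfig",
    "ClusteringResult",
    "standardize",
    "dist",
    "kmeans",
    "pam",
    "silhouette",
    "homogeneity",
    "separation",
    "choose_k",
    "cluster_features",
]


@dataclass
class ClusterConfig:
    """Algorithm, metric and size parameters for one clustering run."""

    algorithm: str = "pam"  # kmeans | pam
    metric: str = "euclidean"  # euclidean | manhattan
    k: int = 2
    seed: int = 0
    max_iter: int = 100
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.algorithm not in ("kmeans", "pam"):
            raise ParameterError(f"algorithm must be 'kmeans' or 'pam', got {self.algorithm!r}")
        if self.metric not in ("euclidean", "manhattan"):
            raise ParameterError(f"metric must be 'euclidean' or 'manhattan', got {self.metric!r}")
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")


@dataclass
class ClusteringResult:
    """Assignments, representatives and quality metrics for one clustering."""

    assignments: np.ndarray
    k: int
    metric: str
    algorithm: str
    objective: float
    centers: np.ndarray | None = None  # k-means centroids
    medoid_indices: np.ndarray | None = None  # PAM medoids (row indices)
    silhouettes: np.ndarray | None = None
    neighbors: np.ndarray | None = None
    average_silhouette: float = float("nan")
    homogeneity: float = float("nan")
    separation: float = float("nan")
    sizes: list[int] = field(default_factory=list)
    probe_ids: list[str] = field(default_factory=list)

    def representatives(self) -> np.ndarray:
        if self.centers is not None:
            return self.centers
        raise UsageError("result has no centroid representatives")


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Center each feature column to mean 0 and scale to SD 1.

    Zero-variance columns carry no distance information and are dropped with
    a warning; it is an error for every column to be constant.  Standardizing
    twice is a no-op.
    """
    if len(fm.data) < 2:
        raise ParameterError("standardization needs at least 2 probes")
    X = fm.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        raise ParameterError("all feature columns are constant; nothing to cluster")
    if not np.all(keep):
        dropped = [c for c, k in zip(fm.feature_names, keep) if not k]
        warnings.warn(f"dropped zero-variance feature column(s) {dropped}", stacklevel=2)
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    df = fm.data.iloc[:, keep].copy()
    df.loc[:, :] = Z
    return FeatureMatrix(df, scaling="standardized")


def dist(x, y, metric: str = "euclidean") -> float:
    """Pointwise L2 or L1 distance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("dimension mismatch")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(x - y)))
    raise ParameterError(f"unknown metric {metric!r}")


def _pairwise(X: np.ndarray, metric: str) -> np.ndarray:
    return cdist(X, X, "euclidean" if metric == "euclidean" else "cityblock")


def _point_dists(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    return cdist(X, C, "euclidean" if metric == "euclidean" else "cityblock")


def _kmeans_objective(D: np.ndarray, assign: np.ndarray, metric: str) -> float:
    d = D[np.arange(D.shape[0]), assign]
    return float(np.sum(d**2)) if metric == "euclidean" else float(np.sum(d))


def _kmeans_pp_init(X: np.ndarray, k: int, metric: str, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [int(rng.integers(n))]
    for _ in range(1, k):
        D = _point_dists(X, X[centers], metric).min(axis=1)
        w = D**2
        if w.sum() == 0:
            centers.append(int(rng.integers(n)))
            continue
        centers.append(int(rng.choice(n, p=w / w.sum())))
    return X[centers].copy()


def _lloyd(X: np.ndarray, k: int, metric: str, rng: np.random.Generator, max_iter: int):
    C = _kmeans_pp_init(X, k, metric, rng)
    assign = None
    for _ in range(max_iter):
        D = _point_dists(X, C, metric)
        new_assign = D.argmin(axis=1)
        # repair empty clusters with the point farthest from its centroid
        for j in range(k):
            if not np.any(new_assign == j):
                d_own = D[np.arange(X.shape[0]), new_assign]
                far = int(np.argmax(d_own))
                new_assign[far] = j
                C[j] = X[far]
                D = _point_dists(X, C, metric)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            C[j] = X[assign == j].mean(axis=0)
    D = _point_dists(X, C, metric)
    assign = D.argmin(axis=1)
    return assign, C, _kmeans_objective(D, assign, metric)


def kmeans(fm: FeatureMatrix, config: ClusterConfig) -> ClusteringResult:
    """Lloyd's k-means with k-means++ seeding and ``n_init`` restarts.

    Centroids are arithmetic means under either metric (under Manhattan the
    metric affects only assignment and evaluation; a k-medians update is out
    of scope).  The best restart by within-cluster (squared, for Euclidean)
    distance wins.  Deterministic for a given seed.
    """
    X = fm.values
    n = X.shape[0]
    if config.k > n:
        raise ParameterError(f"k={config.k} exceeds the number of probes {n}")
    rng = np.random.default_rng(config.seed)
    best = None
    for _ in range(max(1, config.n_init)):
        assign, C, obj = _lloyd(X, config.k, config.metric, rng, config.max_iter)
        if best is None or obj < best[2] - 1e-12:
            best = (assign, C, obj)
    assign, C, obj = best
    result = ClusteringResult(
        assignments=assign, k=config.k, metric=config.metric, algorithm="kmeans",
        objective=obj, centers=C, probe_ids=fm.probe_ids,
    )
    _attach_quality(result, X)
    return result


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.array(
            [np.maximum(nearest - D[:, j], 0.0).sum() if j not in medoids else -1.0
             for j in range(n)]
        )
        medoids.append(int(np.argmax(gains)))
    return sorted(medoids)


def _pam_swap(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Iterate best strictly-improving medoid/non-medoid swaps to convergence."""
    n = D.shape[0]
    medoids = sorted(medoids)
    current = float(D[:, medoids].min(axis=1).sum())
    improved = True
    while improved:
        improved = False
        best_swap = None
        best_obj = current
        non_medoids = [h for h in range(n) if h not in medoids]
        for i in range(len(medoids)):
            for h in non_medoids:
                trial = medoids.copy()
                trial[i] = h
                obj = float(D[:, trial].min(axis=1).sum())
                if obj < best_obj - 1e-12:
                    best_obj = obj
                    best_swap = (i, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            medoids.sort()
            current = best_obj
            improved = True
    return medoids, current


def pam(fm: FeatureMatrix, config: ClusterConfig) -> ClusteringResult:
    """Partitioning around medoids: greedy BUILD then strictly-improving SWAP.

    The SWAP neighborhood has local optima even on tiny instances, so the
    swap phase is additionally restarted from ``n_init - 1`` seeded random
    medoid sets and the best final objective wins (ties toward the
    lexicographically smallest medoid set).  The objective is the total
    distance of every probe to its medoid under the configured metric; the
    run is fully deterministic given the seed.
    """
    X = fm.values
    n = X.shape[0]
    if config.k > n:
        raise ParameterError(f"k={config.k} exceeds the number of probes {n}")
    D = _pairwise(X, config.metric)
    medoids, current = _pam_swap(D, _pam_build(D, config.k))
    rng = np.random.default_rng(config.seed)
    for _ in range(max(0, config.n_init - 1)):
        start = list(rng.choice(n, size=config.k, replace=False))
        cand, obj = _pam_swap(D, start)
        if obj < current - 1e-12 or (abs(obj - current) <= 1e-12 and cand < medoids):
            medoids, current = cand, obj
    medoid_arr = np.array(medoids)
    assign = np.argmin(D[:, medoid_arr], axis=1)
    result = ClusteringResult(
        assignments=assign, k=config.k, metric=config.metric, algorithm="pam",
        objective=current, medoid_indices=medoid_arr, centers=X[medoid_arr].copy(),
        probe_ids=fm.probe_ids,
    )
    _attach_quality(result, X)
    return result


def silhouette(X: np.ndarray, assignments: np.ndarray, metric: str = "euclidean"):
    """Per-item silhouettes s(i) = (b−a)/max(a,b), their mean, and neighbors.

    a(i) is the mean distance to the item's own cluster (excluding itself),
    b(i) the smallest mean distance to another cluster; members of singleton
    clusters get s(i) = 0 by convention.  Returns ``(s, mean_s, neighbor)``.
    """
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ParameterError("silhouette requires at least 2 clusters")
    D = _pairwise(np.asarray(X, dtype=float), metric)
    n = D.shape[0]
    s = np.zeros(n)
    neighbor = np.empty(n, dtype=int)
    masks = {lab: assignments == lab for lab in labels}
    sizes = {lab: int(masks[lab].sum()) for lab in labels}
    for i in range(n):
        own = assignments[i]
        b_best, b_lab = math.inf, own
        for lab in labels:
            if lab == own:
                continue
            b = D[i, masks[lab]].mean()
            if b < b_best:
                b_best, b_lab = b, lab
        neighbor[i] = b_lab
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        a = D[i, masks[own]].sum() / (sizes[own] - 1)
        s[i] = 0.0 if max(a, b_best) == 0 else (b_best - a) / max(a, b_best)
    return s, float(s.mean()), neighbor


def homogeneity(X: np.ndarray, result: ClusteringResult) -> float:
    """Mean distance of every item to its cluster representative (lower = tighter)."""
    C = result.representatives()
    D = _point_dists(np.asarray(X, dtype=float), C, result.metric)
    return float(D[np.arange(D.shape[0]), result.assignments].mean())


def separation(X: np.ndarray, result: ClusteringResult) -> float:
    """Size-weighted mean pairwise distance between cluster representatives."""
    C = result.representatives()
    if C.shape[0] < 2:
        raise ParameterError("separation requires at least 2 clusters")
    sizes = np.array([(result.assignments == j).sum() for j in range(C.shape[0])])
    num = den = 0.0
    for i in range(C.shape[0]):
        for j in range(i + 1, C.shape[0]):
            w = sizes[i] * sizes[j]
            num += w * dist(C[i], C[j], result.metric)
            den += w
    return float(num / den)


def _attach_quality(result: ClusteringResult, X: np.ndarray) -> None:
    result.sizes = [int((result.assignments == j).sum()) for j in range(result.k)]
    if result.k >= 2:
        s, avg, neigh = silhouette(X, result.assignments, result.metric)
        result.silhouettes, result.average_silhouette, result.neighbors = s, avg, neigh
        result.separation = separation(X, result)
    result.homogeneity = homogeneity(X, result)


def cluster_features(fm: FeatureMatrix, config: ClusterConfig) -> ClusteringResult:
    """Standardize if needed, then run the configured algorithm."""
    if fm.scaling == "raw":
        fm = standardize(fm)
    return kmeans(fm, config) if config.algorithm == "kmeans" else pam(fm, config)


def choose_k(fm: FeatureMatrix, config: ClusterConfig, k_range: Sequence[int]):
    """Scan k and keep the clustering with the highest average silhouette.

    Every k uses the same seed policy; ties go to the smallest k.  Returns
    ``(best_k, {k: average silhouette}, best_result)``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ParameterError("k_range must not be empty")
    n = len(fm.data)
    for k in ks:
        if not 2 <= k <= n - 1:
            raise ParameterError(f"k={k} outside valid range [2, {n - 1}]")
    if fm.scaling == "raw":
        fm = standardize(fm)
    scores: dict[int, float] = {}
    best_k, best_result = None, None
    for k in ks:
        cfg = ClusterConfig(
            algorithm=config.algorithm, metric=config.metric, k=k,
            seed=config.seed, max_iter=config.max_iter, n_init=config.n_init,
        )
        res = cluster_features(fm, cfg)
        scores[k] = res.average_silhouette
        if best_k is None or res.average_silhouette > scores[best_k] + 1e-12:
            best_k, best_result = k, res
    return best_k, scores, best_result
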