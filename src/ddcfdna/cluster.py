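"""One-dimensional clustering with small-cluster outlier pruning.

The estimator partitions per-SNP allele-ratio shifts into k groups. In one
dimension the optimal k-means solution (minimum within-cluster sum of
squares) is a contiguous partition of the sorted values and can be found
exactly by dynamic programming in O(k n^2); that exact solver is the default
here, making results deterministic and independent of centroid seeding.
A seeded k-means++ mode (scikit-learn) is kept behind a flag for fidelity
experiments against the stochastic algorithm.

Clusters with three or fewer members are treated as outliers: the member
points are removed and the remainder re-clustered, iterating to a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClusterSet", "ClusteringError", "cluster_1d", "prune_and_recluster"]

DEFAULT_MIN_CLUSTER_SIZE = 4  # clusters smaller than this are outlier clusters


class ClusteringError(ValueError):
    """Raised when a value group cannot support the requested clustering."""


@dataclass
class ClusterSet:
    """A k-partition of 1-D values, clusters indexed in ascending mean order."""

    values: np.ndarray
    labels: np.ndarray  # cluster index per value, 0..k-1 ascending by mean
    means: np.ndarray
    sizes: np.ndarray
    k: int
    degenerate: bool = False  # all values identical: a single effective cluster
    n_excluded: int = 0  # points removed as outlier-cluster members
    n_iterations: int = 1  # prune/re-cluster passes performed

    def within_ss(self) -> float:
        return float(np.sum((self.values - self.means[self.labels]) ** 2))

    def members(self, cluster: int) -> np.ndarray:
        return self.values[self.labels == cluster]


def _dp_optimal_partition(sorted_vals: np.ndarray, k: int) -> list[int]:
    """Boundaries of the optimal contiguous k-partition of sorted values.

    Returns split indices b_0=0 < b_1 < ... < b_k = n such that cluster j is
    sorted_vals[b_j:b_{j+1}]. Uses prefix sums for O(1) interval SSE.
    """
    n = len(sorted_vals)
    ps = np.concatenate(([0.0], np.cumsum(sorted_vals)))
    ps2 = np.concatenate(([0.0], np.cumsum(sorted_vals**2)))

    def sse(i: int, j: int) -> float:
        # SSE of sorted_vals[i:j]
        s = ps[j] - ps[i]
        s2 = ps2[j] - ps2[i]
        m = j - i
        return max(s2 - s * s / m, 0.0)

    INF = float("inf")
    # cost[c][i]: optimal SSE of first i values split into c clusters
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        # at least c values needed for c non-empty clusters
        for i in range(c, n - (k - c) + 1):
            best, best_j = INF, c - 1
            for j in range(c - 1, i):
                if cost[c - 1][j] == INF:
                    continue
                cand = cost[c - 1][j] + sse(j, i)
                if cand < best:
                    best, best_j = cand, j
            cost[c][i] = best
            split[c][i] = best_j

    bounds = [n]
    i = n
    for c in range(k, 0, -1):
        i = split[c][i]
        bounds.append(i)
    return bounds[::-1]


def cluster_1d(
    values: np.ndarray | list[float],
    k: int,
    seed: int | None = None,
    *,
    method: str = "exact",
) -> ClusterSet:
    """Partition 1-D values into k clusters.

    ``method='exact'`` (default) computes the global minimum within-cluster
    sum-of-squares partition by dynamic programming over contiguous segments
    of the sorted values; the result is deterministic and ``seed`` is
    ignored. ``method='kmeans++'`` runs seeded Lloyd iteration with k-means++
    initialisation instead.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ClusteringError("values must be one-dimensional")
    n = len(values)
    if n < k:
        raise ClusteringError(f"cannot form {k} clusters from {n} values")

    degenerate = bool(n > 0 and np.ptp(values) == 0.0)

    if method == "exact":
        order = np.argsort(values, kind="stable")
        sorted_vals = values[order]
        bounds = _dp_optimal_partition(sorted_vals, k)
        labels_sorted = np.empty(n, dtype=int)
        for j in range(k):
            labels_sorted[bounds[j] : bounds[j + 1]] = j
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
    elif method == "kmeans++":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(values.reshape(-1, 1))
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    raw_means = np.array([values[labels == j].mean() for j in range(k)])
    # re-index clusters in ascending order of mean
    order_idx = np.argsort(raw_means, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order_idx] = np.arange(k)
    labels = remap[labels]
    means = raw_means[order_idx]
    sizes = np.bincount(labels, minlength=k)

    return ClusterSet(
        values=values, labels=labels, means=means, sizes=sizes, k=k, degenerate=degenerate
    )


def prune_and_recluster(
    values: np.ndarray | list[float],
    k: int,
    seed: int | None = None,
    *,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    method: str = "exact",
) -> ClusterSet:
    """Cluster, drop members of clusters smaller than ``min_cluster_size``,
    and re-cluster the remainder until no outlier cluster remains.

    Raises :class:`ClusteringError` when pruning leaves fewer than k points.
    """
    values = np.asarray(values, dtype=float)
    n_excluded = 0
    iterations = 0
    current = values
    while True:
        if len(current) < k:
            raise ClusteringError(
                f"only {len(current)} values remain after outlier pruning; need {k}"
            )
        cs = cluster_1d(current, k, seed, method=method)
        iterations += 1
        small = np.flatnonzero(cs.sizes < min_cluster_size)
        if len(small) == 0 or cs.degenerate:
            cs.n_excluded = n_excluded
            cs.n_iterations = iterations
            return cs
        keep = ~np.isin(cs.labels, small)
        n_excluded += int((~keep).sum())
        current = current[keep]
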