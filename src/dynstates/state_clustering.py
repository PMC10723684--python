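"""Clustering pooled leading eigenvectors into phase-locking states.

Recurrent phase-locking states are found by k-means over the pooled
(all subjects, all retained timepoints) leading-eigenvector matrix with
the city-block (L1) metric, the metric under which the component-wise
median is the optimal centroid.  The number of states is selected by
the Davies-Bouldin index, computed with the same metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ClusteringConfig",
    "StateSet",
    "KMeansResult",
    "SelectionResult",
    "kmeans_cityblock",
    "davies_bouldin",
    "select_num_states",
    "state_communities",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """k-means and model-selection settings.

    ``replicates`` random restarts are run per k (best total L1 cost
    wins); replicate ``r`` uses seed ``seed + r`` so runs are
    reproducible across machines.
    """

    distance: str = "cityblock"
    replicates: int = 42
    max_iterations: int = 5000
    k_range: tuple[int, ...] = tuple(range(2, 11))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance not in ("cityblock", "euclidean"):
            raise ValueError("distance must be 'cityblock' or 'euclidean'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.k_range) == 0:
            raise ValueError("k_range must be non-empty")


@dataclass
class StateSet:
    """Centroid eigenvectors defining the phase-locking states.

    Each centroid row splits the components into a positive and a
    negative community; the outer product ``V_c V_c^T`` is the rank-1
    connectivity pattern of the state.
    """

    k: int
    centroids: np.ndarray  # (k, n_components)
    component_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")

    def outer_product(self, state: int) -> np.ndarray:
        """Rank-1 pattern ``V_c V_c^T`` of a state (1-based)."""
        v = self.centroids[state - 1]
        return np.outer(v, v)


@dataclass
class KMeansResult:
    centroids: np.ndarray
    labels: np.ndarray  # 1-based state labels
    cost: float
    n_iterations: int


@dataclass
class SelectionResult:
    k_star: int
    db_table: pd.DataFrame  # columns: k, davies_bouldin, cost
    state_set: StateSet
    labels: np.ndarray  # 1-based labels at k_star
    results_by_k: dict[int, KMeansResult] = field(default_factory=dict)


def _low_median(rows: np.ndarray) -> np.ndarray:
    """Component-wise lower median: the smaller of the two middle order
    statistics for even counts (any point of the median interval
    minimises the L1 cost; the lower end makes the update deterministic)."""
    n = rows.shape[0]
    return np.partition(rows, (n - 1) // 2, axis=0)[(n - 1) // 2]


def _centroid_update(x: np.ndarray, labels0: np.ndarray, k: int, distance: str) -> np.ndarray:
    centroids = np.empty((k, x.shape[1]))
    for j in range(k):
        rows = x[labels0 == j]
        centroids[j] = _low_median(rows) if distance == "cityblock" else rows.mean(axis=0)
    return centroids


def kmeans_cityblock(
    x: np.ndarray, k: int, cfg: ClusteringConfig | None = None
) -> KMeansResult:
    """Best-of-replicates Lloyd k-means under the configured metric.

    City-block assignments with component-wise (lower-)median centroid
    updates; an emptied cluster is re-seeded with the point farthest
    from its previous centroid.  The total within-cluster cost is
    non-increasing across iterations and the best replicate by final
    cost is returned.  Labels are 1-based.
    """
    cfg = cfg or ClusteringConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("input must be 2-D (observations x features)")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite entries")
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in 1..{n}")
    best: KMeansResult | None = None
    idx = np.arange(n)
    for r in range(cfg.replicates):
        rng = np.random.default_rng(cfg.seed + r)
        centroids = x[rng.choice(n, size=k, replace=False)].copy()
        labels0: np.ndarray | None = None
        prev_cost = np.inf
        n_iter = 0
        for n_iter in range(1, cfg.max_iterations + 1):
            d = cdist(x, centroids, metric=cfg.distance)
            labels = np.argmin(d, axis=1)
            reseeded = False
            for j in range(k):  # re-seed emptied clusters (singleton action)
                if not np.any(labels == j):
                    far = int(np.argmax(d[idx, labels]))
                    labels[far] = j
                    reseeded = True
            # Cost of the current centroids under the (possibly repaired)
            # assignment; one full Lloyd step never increases it.
            cost = float(d[idx, labels].sum())
            if not reseeded and cost > prev_cost + 1e-9:
                raise AssertionError("k-means cost increased between iterations")
            if labels0 is not None and np.array_equal(labels, labels0):
                prev_cost = cost
                break
            centroids = _centroid_update(x, labels, k, cfg.distance)
            labels0 = labels
            prev_cost = cost
        assert labels0 is not None
        if best is None or prev_cost < best.cost - 1e-12:
            best = KMeansResult(
                centroids=centroids,
                labels=labels0 + 1,
                cost=prev_cost,
                n_iterations=n_iter,
            )
    assert best is not None
    return best


def davies_bouldin(
    x: np.ndarray,
    labels: np.ndarray,
    centroids: np.ndarray,
    metric: str = "cityblock",
) -> float:
    """Davies-Bouldin validity index (lower is better).

    ``DB = (1/k) * sum_i max_{j != i} (S_i + S_j) / M_ij`` where
    ``S_i`` is the mean distance of cluster-i points to centroid i and
    ``M_ij`` the distance between centroids, all under ``metric``.
    Labels are 1-based.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    centroids = np.asarray(centroids, dtype=float)
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("Davies-Bouldin requires at least 2 clusters")
    scatter = np.empty(k)
    for j in range(k):
        rows = x[labels == j + 1]
        if rows.shape[0] == 0:
            raise ValueError(f"cluster {j + 1} is empty")
        scatter[j] = cdist(rows, centroids[j : j + 1], metric=metric).mean()
    sep = cdist(centroids, centroids, metric=metric)
    ratio = (scatter[:, None] + scatter[None, :]) / np.where(sep > 0, sep, np.inf)
    np.fill_diagonal(ratio, -np.inf)
    return float(ratio.max(axis=1).mean())


def _reorder_by_occupancy(
    result: KMeansResult, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel states by descending pooled occupancy (stable labels)."""
    counts = np.bincount(result.labels - 1, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    return result.centroids[order], remap[result.labels - 1] + 1


def select_num_states(
    x: np.ndarray, cfg: ClusteringConfig | None = None
) -> SelectionResult:
    """Cluster at every k in ``cfg.k_range`` and pick the DB minimum.

    Ties in the Davies-Bouldin index are broken toward the smaller k.
    States in the returned :class:`StateSet` are numbered by descending
    pooled occupancy.  The full DB-versus-k table is returned so the
    selection curve can be inspected.
    """
    cfg = cfg or ClusteringConfig()
    rows = []
    results: dict[int, KMeansResult] = {}
    for k in cfg.k_range:
        res = kmeans_cityblock(x, k, cfg)
        db = (
            davies_bouldin(x, res.labels, res.centroids, metric=cfg.distance)
            if k >= 2
            else np.nan
        )
        results[k] = res
        rows.append({"k": k, "davies_bouldin": db, "cost": res.cost})
    table = pd.DataFrame(rows)
    finite = table.dropna(subset=["davies_bouldin"])
    if len(finite):
        k_star = int(finite.loc[finite["davies_bouldin"].idxmin(), "k"])
    else:  # k_range of size 1 with k = 1
        k_star = int(table["k"].iloc[0])
    centroids, labels = _reorder_by_occupancy(results[k_star], k_star)
    return SelectionResult(
        k_star=k_star,
        db_table=table,
        state_set=StateSet(k=k_star, centroids=centroids),
        labels=labels,
        results_by_k=results,
    )


def state_communities(
    state_set: StateSet, component_ids: list[str] | None = None
) -> list[dict]:
    """Per-state community report.

    For every state, the components are split by centroid sign into the
    positive and negative community, each sorted by decreasing
    \\|centroid element\\| (how strongly the component belongs).  A state
    whose centroid has only one sign is flagged as ``single_community``.
    """
    ids = component_ids or state_set.component_ids
    if ids is None:
        ids = [f"ic{j + 1:02d}" for j in range(state_set.centroids.shape[1])]
    report = []
    for s in range(1, state_set.k + 1):
        v = state_set.centroids[s - 1]
        pos = [(ids[i], float(v[i])) for i in np.argsort(-np.abs(v)) if v[i] > 0]
        neg = [(ids[i], float(v[i])) for i in np.argsort(-np.abs(v)) if v[i] < 0]
        report.append(
            {
                "state": s,
                "positive_community": pos,
                "negative_community": neg,
                "single_community": len(pos) == 0 or len(neg) == 0,
                "outer_product": state_set.outer_product(s),
            }
        )
    return report
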