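"""Density-based clustering of reduced document vectors.

The clustering contract is HDBSCAN's: points are compared under the
mutual reachability distance

    d_mreach(x_i, x_j) = max(core_k(x_i), core_k(x_j), d(x_i, x_j)),

where core_k(x) is the distance from x to its k-th nearest neighbour
(k = ``min_samples``, the point itself excluded); a single-linkage
hierarchy over that metric is condensed by minimum cluster size and the
most stable clusters are selected, with unassigned points labelled -1
(noise). The hierarchy construction is delegated to
``sklearn.cluster.HDBSCAN``; the mutual-reachability metric, the
per-member outlier score

    OutlierScore(x) = core(x) / mean core distance of x's cluster,

and the per-cluster birth/death density thresholds are computed here so
they can be checked against independent references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import HDBSCAN
from sklearn.neighbors import NearestNeighbors

from .embed import EmbeddingMatrix

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass(frozen=True)
class ClusteringConfig:
    """min_cluster_size is the smallest admissible cluster; min_samples is
    the k of the core-distance definition and defaults to min_cluster_size."""

    min_cluster_size: int = 100
    min_samples: int | None = None
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.min_samples is not None and self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")

    @property
    def k(self) -> int:
        return self.min_samples if self.min_samples is not None else self.min_cluster_size


@dataclass
class ClusterStability:
    """Density thresholds (lambda = 1/distance) at which a selected cluster
    separates from the rest of the data (birth) and fragments internally
    (death), with a point-count-scaled persistence score."""

    label: int
    lambda_birth: float
    lambda_death: float
    stability: float


@dataclass
class ClusterResult:
    ids: list[str]
    labels: np.ndarray
    core_distances: np.ndarray
    outlier_scores: np.ndarray = field(default=None)
    stabilities: dict[int, ClusterStability] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.core_distances = np.asarray(self.core_distances, dtype=float)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))

    def copy_with_labels(self, labels: np.ndarray) -> "ClusterResult":
        return ClusterResult(
            ids=list(self.ids),
            labels=np.asarray(labels, dtype=int).copy(),
            core_distances=self.core_distances.copy(),
            outlier_scores=None
            if self.outlier_scores is None
            else self.outlier_scores.copy(),
            stabilities=dict(self.stabilities),
        )


def core_distances(points: np.ndarray, k: int, metric: str = "euclidean") -> np.ndarray:
    """Distance from each point to its k-th nearest neighbour (self excluded)."""
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"min_samples k={k} must be < number of points {n}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(points)
    dists, _ = nn.kneighbors(points)
    return dists[:, k]


def mutual_reachability(
    points: EmbeddingMatrix | np.ndarray, cfg: ClusteringConfig
) -> np.ndarray:
    """Pairwise mutual reachability distance matrix (symmetric, >= the
    underlying metric pointwise, zero diagonal by convention)."""
    x = points.vectors if isinstance(points, EmbeddingMatrix) else np.asarray(points)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    core = core_distances(x, cfg.k, cfg.metric)
    d = cdist(x, x, metric=cfg.metric)
    m = np.maximum(d, np.maximum(core[:, None], core[None, :]))
    np.fill_diagonal(m, 0.0)
    return m


def fit_clusters(
    points: EmbeddingMatrix, cfg: ClusteringConfig | None = None
) -> ClusterResult:
    """Cluster reduced vectors; returns labels (noise = -1), core distances,
    per-member outlier scores and per-cluster stability diagnostics.

    Fewer points than ``min_cluster_size`` cannot form any cluster: all
    points are labelled noise with a warning.
    """
    cfg = cfg or ClusteringConfig()
    x = points.vectors
    n = x.shape[0]

    if n < cfg.min_cluster_size:
        logger.warning(
            "fit_clusters: N=%d < min_cluster_size=%d; labelling all noise",
            n,
            cfg.min_cluster_size,
        )
        return ClusterResult(
            ids=list(points.ids),
            labels=np.full(n, NOISE),
            core_distances=core_distances(x, min(cfg.k, n - 1), cfg.metric),
            outlier_scores=np.full(n, np.nan),
        )

    model = HDBSCAN(
        min_cluster_size=cfg.min_cluster_size,
        min_samples=min(cfg.k, n - 1),
        metric=cfg.metric,
        copy=True,
    )
    labels = model.fit_predict(x)

    core = core_distances(x, min(cfg.k, n - 1), cfg.metric)
    result = ClusterResult(
        ids=list(points.ids),
        labels=labels,
        core_distances=core,
    )
    result.outlier_scores = outlier_scores(result)
    result.stabilities = _cluster_stabilities(x, result, cfg)
    return result


def outlier_scores(result: ClusterResult) -> np.ndarray:
    """Core-distance ratio outlier score per cluster member.

    score(x) = core(x) / mean core distance of x's cluster; within each
    cluster the scores average to exactly 1. Noise points receive NaN
    (they belong to no cluster and have no reference density).
    """
    labels = result.labels
    scores = np.full(labels.shape, np.nan)
    for lab in sorted(set(labels[labels != NOISE])):
        mask = labels == lab
        mean_core = float(np.mean(result.core_distances[mask]))
        if mean_core == 0.0:
            scores[mask] = 1.0  # coincident points: uniform density
        else:
            scores[mask] = result.core_distances[mask] / mean_core
    return scores


def _cluster_stabilities(
    x: np.ndarray, result: ClusterResult, cfg: ClusteringConfig
) -> dict[int, ClusterStability]:
    """Birth/death density thresholds per selected cluster from the
    mutual-reachability minimum spanning tree.

    With lambda = 1/distance, a cluster is born when it splits off the rest
    of the data (the cheapest MST edge leaving it) and dies when its own
    densest structure fragments (its largest internal MST edge). The
    persistence score scales the lambda span by member count. Skipped for
    large N (quadratic memory) — it is a diagnostic, not part of labelling.
    """
    n = x.shape[0]
    labels = result.labels
    labs = sorted(set(labels[labels != NOISE]))
    if not labs or n > 5000:
        return {}
    m = mutual_reachability(x, cfg)
    mst = minimum_spanning_tree(m).tocoo()
    out: dict[int, ClusterStability] = {}
    eps = np.finfo(float).tiny
    for lab in labs:
        internal: list[float] = []
        leaving: list[float] = []
        for i, j, w in zip(mst.row, mst.col, mst.data):
            li, lj = labels[i], labels[j]
            if li == lab and lj == lab:
                internal.append(w)
            elif (li == lab) != (lj == lab):
                leaving.append(w)
        lam_birth = 1.0 / max(min(leaving), eps) if leaving else 0.0
        lam_death = 1.0 / max(max(internal), eps) if internal else np.inf
        n_members = int(np.sum(labels == lab))
        stability = n_members * max(lam_death - lam_birth, 0.0)
        out[int(lab)] = ClusterStability(
            label=int(lab),
            lambda_birth=float(lam_birth),
            lambda_death=float(lam_death),
            stability=float(stability),
        )
    return out
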