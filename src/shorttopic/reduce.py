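"""Manifold reduction of document embeddings with silhouette-tuned output
dimensionality.

Fixed-dimension UMAP can lose topical structure; instead the output
dimension d is swept over a candidate grid, the reduced space is
clustered at each d, and the d maximising the silhouette score of the
non-noise points (Euclidean, in the reduced space) is selected. Clustering
hyperparameters and the random seed are held fixed across the sweep so
dimension is the only varying factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cluster import NOISE, ClusteringConfig, fit_clusters
from .embed import EmbeddingMatrix
from .metrics import silhouette

logger = logging.getLogger(__name__)

#: Sentinel silhouette for dimensions where the score is undefined
#: (fewer than two clusters, or everything noise).
UNDEFINED_SCORE = -1.0

#: Output dimensionality of the untuned baseline configuration.
BASELINE_DIM = 5


@dataclass(frozen=True)
class ReductionConfig:
    n_neighbors: int = 30
    metric: str = "cosine"
    min_dist: float = 0.1
    seed: int = 0
    candidate_dims: tuple[int, ...] = tuple(range(2, 41))
    silhouette_subsample: int = 20000

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if not self.candidate_dims:
            raise ValueError("candidate_dims must be non-empty")
        if any(d < 2 for d in self.candidate_dims):
            raise ValueError("candidate dimensions must be >= 2")


@dataclass
class DDEOResult:
    """Silhouette-per-dimension table, the selected dimension, and the
    reduced matrix at that dimension."""

    scores: dict[int, float]
    chosen_dim: int
    reduced: EmbeddingMatrix | None
    n_clusters: dict[int, int] = field(default_factory=dict)
    outlier_rates: dict[int, float] = field(default_factory=dict)
    fallback: bool = False


def reduce(
    vectors: EmbeddingMatrix, dim: int, cfg: ReductionConfig | None = None
) -> EmbeddingMatrix:
    """UMAP-project vectors to ``dim`` dimensions; deterministic for a
    fixed seed (single-threaded when random_state is set)."""
    cfg = cfg or ReductionConfig()
    if dim < 2:
        raise ValueError("dim must be >= 2")
    n = len(vectors)
    if n <= cfg.n_neighbors:
        raise ValueError(
            f"N={n} must exceed n_neighbors={cfg.n_neighbors}; lower "
            "n_neighbors in the reduction config for small corpora"
        )
    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning, module="umap")
        model = umap.UMAP(
            n_neighbors=cfg.n_neighbors,
            n_components=dim,
            metric=cfg.metric,
            min_dist=cfg.min_dist,
            random_state=cfg.seed,
        )
        reduced = model.fit_transform(vectors.vectors)
    reduced = np.asarray(reduced, dtype=float)
    if not np.all(np.isfinite(reduced)):
        raise RuntimeError("reduction produced non-finite values")
    return EmbeddingMatrix(ids=list(vectors.ids), vectors=reduced)


def argmax_dimension(scores: dict[int, float]) -> int:
    """Dimension with the maximal score; exact ties go to the smallest
    dimension."""
    if not scores:
        raise ValueError("empty score table")
    best = max(scores.values())
    return min(d for d, s in scores.items() if s == best)


def select_dimension(
    vectors: EmbeddingMatrix,
    cfg: ReductionConfig | None = None,
    cluster_cfg: ClusteringConfig | None = None,
) -> DDEOResult:
    """Sweep candidate dimensions, score each by the silhouette of its
    clustering, and return the argmax with the full score table.

    Dimensions where the silhouette is undefined score the sentinel -1.
    If every candidate is undefined the sweep falls back to the baseline
    dimension (5) with a warning.
    """
    cfg = cfg or ReductionConfig()
    cluster_cfg = cluster_cfg or ClusteringConfig()

    scores: dict[int, float] = {}
    n_clusters: dict[int, int] = {}
    outlier_rates: dict[int, float] = {}
    reduced_cache: dict[int, EmbeddingMatrix] = {}

    for dim in cfg.candidate_dims:
        red = reduce(vectors, dim, cfg)
        reduced_cache[dim] = red
        result = fit_clusters(red, cluster_cfg)
        n_clusters[dim] = result.n_clusters
        outlier_rates[dim] = result.n_noise / len(result.labels)
        s = _sweep_silhouette(red, result.labels, cfg)
        scores[dim] = UNDEFINED_SCORE if s is None else s
        logger.info(
            "ddeo sweep: dim=%d silhouette=%.4f clusters=%d noise=%.1f%%",
            dim,
            scores[dim],
            n_clusters[dim],
            100 * outlier_rates[dim],
        )

    if all(s == UNDEFINED_SCORE for s in scores.values()):
        logger.warning(
            "ddeo sweep: silhouette undefined at every candidate dimension; "
            "falling back to baseline dim %d",
            BASELINE_DIM,
        )
        red = reduced_cache.get(BASELINE_DIM) or reduce(vectors, BASELINE_DIM, cfg)
        return DDEOResult(
            scores=scores,
            chosen_dim=BASELINE_DIM,
            reduced=red,
            n_clusters=n_clusters,
            outlier_rates=outlier_rates,
            fallback=True,
        )

    chosen = argmax_dimension(scores)
    return DDEOResult(
        scores=scores,
        chosen_dim=chosen,
        reduced=reduced_cache[chosen],
        n_clusters=n_clusters,
        outlier_rates=outlier_rates,
    )


def _sweep_silhouette(
    red: EmbeddingMatrix, labels: np.ndarray, cfg: ReductionConfig
) -> float | None:
    """Euclidean silhouette over non-noise points, optionally on a seeded
    subsample for large corpora."""
    mask = labels != NOISE
    x, y = red.vectors[mask], labels[mask]
    if len(set(y)) < 2:
        return None
    if x.shape[0] > cfg.silhouette_subsample:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(x.shape[0], cfg.silhouette_subsample, replace=False)
        x, y = x[idx], y[idx]
        if len(set(y)) < 2:
            return None
    return silhouette(x, y)
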