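"""Probabilistic reassignment of noise documents to topics.

Hard density clustering discards low-density documents as noise. Here
every document receives a row-stochastic probability distribution over
the discovered topics — a softmax over negative document-to-centroid
distances — and a noise document whose winning probability strictly
exceeds a threshold is reassigned to that topic. Non-noise labels are
never touched, so the outlier rate can only decrease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cluster import NOISE, ClusterResult
from .embed import EmbeddingMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRMConfig:
    """threshold: minimum winning probability for rescue (strict >);
    distance: 'cosine' or 'euclidean' document-to-centroid distance,
    measured in the reduced space by default."""

    threshold: float = 0.15
    distance: str = "cosine"
    space: str = "reduced"

    def __post_init__(self) -> None:
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must be in [0, 1)")
        if self.distance not in ("cosine", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.space not in ("reduced", "original"):
            raise ValueError(f"unknown space {self.space!r}")


@dataclass
class DocTopicMatrix:
    """Row-stochastic document-topic probabilities."""

    ids: list[str]
    topics: list[int]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.ids), len(self.topics)):
            raise ValueError("P must be n_docs x n_topics")
        if (self.P < -1e-12).any() or (self.P > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")


def topic_centroids(
    points: EmbeddingMatrix, result: ClusterResult
) -> tuple[list[int], np.ndarray]:
    """Mean member vector per non-noise topic, in label order."""
    labels = np.asarray(result.labels)
    topics = sorted(set(labels[labels != NOISE].tolist()))
    if not topics:
        raise ValueError("no topics to build centroids from")
    cents = np.stack([points.vectors[labels == t].mean(axis=0) for t in topics])
    return topics, cents


def topic_distances(
    points: EmbeddingMatrix,
    result: ClusterResult,
    cfg: PRMConfig | None = None,
) -> tuple[list[int], np.ndarray]:
    """N x M distance matrix from each document to each topic centroid.

    Cosine distance is 1 - cosine similarity; a zero-norm vector (where
    cosine is undefined) falls back to Euclidean distance for the affected
    entries, with a warning.
    """
    cfg = cfg or PRMConfig()
    topics, cents = topic_centroids(points, result)
    x = points.vectors
    if cfg.distance == "euclidean":
        from scipy.spatial.distance import cdist

        return topics, cdist(x, cents)

    x_norm = np.linalg.norm(x, axis=1)
    c_norm = np.linalg.norm(cents, axis=1)
    bad_rows = x_norm == 0
    bad_cols = c_norm == 0
    safe_x = np.where(bad_rows, 1.0, x_norm)
    safe_c = np.where(bad_cols, 1.0, c_norm)
    cos = (x @ cents.T) / (safe_x[:, None] * safe_c[None, :])
    d = 1.0 - cos
    if bad_rows.any() or bad_cols.any():
        logger.warning(
            "topic_distances: %d zero-norm vectors; euclidean fallback",
            int(bad_rows.sum() + bad_cols.sum()),
        )
        from scipy.spatial.distance import cdist

        eu = cdist(x, cents)
        mask = bad_rows[:, None] | bad_cols[None, :]
        d = np.where(mask, eu, d)
    return topics, np.maximum(d, 0.0)


def soft_assign(distances: np.ndarray) -> np.ndarray:
    """Row-wise softmax of negative distances with max-subtraction for
    numerical stability; invariant to adding a constant per row."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[1] == 0:
        raise ValueError("need an N x M distance matrix with M >= 1")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    z = -d
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_doc_topic_matrix(
    points: EmbeddingMatrix,
    result: ClusterResult,
    cfg: PRMConfig | None = None,
) -> DocTopicMatrix:
    cfg = cfg or PRMConfig()
    topics, d = topic_distances(points, result, cfg)
    return DocTopicMatrix(ids=list(points.ids), topics=topics, P=soft_assign(d))


def reassign_outliers(
    result: ClusterResult,
    P: DocTopicMatrix,
    cfg: PRMConfig | None = None,
) -> tuple[ClusterResult, list[tuple[str, int, int, float]]]:
    """Rescue noise documents whose winning topic probability strictly
    exceeds the threshold.

    Only documents labelled -1 are touched; ties on the winning
    probability go to the lowest topic index (argmax convention). Returns
    the updated result and a report of (id, old_label, new_label,
    winning_probability) for every noise document considered.
    """
    cfg = cfg or PRMConfig()
    if list(P.ids) != list(result.ids):
        raise ValueError("probability matrix and cluster result misaligned")
    labels = result.labels.copy()
    report: list[tuple[str, int, int, float]] = []
    for i in np.nonzero(labels == NOISE)[0]:
        j = int(np.argmax(P.P[i]))
        p = float(P.P[i, j])
        new = P.topics[j] if p > cfg.threshold else NOISE
        labels[i] = new
        report.append((result.ids[i], NOISE, new, p))
    out = result.copy_with_labels(labels)
    n_rescued = sum(1 for _, _, new, _ in report if new != NOISE)
    logger.info(
        "reassign_outliers: rescued %d of %d noise documents", n_rescued, len(report)
    )
    return out, report
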