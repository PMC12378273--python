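"""Evaluation metrics for the topic pipeline.

Module-level metrics — silhouette coefficient (clustering structure),
outlier rate (document retention), lexical diversity (within-topic
keyword uniqueness) and centroid cosine similarity (embedding
homogenisation) — and corpus-level metrics: NPMI topic coherence, topic
diversity, and an assigned-topic perplexity.

All metrics are defined directly on in-memory arrays/lists so each one
can be checked against an independent brute-force reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .cluster import NOISE
from .embed import EmbeddingMatrix
from .preprocess import CleanDocument

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class MetricsReport:
    """All metric values for one run; a metric that is undefined on the
    input is None with the reason recorded in ``notes``."""

    npmi: float | None = None
    topic_diversity: float | None = None
    perplexity: float | None = None
    lexical_diversity: float | None = None
    centroid_cosine: float | None = None
    silhouette: float | None = None
    outlier_rate: float | None = None
    n_noise: int | None = None
    n_docs: int | None = None
    n_topics: int | None = None
    top_k: int = 10
    notes: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_array(points: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    return points.vectors if isinstance(points, EmbeddingMatrix) else np.asarray(points, dtype=float)


def silhouette(points: EmbeddingMatrix | np.ndarray, labels: Sequence[int]) -> float | None:
    """Mean over non-noise points of (b - a)/max(a, b), where a is the mean
    intra-cluster distance and b the smallest mean distance to another
    cluster. Euclidean; returns None when fewer than two clusters exist."""
    x = _as_array(points)
    y = np.asarray(labels, dtype=int)
    mask = y != NOISE
    x, y = x[mask], y[mask]
    if len(set(y.tolist())) < 2:
        return None
    return float(silhouette_score(x, y, metric="euclidean"))


def outlier_rate(labels: Sequence[int]) -> tuple[float, int, int]:
    """Fraction of documents labelled noise, with numerator/denominator."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("labels must be non-empty")
    n_noise = int(np.sum(y == NOISE))
    return n_noise / y.size, n_noise, int(y.size)


def npmi(
    topics: Sequence[Sequence[str]],
    docs: Sequence[CleanDocument],
    *,
    eps: float = _EPS,
) -> tuple[float | None, float]:
    """Mean normalized pointwise mutual information of the top words.

    Per topic, NPMI is averaged over all word pairs using document-level
    occurrence probabilities: npmi(w_i, w_j) = pmi / (-log p(w_i, w_j))
    with the joint probability floored at ``eps``. Word pairs whose
    members never occur in the corpus are skipped and reported through
    the returned coverage fraction (pairs evaluated / pairs total).
    """
    if not docs:
        raise ValueError("corpus must be non-empty")
    n = len(docs)
    doc_sets = [set(d.tokens) for d in docs]
    occurs: dict[str, int] = {}
    for s in doc_sets:
        for w in s:
            occurs[w] = occurs.get(w, 0) + 1

    per_topic: list[float] = []
    evaluated = total = 0
    for words in topics:
        vals: list[float] = []
        for wi, wj in combinations(words, 2):
            total += 1
            if wi not in occurs or wj not in occurs:
                continue
            evaluated += 1
            p_i = occurs[wi] / n
            p_j = occurs[wj] / n
            joint = sum(1 for s in doc_sets if wi in s and wj in s) / n
            joint = max(joint, eps)
            if joint >= 1.0:
                # both words in every document: perfect co-occurrence,
                # the normalizer -log(1) degenerates; limit value is 1
                vals.append(1.0)
                continue
            val = math.log(joint / (p_i * p_j)) / (-math.log(joint))
            vals.append(val)
        if vals:
            per_topic.append(float(np.mean(vals)))
    coverage = evaluated / total if total else 0.0
    if not per_topic:
        return None, coverage
    return float(np.mean(per_topic)), coverage


def topic_diversity(topics: Sequence[Sequence[str]]) -> float:
    """Distinct words across all top-k lists divided by total slots."""
    if not topics:
        raise ValueError("need at least one topic")
    all_words = [w for words in topics for w in words]
    return len(set(all_words)) / len(all_words)


def perplexity(P: np.ndarray, labels: Sequence[int]) -> float | None:
    """exp of the mean negative log probability of each non-noise
    document's assigned topic; 1 for one-hot rows, M for uniform rows."""
    P = np.asarray(P, dtype=float)
    y = np.asarray(labels, dtype=int)
    if P.shape[0] != y.size:
        raise ValueError("probability matrix and labels misaligned")
    mask = y != NOISE
    if not mask.any():
        return None
    probs = P[mask, y[mask]]
    floored = np.maximum(probs, _EPS)
    if (probs < _EPS).any():
        logger.warning("perplexity: %d winning probabilities floored", int((probs < _EPS).sum()))
    return float(np.exp(-np.mean(np.log(floored))))


def lexical_diversity(
    topic_term_weights: dict[int, dict[str, float]],
    docs: Sequence[CleanDocument],
    labels: Sequence[int],
    per_doc_top_m: int = 5,
) -> float | None:
    """Within-topic keyword uniqueness.

    For each topic, every member document contributes its ``per_doc_top_m``
    highest-weighted tokens (weights from the topic's term-weight row; ties
    broken lexicographically); the topic's score is distinct/total over the
    concatenation and the mean over topics is returned.
    """
    y = np.asarray(labels, dtype=int)
    per_topic: list[float] = []
    for topic, weights in sorted(topic_term_weights.items()):
        member_idx = np.nonzero(y == topic)[0]
        if member_idx.size == 0:
            continue
        slots: list[str] = []
        for i in member_idx:
            toks = sorted(set(docs[i].tokens), key=lambda t: (-weights.get(t, 0.0), t))
            slots.extend(toks[:per_doc_top_m])
        if slots:
            per_topic.append(len(set(slots)) / len(slots))
    if not per_topic:
        return None
    return float(np.mean(per_topic))


def centroid_cosine(
    vectors: EmbeddingMatrix | np.ndarray, labels: Sequence[int]
) -> float | None:
    """Mean cosine similarity between each non-noise document vector and
    its topic centroid; zero-norm vectors are excluded with a warning."""
    x = _as_array(vectors)
    y = np.asarray(labels, dtype=int)
    vals: list[float] = []
    skipped = 0
    for topic in sorted(set(y[y != NOISE].tolist())):
        members = x[y == topic]
        centroid = members.mean(axis=0)
        c_norm = np.linalg.norm(centroid)
        for v in members:
            v_norm = np.linalg.norm(v)
            if v_norm == 0 or c_norm == 0:
                skipped += 1
                continue
            vals.append(float(v @ centroid / (v_norm * c_norm)))
    if skipped:
        logger.warning("centroid_cosine: skipped %d zero-norm vectors", skipped)
    if not vals:
        return None
    return float(np.mean(vals))
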