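"""Seeded generators for planted-topic short-text corpora and
Gaussian-mixture embedding fixtures.

The corpus generator emulates the statistics that matter for short-text
topic modeling — documents of ~5-30 tokens mixing Zipf-distributed
generic terms (which dominate the corpus-frequency top decile, giving the
popularity regularizer a target), topic-specific term blocks with
controllable overlap, domain-dictionary terms planted inside blocks, and
a fraction of outlier documents that sample across all blocks. Gold topic
labels (-1 for outliers) are returned alongside and are never encoded in
the text itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embed import EmbeddingMatrix
from .preprocess import RawDocument

#: Domain terms planted into topic blocks (singular/no-trailing-s forms so
#: preprocessing leaves them intact).
PLANTABLE_DICTIONARY_TERMS = (
    "sleep",
    "anxiety",
    "bullying",
    "nutrition",
    "mindfulness",
    "therapy",
    "resilience",
    "insomnia",
    "trauma",
    "addiction",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a planted-topic corpus.

    ``separation`` in [0, 1] is the fraction of each topic's term block
    that is unique to it (the rest is drawn from a pool shared between
    topics); ``generic_mix`` the expected fraction of generic (Zipf)
    tokens per topical document; ``outlier_fraction`` the fraction of
    documents sampling uniformly across all blocks.
    """

    n_topics: int = 5
    docs_per_topic: int = 200
    vocab_generic: int = 25
    vocab_per_topic: int = 40
    zipf_exponent: float = 1.0
    doc_length: tuple[int, int] = (5, 30)
    generic_mix: float = 0.4
    outlier_fraction: float = 0.10
    separation: float = 1.0
    plant_dictionary_terms: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_topics, self.docs_per_topic, self.vocab_generic, self.vocab_per_topic) < 1:
            raise ValueError("all counts must be positive")
        for name in ("generic_mix", "outlier_fraction", "separation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.doc_length[0] < 1 or self.doc_length[1] < self.doc_length[0]:
            raise ValueError("doc_length must be a valid (min, max) range")


@dataclass
class SyntheticCorpus:
    docs: list[RawDocument]
    gold_labels: np.ndarray
    topic_blocks: list[list[str]] = field(default_factory=list)
    generic_terms: list[str] = field(default_factory=list)
    dictionary_terms: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gold_labels = np.asarray(self.gold_labels, dtype=int)
        if len(self.docs) != self.gold_labels.size:
            raise ValueError("gold label count must match doc count")


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def generate_corpus(spec: SyntheticSpec | None = None) -> SyntheticCorpus:
    """Generate a planted-topic corpus, fully reproducible from the seed.

    Topical documents mix Zipf-sampled generic terms with uniform draws
    from their topic's block; outlier documents draw uniformly from the
    union of all blocks. Term names carry no topic information beyond
    their block membership (ids like ``gen012x``, ``blk3w07x``).
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)

    generic = [f"gen{i:03d}x" for i in range(spec.vocab_generic)]
    zipf_p = _zipf_probs(spec.vocab_generic, spec.zipf_exponent)

    n_unique = int(round(spec.separation * spec.vocab_per_topic))
    n_shared = spec.vocab_per_topic - n_unique
    shared_pool = [f"shared{i:03d}x" for i in range(max(n_shared * 2, 1))]

    blocks: list[list[str]] = []
    dictionary_terms: dict[int, list[str]] = {}
    for t in range(spec.n_topics):
        block = [f"blk{t}w{i:02d}x" for i in range(n_unique)]
        if n_shared:
            block += list(rng.choice(shared_pool, size=n_shared, replace=False))
        if spec.plant_dictionary_terms:
            planted = [
                PLANTABLE_DICTIONARY_TERMS[(2 * t + k) % len(PLANTABLE_DICTIONARY_TERMS)]
                for k in range(2)
            ]
            # replace the last block slots so block size stays fixed
            block[-len(planted):] = planted
            dictionary_terms[t] = planted
        blocks.append(block)

    n_total = spec.n_topics * spec.docs_per_topic
    n_outliers = int(round(spec.outlier_fraction * n_total))
    all_block_terms = sorted({w for b in blocks for w in b})

    # interleave outliers deterministically among topical docs
    is_outlier = np.zeros(n_total, dtype=bool)
    if n_outliers:
        is_outlier[rng.choice(n_total, size=n_outliers, replace=False)] = True
    topic_cycle = rng.permutation(
        np.repeat(np.arange(spec.n_topics), spec.docs_per_topic)
    )

    docs: list[RawDocument] = []
    gold: list[int] = []
    lo, hi = spec.doc_length
    for i in range(n_total):
        length = int(rng.integers(lo, hi + 1))
        if is_outlier[i]:
            tokens = list(rng.choice(all_block_terms, size=length, replace=True))
            label = -1
        else:
            t = int(topic_cycle[i])
            n_generic = int(rng.binomial(length, spec.generic_mix))
            tokens = list(
                rng.choice(generic, size=n_generic, replace=True, p=zipf_p)
            ) + list(rng.choice(blocks[t], size=length - n_generic, replace=True))
            rng.shuffle(tokens)
            label = t
        docs.append(RawDocument(id=f"d{i:05d}", text=" ".join(tokens)))
        gold.append(label)

    return SyntheticCorpus(
        docs=docs,
        gold_labels=np.array(gold),
        topic_blocks=blocks,
        generic_terms=generic,
        dictionary_terms=dictionary_terms,
    )


def generate_embeddings(
    n_clusters: int,
    n_points: int,
    dim: int,
    separation: float,
    outlier_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Isotropic Gaussian blobs (unit sigma) with centers at pairwise
    distance ``separation``; outliers are uniform in the data bounding
    box and carry gold label -1.

    When ``dim >= n_clusters`` the centers sit on scaled coordinate axes
    (exactly equidistant); otherwise they are random Gaussian directions
    scaled to the requested mean pairwise distance.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if n_points < n_clusters:
        raise ValueError("n_points must be >= n_clusters")
    rng = np.random.default_rng(seed)

    if dim >= n_clusters:
        centers = np.zeros((n_clusters, dim))
        centers[np.arange(n_clusters), np.arange(n_clusters)] = separation / np.sqrt(2)
    else:
        centers = rng.standard_normal((n_clusters, dim))
        from scipy.spatial.distance import pdist

        mean_d = pdist(centers).mean() or 1.0
        centers *= separation / mean_d

    n_outliers = int(round(outlier_fraction * n_points))
    n_in = n_points - n_outliers
    sizes = np.full(n_clusters, n_in // n_clusters)
    sizes[: n_in % n_clusters] += 1

    points, labels = [], []
    for c, size in enumerate(sizes):
        points.append(centers[c] + rng.standard_normal((size, dim)))
        labels.extend([c] * size)
    x = np.vstack(points)
    if n_outliers:
        lo, hi = x.min(axis=0), x.max(axis=0)
        points.append(rng.uniform(lo, hi, size=(n_outliers, dim)))
        labels.extend([-1] * n_outliers)
        x = np.vstack(points)

    perm = rng.permutation(len(labels))
    x = x[perm]
    gold = np.asarray(labels)[perm]
    ids = [f"p{i:05d}" for i in range(len(gold))]
    return EmbeddingMatrix(ids=ids, vectors=x), gold
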