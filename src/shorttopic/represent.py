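"""Topic keyword extraction: class-based TF-IDF, popularity-deviation
regularization, and maximal-marginal-relevance re-ranking.

c-TF-IDF scores a term per topic (class) rather than per document:

    w(t, c) = TF(t, c) / sum_t' TF(t', c) * log(N / df(t)),

with N the corpus size and df the document frequency — frequent within a
topic, rare across the corpus. The popularity-deviation regularizer (PDR)
then multiplies terms in the top decile of corpus frequency by
exp(-alpha * rank) (rank 1 = most frequent) and terms of a domain
dictionary by a fixed boost, sharpening domain-specific vocabulary.
Final keyword lists are selected greedily by maximal marginal relevance,

    MMR(w) = lambda * Sim(w, q) - (1 - lambda) * max_{s in S} Sim(w, s),

trading relevance to the topic query q against redundancy with already
selected words.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .cluster import NOISE
from .embed import HashEmbedder
from .preprocess import CleanDocument

logger = logging.getLogger(__name__)


def load_default_dictionary() -> frozenset[str]:
    """The packaged adolescent-health domain vocabulary."""
    text = (
        resources.files("shorttopic.data").joinpath("adolescent_health.txt").read_text()
    )
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass
class TermWeights:
    """Per-topic term weight matrix with the corpus statistics needed for
    regularization and diagnostics."""

    topics: list[int]
    vocabulary: list[str]
    weights: np.ndarray  # M x V, nonnegative
    doc_freq: np.ndarray  # V, document counts over the whole corpus
    corpus_tf: np.ndarray  # V, raw term counts over the whole corpus
    n_docs: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.topics), len(self.vocabulary)):
            raise ValueError("weights must be n_topics x vocabulary")

    def topic_row(self, topic: int) -> dict[str, float]:
        i = self.topics.index(topic)
        return dict(zip(self.vocabulary, self.weights[i]))


@dataclass(frozen=True)
class PDRConfig:
    """Popularity-deviation regularizer settings.

    ``alpha`` is the exponential decay rate over frequency rank; ``decile``
    the top fraction of the corpus-frequency ranking that is penalized;
    ``boost`` the multiplier for domain-dictionary terms (applied after
    decay when a term is both). ``rank_direction`` 'as_printed' applies
    exp(-alpha*rank) with rank 1 = most frequent (mildest penalty on the
    top term); 'inverted' reverses the ranks inside the decile so the most
    frequent term is penalized hardest. ``rank_scope`` 'all' decays every
    term by its global rank instead of only the decile.
    """

    alpha: float = 0.05
    decile: float = 0.10
    boost: float = 1.5
    dictionary: frozenset[str] = field(default_factory=load_default_dictionary)
    rank_scope: str = "decile_only"
    rank_direction: str = "as_printed"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.decile <= 1:
            raise ValueError("decile must be in (0, 1]")
        if self.boost < 1:
            raise ValueError("boost must be >= 1")
        if self.rank_scope not in ("decile_only", "all"):
            raise ValueError(f"unknown rank_scope {self.rank_scope!r}")
        if self.rank_direction not in ("as_printed", "inverted"):
            raise ValueError(f"unknown rank_direction {self.rank_direction!r}")


@dataclass
class TopicRepresentation:
    topic_id: int
    keywords: list[tuple[str, float]]
    mmr_lambda: float = 0.5

    @property
    def words(self) -> list[str]:
        return [w for w, _ in self.keywords]


def ctfidf(
    docs: Sequence[CleanDocument],
    labels: Sequence[int],
    *,
    log_base: float | None = None,
) -> TermWeights:
    """Class-based TF-IDF over topics.

    Noise-labelled documents contribute to N and to document frequencies
    but not to any topic's term frequencies. Natural log by default
    (``log_base`` overrides). A term present in every document has zero
    weight everywhere; an empty topic yields a zero row with a warning.
    """
    y = np.asarray(labels, dtype=int)
    if len(docs) != y.size:
        raise ValueError("docs and labels misaligned")
    topics = sorted(set(y[y != NOISE].tolist()))
    if not topics:
        raise ValueError("need at least one non-noise topic")

    vocab_counter: Counter[str] = Counter()
    doc_freq_counter: Counter[str] = Counter()
    for d in docs:
        vocab_counter.update(d.tokens)
        doc_freq_counter.update(set(d.tokens))
    vocabulary = sorted(vocab_counter)
    if not vocabulary:
        raise ValueError("empty vocabulary")
    index = {w: i for i, w in enumerate(vocabulary)}

    n_docs = len(docs)
    doc_freq = np.array([doc_freq_counter[w] for w in vocabulary], dtype=float)
    corpus_tf = np.array([vocab_counter[w] for w in vocabulary], dtype=float)

    tf = np.zeros((len(topics), len(vocabulary)))
    for d, lab in zip(docs, y):
        if lab == NOISE:
            continue
        row = topics.index(lab)
        for tok in d.tokens:
            tf[row, index[tok]] += 1

    totals = tf.sum(axis=1, keepdims=True)
    empty = totals[:, 0] == 0
    if empty.any():
        logger.warning("ctfidf: %d empty topics get zero rows", int(empty.sum()))
    totals[empty] = 1.0

    idf = np.log(n_docs / doc_freq)
    if log_base is not None:
        idf = idf / math.log(log_base)
    weights = (tf / totals) * idf
    return TermWeights(
        topics=topics,
        vocabulary=vocabulary,
        weights=weights,
        doc_freq=doc_freq,
        corpus_tf=corpus_tf,
        n_docs=n_docs,
    )


def frequency_ranks(tw: TermWeights) -> dict[str, int]:
    """1-based corpus-frequency rank per term (1 = most frequent); ties
    broken lexicographically for determinism."""
    order = sorted(zip(-tw.corpus_tf, tw.vocabulary))
    return {term: r + 1 for r, (_, term) in enumerate(order)}


def _dictionary_tokens(dictionary: frozenset[str]) -> frozenset[str]:
    """Unigram match set: multiword entries contribute their component
    tokens (hyphenated entries also contribute the joined form)."""
    out: set[str] = set()
    for entry in dictionary:
        out.update(entry.replace("-", " ").split())
        if "-" in entry:
            out.add(entry.replace("-", ""))
        out.add(entry)
    return frozenset(out)


@dataclass
class PDRDiagnostics:
    """Mean new/old weight ratios over the affected term sets."""

    reduction_ratio: float | None
    boosting_rate: float | None
    n_decile_terms: int
    n_dictionary_terms: int


def pdr_weights(
    tw: TermWeights, cfg: PDRConfig | None = None
) -> tuple[TermWeights, PDRDiagnostics]:
    """Apply the popularity-deviation regularizer to a term-weight matrix.

    Terms in the top ``decile`` of corpus frequency are multiplied by the
    exponential rank decay; dictionary terms by ``boost`` (after decay when
    both apply). All other weights are untouched; output stays >= 0.
    """
    cfg = cfg or PDRConfig()
    ranks = frequency_ranks(tw)
    v = len(tw.vocabulary)
    n_decile = max(1, int(math.ceil(cfg.decile * v)))
    dict_tokens = _dictionary_tokens(cfg.dictionary)

    multiplier = np.ones(v)
    n_dict = 0
    for j, term in enumerate(tw.vocabulary):
        rank = ranks[term]
        in_decile = rank <= n_decile
        if cfg.rank_scope == "all" or in_decile:
            r = rank
            if cfg.rank_direction == "inverted":
                span = n_decile if cfg.rank_scope == "decile_only" else v
                r = span - rank + 1
            multiplier[j] *= math.exp(-cfg.alpha * r)
        if term in dict_tokens:
            multiplier[j] *= cfg.boost
            n_dict += 1

    new_weights = tw.weights * multiplier[None, :]

    decile_mask = np.array([ranks[t] <= n_decile for t in tw.vocabulary])
    dict_mask = np.array([t in dict_tokens for t in tw.vocabulary])
    diag = PDRDiagnostics(
        reduction_ratio=_mean_ratio(tw.weights, new_weights, decile_mask),
        boosting_rate=_mean_ratio(tw.weights, new_weights, dict_mask),
        n_decile_terms=int(decile_mask.sum()),
        n_dictionary_terms=n_dict,
    )
    out = TermWeights(
        topics=list(tw.topics),
        vocabulary=list(tw.vocabulary),
        weights=new_weights,
        doc_freq=tw.doc_freq.copy(),
        corpus_tf=tw.corpus_tf.copy(),
        n_docs=tw.n_docs,
    )
    return out, diag


def _mean_ratio(old: np.ndarray, new: np.ndarray, col_mask: np.ndarray) -> float | None:
    mask = (old > 0) & col_mask[None, :]
    if not mask.any():
        return None
    return float(np.mean(new[mask] / old[mask]))


def mmr_select(
    candidates: Sequence[tuple[str, float]],
    sim: np.ndarray,
    lam: float,
    k: int,
) -> list[tuple[str, float]]:
    """Greedy maximal-marginal-relevance selection.

    ``candidates`` are (term, relevance) pairs; ``sim`` the term-term
    similarity matrix in candidate order. The first pick is the highest
    relevance; each later pick maximizes lam*relevance - (1-lam)*max
    similarity to the already-selected set. Requesting more than
    ``len(candidates)`` returns all with a warning.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(candidates)
    if k > n:
        logger.warning("mmr_select: k=%d > %d candidates; returning all", k, n)
        k = n
    if n == 0:
        return []
    sim = np.asarray(sim, dtype=float)
    rel = np.array([r for _, r in candidates])

    selected: list[int] = [int(np.argmax(rel))]
    remaining = set(range(n)) - set(selected)
    while len(selected) < k:
        best_i, best_score = None, -np.inf
        for i in sorted(remaining):
            redundancy = max(sim[i, j] for j in selected)
            score = lam * rel[i] - (1 - lam) * redundancy
            if score > best_score:
                best_i, best_score = i, score
        selected.append(best_i)
        remaining.discard(best_i)
    return [candidates[i] for i in selected]


def extract_topic_keywords(
    tw: TermWeights,
    embedder: HashEmbedder | None = None,
    *,
    top_k: int = 10,
    mmr_lambda: float = 0.5,
    candidate_pool: int | None = None,
) -> list[TopicRepresentation]:
    """Ranked keyword lists per topic via MMR over the top-weighted terms.

    The candidate pool is the topic's ``candidate_pool`` (default 2*top_k)
    highest-weighted terms; the query q is their weight-weighted centroid
    in token-embedding space, relevance is cosine(term, q), and term-term
    similarity is cosine between token embeddings. Without an embedder the
    selection degrades to plain weight ranking (lambda=1 equivalent).
    """
    pool_size = candidate_pool or 2 * top_k
    reps: list[TopicRepresentation] = []
    for row, topic in enumerate(tw.topics):
        w = tw.weights[row]
        order = sorted(range(len(w)), key=lambda j: (-w[j], tw.vocabulary[j]))
        pool = [j for j in order[:pool_size] if w[j] > 0]
        if not pool:
            reps.append(TopicRepresentation(topic_id=topic, keywords=[], mmr_lambda=mmr_lambda))
            continue
        terms = [tw.vocabulary[j] for j in pool]
        weights = np.array([w[j] for j in pool])
        if embedder is None:
            chosen = [(t, float(x)) for t, x in zip(terms, weights)][:top_k]
        else:
            vecs = np.stack([embedder.token_vector(t) for t in terms])
            q = (weights[:, None] * vecs).sum(axis=0) / weights.sum()
            qn = np.linalg.norm(q)
            rel = vecs @ q / qn if qn > 0 else weights
            sim = vecs @ vecs.T
            picked = mmr_select(list(zip(terms, rel)), sim, mmr_lambda, top_k)
            weight_of = dict(zip(terms, weights))
            chosen = [(t, float(weight_of[t])) for t, _ in picked]
        reps.append(
            TopicRepresentation(topic_id=topic, keywords=chosen, mmr_lambda=mmr_lambda)
        )
    return reps
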