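import math
from itertools import combinations

import numpy as np
import pytest

from shorttopic.metrics import (
    centroid_cosine,
    lexical_diversity,
    npmi,
    outlier_rate,
    perplexity,
    silhouette,
    topic_diversity,
)

from conftest import make_docs, make_matrix


# --- independent brute-force references ------------------------------------

def brute_silhouette(x, labels):
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    vals = []
    for i in range(len(x)):
        own = [j for j in range(len(x)) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j]) for j in range(len(x)) if labels[j] == other])
            for other in set(labels.tolist()) - {labels[i]}
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def brute_npmi(topics, docs, eps=1e-12):
    n = len(docs)
    sets = [set(d.tokens) for d in docs]
    per_topic = []
    for words in topics:
        vals = []
        for wi, wj in combinations(words, 2):
            di = sum(1 for s in sets if wi in s)
            dj = sum(1 for s in sets if wj in s)
            if di == 0 or dj == 0:
                continue
            joint = max(sum(1 for s in sets if wi in s and wj in s) / n, eps)
            vals.append(math.log(joint / (di / n * dj / n)) / (-math.log(joint)))
        if vals:
            per_topic.append(np.mean(vals))
    return float(np.mean(per_topic)) if per_topic else None


# --- silhouette -------------------------------------------------------------

def test_silhouette_hand_example():
    """1-D points {0, 0.1 | 10, 10.1}: s(0) = (10.05 - 0.1)/10.05."""
    x = np.array([[0.0], [0.1], [10.0], [10.1]])
    labels = [0, 0, 1, 1]
    s0 = (10.05 - 0.1) / 10.05
    s1 = (9.95 - 0.1) / 9.95
    expected = np.mean([s0, s1, s1, s0])
    assert silhouette(x, labels) == pytest.approx(expected, abs=1e-9)
    assert s0 == pytest.approx(0.99005, abs=1e-5)


def test_silhouette_overlapping_clusters_near_zero(rng):
    x = rng.normal(0, 1.0, size=(40, 2))  # one cloud, arbitrary split
    labels = [0] * 20 + [1] * 20
    assert silhouette(x, labels) <= 0.05


def test_silhouette_matches_brute_force(rng):
    x = rng.normal(size=(10, 2))
    labels = rng.choice([0, 1, 2], size=10)
    while len(set(labels)) < 2:
        labels = rng.choice([0, 1, 2], size=10)
    assert silhouette(x, labels) == pytest.approx(brute_silhouette(x, labels), abs=1e-9)


def test_silhouette_excludes_noise(rng):
    x = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(5, 0.1, (5, 2))])
    labels = np.array([0] * 5 + [1] * 5)
    with_noise = np.concatenate([labels, [-1]])
    x_noise = np.vstack([x, [[100.0, 100.0]]])
    assert silhouette(x_noise, with_noise) == pytest.approx(silhouette(x, labels), abs=1e-12)


def test_silhouette_undefined_single_cluster():
    assert silhouette(np.ones((4, 2)), [0, 0, 0, -1]) is None


# --- outlier rate ------------------------------------------------------------

@pytest.mark.parametrize(
    "n_noise,n_total,expected_pct",
    [(17670, 64407, 27.43), (3368, 64407, 5.23), (0, 100, 0.0)],
)
def test_outlier_rate_printed_values(n_noise, n_total, expected_pct):
    labels = [-1] * n_noise + [0] * (n_total - n_noise)
    rate, num, den = outlier_rate(labels)
    assert round(100 * rate, 2) == expected_pct
    assert (num, den) == (n_noise, n_total)


def test_outlier_rate_empty_errors():
    with pytest.raises(ValueError):
        outlier_rate([])


# --- NPMI --------------------------------------------------------------------

def test_npmi_perfect_cooccurrence():
    docs = make_docs([["a", "b"], ["a", "b"], ["c"], ["d"]])
    val, coverage = npmi([["a", "b"]], docs)
    assert val == pytest.approx(1.0, abs=1e-9)
    assert coverage == 1.0


def test_npmi_independence_is_zero():
    docs = make_docs([["w1", "w2"], ["w1"], ["w2"], ["z"]])
    val, _ = npmi([["w1", "w2"]], docs)
    assert val == pytest.approx(0.0, abs=1e-12)


def test_npmi_disjoint_tends_to_minus_one():
    """Never co-occurring words score the smoothed minimum, which tends
    to -1 as the smoothing epsilon vanishes."""
    docs = make_docs([["a"], ["a"], ["b"], ["b"]])
    val, _ = npmi([["a", "b"]], docs)
    assert val < -0.9
    tighter, _ = npmi([["a", "b"]], docs, eps=1e-300)
    assert tighter == pytest.approx(-1.0, abs=3e-3)
    assert tighter < val


def test_npmi_symmetric_and_duplication_invariant(rng):
    vocab = [f"w{i}" for i in range(8)]
    docs = make_docs([list(rng.choice(vocab, size=4, replace=False)) for _ in range(12)])
    fwd, _ = npmi([["w0", "w1", "w2"]], docs)
    rev, _ = npmi([["w2", "w1", "w0"]], docs)
    assert fwd == pytest.approx(rev, abs=1e-12)
    doubled = docs + [
        type(d)(id=d.id + "_copy", tokens=d.tokens) for d in docs
    ]
    dup, _ = npmi([["w0", "w1", "w2"]], docs + doubled[len(docs):])
    assert dup == pytest.approx(fwd, abs=1e-12)


def test_npmi_matches_brute_force(rng):
    vocab = [f"w{i}" for i in range(10)]
    docs = make_docs([list(rng.choice(vocab, size=5)) for _ in range(30)])
    topics = [["w0", "w1", "w2", "w3"], ["w4", "w5", "w6"]]
    val, _ = npmi(topics, docs)
    assert val == pytest.approx(brute_npmi(topics, docs), abs=1e-9)


def test_npmi_skips_unseen_words():
    docs = make_docs([["a", "b"]] * 3)
    val, coverage = npmi([["a", "b", "zzz"]], docs)
    assert val == pytest.approx(1.0)
    assert coverage == pytest.approx(1 / 3)


# --- topic diversity ---------------------------------------------------------

def test_topic_diversity_cases():
    assert topic_diversity([["a", "b"], ["c", "d"]]) == 1.0
    same = [["w1", "w2", "w3"]] * 4
    assert topic_diversity(same) == 0.25
    t1 = [f"w{i}" for i in range(10)]
    t2 = [f"w{i}" for i in range(5)] + [f"v{i}" for i in range(5)]
    assert topic_diversity([t1, t2]) == 0.75


# --- perplexity --------------------------------------------------------------

def test_perplexity_one_hot():
    P = np.eye(3)[[0, 1, 2, 0]]
    assert perplexity(P, [0, 1, 2, 0]) == pytest.approx(1.0, abs=1e-12)


def test_perplexity_uniform_equals_m():
    P = np.full((6, 5), 0.2)
    assert perplexity(P, [0, 1, 2, 3, 4, 0]) == pytest.approx(5.0, abs=1e-9)


def test_perplexity_closed_form():
    P = np.tile([0.75, 0.25], (4, 1))
    assert perplexity(P, [0, 0, 0, 0]) == pytest.approx(4 / 3, abs=1e-12)


def test_perplexity_ignores_noise_and_bounds(rng):
    d = rng.uniform(size=(10, 4))
    P = d / d.sum(axis=1, keepdims=True)
    labels = np.argmax(P, axis=1)
    labels[0] = -1
    val = perplexity(P, labels)
    assert 1.0 <= val <= 4.0


def test_perplexity_misaligned_errors():
    with pytest.raises(ValueError):
        perplexity(np.eye(2), [0])


# --- lexical diversity -------------------------------------------------------

def test_lexical_diversity_cases():
    docs = make_docs([["a", "b"], ["c", "d"], ["a", "b"], ["a", "b"]])
    weights = {0: {"a": 2.0, "b": 1.0, "c": 0.5, "d": 0.2}}
    # topic 0 has docs 0 and 1, all four slots distinct
    assert lexical_diversity(weights, docs, [0, 0, -1, -1], per_doc_top_m=2) == 1.0
    # three identical docs: 6 slots, 2 distinct
    assert lexical_diversity(weights, docs, [0, -1, 0, 0], per_doc_top_m=2) == pytest.approx(2 / 6)
    # single-document topic is 1.0 by construction
    assert lexical_diversity(weights, docs, [0, -1, -1, -1], per_doc_top_m=2) == 1.0


def test_lexical_diversity_uses_weights_for_top_m():
    docs = make_docs([["low", "high", "mid"]])
    weights = {0: {"high": 3.0, "mid": 2.0, "low": 1.0}}
    # with m=2 only high and mid are counted; still 1.0 (distinct), but
    # check the slot count through a repeated-doc variant
    docs2 = make_docs([["low", "high", "mid"], ["high", "mid", "other"]])
    val = lexical_diversity(weights, docs2, [0, 0], per_doc_top_m=2)
    assert val == pytest.approx(2 / 4)


def test_lexical_diversity_no_members_is_none():
    docs = make_docs([["a"]])
    assert lexical_diversity({0: {"a": 1.0}}, docs, [-1]) is None


# --- centroid cosine ---------------------------------------------------------

def test_centroid_cosine_identical_docs():
    x = np.tile([1.0, 2.0], (5, 1))
    assert centroid_cosine(x, [0] * 5) == pytest.approx(1.0, abs=1e-12)


def test_centroid_cosine_orthogonal_pair():
    x = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert centroid_cosine(x, [0, 0]) == pytest.approx(math.sqrt(2) / 2, abs=1e-9)


def test_centroid_cosine_range_and_noise(rng):
    x = rng.normal(size=(20, 3))
    labels = rng.choice([0, 1, -1], size=20)
    while len(set(labels.tolist()) - {-1}) < 1:
        labels = rng.choice([0, 1, -1], size=20)
    val = centroid_cosine(x, labels)
    assert -1.0 - 1e-9 <= val <= 1.0 + 1e-9


def test_centroid_cosine_brute_force(rng):
    x = rng.normal(size=(9, 3))
    labels = np.array([0, 0, 0, 1, 1, 1, -1, 2, 2])
    vals = []
    for t in (0, 1, 2):
        c = x[labels == t].mean(axis=0)
        for v in x[labels == t]:
            vals.append(v @ c / (np.linalg.norm(v) * np.linalg.norm(c)))
    assert centroid_cosine(x, labels) == pytest.approx(np.mean(vals), abs=1e-9)
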