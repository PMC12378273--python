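import math

import numpy as np
import pytest

from shorttopic.represent import (
    PDRConfig,
    ctfidf,
    extract_topic_keywords,
    frequency_ranks,
    mmr_select,
    pdr_weights,
)
from shorttopic.embed import HashEmbedder

from conftest import make_docs


def brute_ctfidf(docs, labels):
    """Literal two-loop reference for class-based TF-IDF (natural log)."""
    vocab = sorted({t for d in docs for t in d.tokens})
    topics = sorted({l for l in labels if l != -1})
    n = len(docs)
    df = {w: sum(1 for d in docs if w in d.tokens) for w in vocab}
    out = np.zeros((len(topics), len(vocab)))
    for ti, topic in enumerate(topics):
        members = [d for d, l in zip(docs, labels) if l == topic]
        total = sum(len(d.tokens) for d in members)
        for wi, w in enumerate(vocab):
            tf = sum(d.tokens.count(w) for d in members)
            if total and tf:
                out[ti, wi] = tf / total * math.log(n / df[w])
    return topics, vocab, out


def test_ctfidf_hand_example():
    """N=4 docs, term in 1 doc with TF 2 of topic total 10 -> 0.2 ln 4."""
    docs = make_docs(
        [
            ["w", "w", "a", "a", "a", "a", "a", "a", "a", "a"],
            ["b", "b", "b"],
            ["c"],
            ["a", "c"],
        ]
    )
    labels = [0, 1, 1, -1]
    tw = ctfidf(docs, labels)
    j = tw.vocabulary.index("w")
    assert tw.weights[0, j] == pytest.approx(0.2 * math.log(4), abs=1e-12)


def test_ctfidf_ubiquitous_term_zero():
    docs = make_docs([["x", "a"], ["x", "b"], ["x", "c"]])
    tw = ctfidf(docs, [0, 0, 1])
    j = tw.vocabulary.index("x")
    np.testing.assert_allclose(tw.weights[:, j], 0.0, atol=1e-15)


def test_ctfidf_absent_term_zero():
    docs = make_docs([["a", "b"], ["c"]])
    tw = ctfidf(docs, [0, 1])
    assert tw.weights[1, tw.vocabulary.index("a")] == 0.0


def test_ctfidf_matches_two_loop_reference(rng):
    vocab = [f"w{i}" for i in range(30)]
    docs = make_docs(
        [list(rng.choice(vocab, size=rng.integers(3, 12))) for _ in range(40)]
    )
    labels = list(rng.choice([0, 1, 2, -1], size=40))
    if not set(labels) - {-1}:
        labels[0] = 0
    tw = ctfidf(docs, labels)
    topics, vocab_ref, ref = brute_ctfidf(docs, labels)
    assert tw.topics == topics and tw.vocabulary == vocab_ref
    np.testing.assert_allclose(tw.weights, ref, atol=1e-9)


def test_ctfidf_log10_option():
    docs = make_docs([["w", "a"], ["b"], ["c"], ["d"]])
    tw = ctfidf(docs, [0, 0, 1, 1], log_base=10)
    # topic 0 has 3 tokens total (w, a, b); w in 1 of 4 docs
    j = tw.vocabulary.index("w")
    assert tw.weights[0, j] == pytest.approx((1 / 3) * math.log10(4))


def _uniform_tw(docs, labels):
    return ctfidf(docs, labels)


def make_ranked_corpus():
    """Corpus where 'pop' is the most frequent term by a wide margin but
    absent from some documents (so its IDF stays positive)."""
    lists = []
    for i in range(10):
        toks = []
        if i < 8:
            toks += ["pop"] * 5
        if i < 6:
            toks += ["mid"] * 2
        toks.append(f"rare{i}")
        lists.append(toks)
    return make_docs(lists), [i % 2 for i in range(10)]


def test_pdr_rank_one_closed_form():
    docs, labels = make_ranked_corpus()
    tw = ctfidf(docs, labels)
    assert frequency_ranks(tw)["pop"] == 1
    cfg = PDRConfig(alpha=0.05, decile=0.05, dictionary=frozenset())  # decile of 12 terms -> top 1
    out, _ = pdr_weights(tw, cfg)
    j = tw.vocabulary.index("pop")
    mask = tw.weights[:, j] > 0
    ratio = out.weights[mask, j] / tw.weights[mask, j]
    np.testing.assert_allclose(ratio, math.exp(-0.05), atol=1e-12)


def test_pdr_dictionary_boost_outside_decile():
    """Dictionary term outside the decile: weight 0.4 -> 0.6 (x1.5)."""
    lists = [["pop"] * 10 + ["bullying"] for _ in range(8)]
    docs = make_docs(lists)
    tw = ctfidf(docs, [0] * 4 + [1] * 4)
    cfg = PDRConfig(decile=0.5, dictionary=frozenset({"bullying"}))
    ranks = frequency_ranks(tw)
    assert ranks["bullying"] > 1  # pop occupies rank 1
    tw.weights = np.where(
        np.array(tw.vocabulary) == "bullying", 0.4, tw.weights
    )
    out, _ = pdr_weights(tw, cfg)
    j = tw.vocabulary.index("bullying")
    np.testing.assert_allclose(out.weights[:, j], 0.6, atol=1e-12)


def test_pdr_alpha_zero_only_boost_applies():
    docs, labels = make_ranked_corpus()
    tw = ctfidf(docs, labels)
    out, _ = pdr_weights(tw, PDRConfig(alpha=0.0, dictionary=frozenset()))
    np.testing.assert_allclose(out.weights, tw.weights, atol=1e-15)


def test_pdr_identity_off_support():
    docs, labels = make_ranked_corpus()
    tw = ctfidf(docs, labels)
    cfg = PDRConfig(alpha=0.3, decile=0.1, dictionary=frozenset({"bullying"}))
    out, _ = pdr_weights(tw, cfg)
    ranks = frequency_ranks(tw)
    n_dec = max(1, math.ceil(0.1 * len(tw.vocabulary)))
    for j, term in enumerate(tw.vocabulary):
        if ranks[term] > n_dec and term != "bullying":
            np.testing.assert_allclose(out.weights[:, j], tw.weights[:, j], atol=1e-15)


def test_pdr_monotone_decay_within_decile():
    lists = [["a"] * 8, ["b"] * 6, ["c"] * 4, ["d"] * 2, ["e"]]
    docs = make_docs([l + ["filler"] for l in lists])
    tw = ctfidf(docs, [0, 0, 1, 1, 1])
    cfg = PDRConfig(alpha=0.5, decile=0.67, dictionary=frozenset())
    out, _ = pdr_weights(tw, cfg)
    ranks = frequency_ranks(tw)
    n_dec = max(1, math.ceil(0.67 * len(tw.vocabulary)))
    mults = {}
    for j, t in enumerate(tw.vocabulary):
        mask = tw.weights[:, j] > 0
        if ranks[t] <= n_dec and mask.any():
            mults[ranks[t]] = float((out.weights[mask, j] / tw.weights[mask, j])[0])
    ranks_sorted = sorted(mults)
    assert all(
        mults[r1] > mults[r2] for r1, r2 in zip(ranks_sorted, ranks_sorted[1:])
    )


def test_pdr_inverted_direction_penalizes_top_hardest():
    docs, labels = make_ranked_corpus()
    tw = ctfidf(docs, labels)
    cfg = PDRConfig(alpha=0.5, decile=0.3, rank_direction="inverted", dictionary=frozenset())
    out, _ = pdr_weights(tw, cfg)
    ranks = frequency_ranks(tw)
    n_dec = max(1, math.ceil(0.3 * len(tw.vocabulary)))
    mult_of_rank = {}
    for j, t in enumerate(tw.vocabulary):
        mask = tw.weights[:, j] > 0
        if ranks[t] <= n_dec and mask.any():
            mult_of_rank[ranks[t]] = float((out.weights[mask, j] / tw.weights[mask, j])[0])
    assert mult_of_rank[1] == min(mult_of_rank.values())


def test_pdr_diagnostics_match_brute_force(rng):
    vocab = [f"w{i}" for i in range(40)] + ["bullying", "sleep"]
    docs = make_docs(
        [list(rng.choice(vocab, size=10)) for _ in range(30)]
    )
    labels = list(rng.choice([0, 1], size=30))
    tw = ctfidf(docs, labels)
    cfg = PDRConfig(dictionary=frozenset({"bullying", "sleep"}))
    out, diag = pdr_weights(tw, cfg)
    ranks = frequency_ranks(tw)
    n_dec = max(1, math.ceil(cfg.decile * len(tw.vocabulary)))
    ratios = [
        out.weights[i, j] / tw.weights[i, j]
        for j, t in enumerate(tw.vocabulary)
        for i in range(len(tw.topics))
        if ranks[t] <= n_dec and tw.weights[i, j] > 0
    ]
    assert diag.reduction_ratio == pytest.approx(np.mean(ratios), abs=1e-12)
    dict_ratios = [
        out.weights[i, j] / tw.weights[i, j]
        for j, t in enumerate(tw.vocabulary)
        for i in range(len(tw.topics))
        if t in ("bullying", "sleep") and tw.weights[i, j] > 0
    ]
    if dict_ratios:
        assert diag.boosting_rate == pytest.approx(np.mean(dict_ratios), abs=1e-12)


def test_pdr_nonnegative_output(rng):
    vocab = [f"w{i}" for i in range(20)]
    docs = make_docs([list(rng.choice(vocab, size=8)) for _ in range(20)])
    tw = ctfidf(docs, list(rng.choice([0, 1], size=20)))
    out, _ = pdr_weights(tw, PDRConfig())
    assert (out.weights >= 0).all()


def test_mmr_lambda_one_is_topk_by_relevance():
    cands = [("a", 0.9), ("b", 0.8), ("c", 0.5), ("d", 0.2)]
    sim = np.ones((4, 4))
    picked = mmr_select(cands, sim, lam=1.0, k=3)
    assert [t for t, _ in picked] == ["a", "b", "c"]


def test_mmr_diversity_example():
    """rel=(0.9,0.8,0.5), sim(1,2)=0.9 others 0, lambda=0.5 -> (1,3,2)."""
    cands = [("w1", 0.9), ("w2", 0.8), ("w3", 0.5)]
    sim = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
    picked = mmr_select(cands, sim, lam=0.5, k=3)
    assert [t for t, _ in picked] == ["w1", "w3", "w2"]


def test_mmr_exhaustive_and_overflow():
    cands = [("a", 0.9), ("b", 0.1)]
    sim = np.eye(2)
    assert len(mmr_select(cands, sim, 0.5, 2)) == 2
    assert len(mmr_select(cands, sim, 0.5, 5)) == 2
    assert len({t for t, _ in mmr_select(cands, sim, 0.5, 2)}) == 2


def test_mmr_validation():
    with pytest.raises(ValueError):
        mmr_select([("a", 1.0)], np.eye(1), lam=1.5, k=1)
    with pytest.raises(ValueError):
        mmr_select([("a", 1.0)], np.eye(1), lam=0.5, k=0)


def test_extract_topic_keywords_unique_and_sized(rng):
    vocab = [f"w{i}" for i in range(50)]
    docs = make_docs([list(rng.choice(vocab, size=10)) for _ in range(40)])
    tw = ctfidf(docs, list(rng.choice([0, 1, 2], size=40)))
    reps = extract_topic_keywords(tw, HashEmbedder(dim=32, seed=0), top_k=5)
    assert [r.topic_id for r in reps] == tw.topics
    for rep in reps:
        words = rep.words
        assert len(words) == len(set(words)) <= 5
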