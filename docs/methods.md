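# Methods

`shorttopic` implements a topic-modeling pipeline for short, noisy texts
(tweet-length documents) built from five stages — embedding, manifold
reduction, density clustering, class-based keyword extraction, and
probabilistic outlier reassignment — plus three optimisations aimed at
the failure modes of this family of models on short text: a popularity
deviation regularizer (PDR) on keyword weights, silhouette-driven
selection of the reduced dimensionality (DDEO), and a probabilistic
reassignment matrix (PRM) that rescues noise documents. This note
records the model, its assumptions, the parameter choices, and what the
synthetic evaluation does and does not show.

## Preprocessing

Documents are lowercased; URLs (strings starting `http(s)://` or `www`)
and emoji (fixed Unicode ranges: emoticons U+1F600–1F64F, symbols &
pictographs U+1F300–1F5FF, transport U+1F680–1F6FF, flags
U+1F1E6–1F1FF, supplemental U+1F900–1F9FF, plus the BMP
misc-symbol/dingbat blocks U+2600–27BF) are removed; leading `@`/`#`
sigils are stripped; tokens are maximal runs of word characters
(underscores kept). Stopwords come from a packaged static copy of the
standard English list so behaviour never depends on a download. HTML
entities are deliberately *not* decoded (so `&amp;` yields the token
`amp`): the pipeline treats punctuation stripping as the only
normalisation, and entity decoding is left to the caller. A plural `-s`
stripper (protected endings `-ss`, `-us`, `-is`; minimum length 4) is on
by default and is the reason `portraits` → `portrait`. Cleaning is
idempotent, which the suite checks property-style.

Near-duplicate removal runs in input order: exact SHA-256 hash matching
on the normalised text first (cheap), then cosine similarity of document
embeddings against every already-retained document, dropping a candidate
when similarity reaches ε (default 0.95). The earliest member of a
duplicate group always survives, making the operation deterministic and
idempotent.

## Embedding

A document vector is the arithmetic mean of its token vectors. The
default backend maps each term to a deterministic unit-norm Gaussian
direction seeded from a SHA-256 digest of (term, seed), at dimension
256. At this dimension distinct terms are nearly orthogonal
(|cos| ≈ 1/16 typical), which is the property the rest of the pipeline
relies on; 64 dimensions proved too low — cross-talk between unrelated
terms of a few-hundred-term vocabulary visibly blurred the mean-pooled
vectors. A pretrained sentence-transformer backend
(`paraphrase-multilingual-MiniLM-L12-v2` by default) is available behind
the same interface when the optional dependency is installed; it does
its own internal pooling and is not exercised by the test suite.
Documents that are empty after cleaning are dropped with a warning
rather than zero-embedded, because zero vectors have no cosine geometry.
Hash vectors are unit-norm; transformer vectors are taken as produced,
without L2 normalisation.

## Reduction and dimension selection

Reduction is UMAP (`n_neighbors` 30 on full-scale corpora, cosine
metric, fixed `random_state` so runs are reproducible and
single-threaded). Rather than fixing the output dimensionality, the
selector sweeps a candidate grid (every integer in [2, 40] by default; a
strided grid 2..40 step 4 in the bundled 1000-document run configuration,
purely a cost knob), clusters each reduced space with *fixed* clustering
hyperparameters and one shared seed, and scores each dimension by the
Euclidean silhouette of the non-noise points. The selected dimension is
the argmax; exact ties go to the smaller dimension; dimensions where the
silhouette is undefined (fewer than two clusters) score a −1 sentinel;
if every candidate is undefined the selector falls back to the fixed
baseline dimensionality 5 with a warning. For corpora beyond 20k points
the silhouette is computed on a seeded subsample (documented
approximation; off by default at the scales shipped).

## Clustering

Clustering is HDBSCAN over the reduced vectors: mutual reachability
distance d_mreach(i,j) = max(core_k(i), core_k(j), d(i,j)) with
core_k(x) the distance to the k-th nearest neighbour (self excluded),
k = `min_samples`, defaulting to `min_cluster_size`; single-linkage
hierarchy; condensation by minimum cluster size; stability-based cluster
selection; unassigned points labelled −1. The hierarchy construction is
delegated to `sklearn.cluster.HDBSCAN`; the package implements the
mutual-reachability metric and the outlier score itself and cross-checks
the metric against a brute-force reference in the tests.

The per-member outlier score is core(x) divided by the arithmetic mean
core distance of x's cluster, so scores within a cluster average to
exactly 1 and values well above 1 mark the sparse fringe. Noise points
get NaN — they have no reference density.

Per-cluster stability diagnostics report λ_birth (inverse of the
cheapest spanning-tree edge leaving the cluster) and λ_death (inverse of
the largest internal spanning-tree edge), with persistence
n_members·(λ_death − λ_birth) ≥ 0. Under the λ = 1/distance convention a
cluster is born at a *smaller* λ than it dies, so the persistence is the
death-minus-birth span; formulations that subtract in the other order
describe the same quantity up to sign. These diagnostics are computed
from an O(N²) spanning tree and are skipped above 5000 points; they
never influence labelling.

`min_cluster_size` defaults to 100, appropriate for corpora of tens of
thousands of documents; the bundled 1000-document run configuration uses
50, keeping every planted topic (≈180 topical documents) comfortably
above the threshold at 1/64 of that corpus scale.

## Keyword extraction

Class-based TF-IDF treats each topic as one pseudo-document:

    w(t, c) = TF(t, c) / Σ_t' TF(t', c) · ln(N / df(t)),

with N the total corpus size and df document frequency over the whole
corpus; noise documents count toward N and df but contribute no topic
term frequency. Natural log by default (log10 available). A term in
every document is annihilated by the IDF factor; empty topics get zero
rows with a warning.

The popularity deviation regularizer then multiplies terms in the top
decile of raw corpus term frequency (rank 1 = most frequent, ties broken
lexicographically) by exp(−α·rank) with α = 0.05, and terms of a domain
dictionary by 1.5 (after the decay when both apply). All other weights
are untouched. Two deliberate knobs cover a genuine ambiguity in the
decay's direction: as printed, rank 1 receives the *mildest* penalty
(e^{−α}) while deep-decile terms are crushed; an `inverted` mode
reverses the ranks inside the decile so the most popular term is
penalised hardest, which arguably matches the stated intent of
suppressing top terms. The default honours the printed form, and both
are tested. Whether the decile should be taken over raw term frequency
or document frequency is likewise unspecified; raw term frequency is the
default. Two diagnostics are emitted per run — the mean new/old weight
ratio over decile terms ("reduction ratio") and over dictionary terms
("boosting rate") — implemented as mean weight ratios, an explicit
interpretation since no formula defines them.

The shipped dictionary (`data/adolescent_health.txt`) is the
adolescent-health vocabulary (sleep, stress, depression, …, mental
health, social media, …); multiword entries match through their
component tokens. Final per-topic lists are selected greedily by maximal
marginal relevance, MMR(w) = λ·Sim(w, q) − (1−λ)·max_{s∈S} Sim(w, s),
λ = 0.5, over the topic's top-2k weighted terms; the query q is the
weight-weighted centroid of those terms' token embeddings and Sim is
cosine in token-embedding space. The first pick is always the
highest-relevance term.

## Probabilistic reassignment

Every document receives a row-stochastic distribution over topics: a
softmax (temperature 1, max-subtraction for stability) of negative
distances from the document to each topic centroid (mean member
vector). Distances are cosine in the reduced space by default; both the
metric and the space (reduced vs original embedding) are configurable,
and zero-norm vectors fall back to Euclidean entries with a warning. A
noise document is reassigned to its argmax topic iff the winning
probability strictly exceeds 0.15; ties go to the lowest topic index;
hard-assigned documents are never touched, so the outlier rate is
non-increasing by construction. Reassignment is single-pass: keyword
lists and the term-weight matrix are computed from the pre-reassignment
clustering (a flag allows recomputation), so the rescue step changes the
outlier rate and the perplexity but not NPMI or topic diversity.

## Metrics

* **Silhouette** — mean over non-noise points of (b−a)/max(a,b),
  Euclidean in the reduced space; undefined (None) below two clusters.
* **Outlier rate** — fraction of documents labelled −1, reported with
  numerator and denominator.
* **NPMI coherence** — per topic, the mean over top-k word pairs of
  PMI/(−log p(wi,wj)) with document-level occurrence probabilities and
  joint probability floored at 1e−12; mean over topics; word pairs with
  an unseen member are skipped and surface in a coverage fraction. A
  pair present in every document takes the limit value 1. Implemented
  internally so results are self-contained rather than delegated to an
  external coherence service.
* **Topic diversity** — distinct words across all top-k lists over k·T.
* **Perplexity** — exp(−mean log P(d, assigned topic)) over non-noise
  documents. For this non-generative model perplexity has no canonical
  definition; this assigned-topic negative-log-likelihood form is the
  package's explicit choice. Its range is [1, M] when assignment is the
  argmax of valid rows, which matches the magnitudes such models report.
* **Lexical diversity** — per topic, each member document contributes
  its m (default 5) highest-weighted tokens under the topic's term
  weights; the topic score is distinct/total over the concatenation,
  averaged over topics. The formula is an interpretation — it is the
  per-document reading that the keyword regularizer can actually move.
* **Centroid cosine** — mean cosine between each document vector and its
  topic centroid. When the regularizer is active the document vectors
  are re-pooled as PDR-weight-weighted token means, since plain mean
  embeddings cannot register a keyword reweighting.

Top-k is 10 for NPMI and diversity. Every metric is verified against an
independent brute-force implementation on ≤50-document fixtures at
1e−9, and the closed forms (uniform-row perplexity = M, diversity of T
identical lists = 1/T, softmax of (0, ln 3) = (¾, ¼), decay multiplier
e^{−0.05} at rank 1) exactly.

## Synthetic study conditions

The corpus generator plants T = 5 topics × 200 documents of 5–30 tokens.
Each topical document mixes Zipf-distributed generic terms (25 terms,
exponent 1.0, 40% of tokens in expectation) with uniform draws from its
topic's 40-term block; `separation` sets the fraction of each block
unique to its topic (1.0 = fully disjoint); 10% of documents are planted
outliers sampling uniformly across all blocks; two domain-dictionary
terms are planted into each topic block. These conditions make the
generator's two construction goals checkable: the generic block occupies
the corpus-frequency top decile (the regularizer's intended target — an
exponent-1 Zipf over a compact generic vocabulary is what produces
this; a long-tailed generic vocabulary does not), and dictionary terms
sit inside exactly one topic, so the boost measurably raises their
keyword rank in an A/B comparison. Gold labels live in a sidecar array,
never in the text.

The embedding-fixture generator places isotropic unit-σ Gaussian blobs
with exactly equidistant centers (scaled coordinate axes when dim ≥
number of blobs) and uniform bounding-box outliers.

What passing these tests shows: the pipeline's machinery — cleaning,
pooling, dimension selection, density clustering, reweighting, rescue —
recovers planted structure and moves each metric in the direction each
optimisation targets. What it does not show: performance on real tweets,
whose embeddings come from a trained language model, whose topic
structure is not block-disjoint, and whose vocabulary is vastly larger;
no claim about real-corpus metric values is made or tested.

## Problem sizes and numerical choices

The bundled run configuration (1000 documents, 256-dim hash embeddings,
strided dimension grid, `min_cluster_size` 50) completes a fully tuned
pipeline run in well under two minutes on one CPU; the acceptance script
uses exactly these conditions. Determinism: every random source (hash
backend, UMAP, generators) is seeded from the run seed; UMAP with a
fixed `random_state` runs single-threaded. Degenerate inputs are
defined, not crashed on: empty corpora raise a clear error, empty topics
get zero keyword rows, silhouette/NPMI/perplexity return None with a
recorded reason when undefined, and all argmax ties break toward the
smaller index or lexicographically smaller term.

## Known limitations

Dictionary matching is unigram-based (multiword entries match through
their components); phrase mining beyond that is out of scope. The
transformer backend is untested offline. Stability diagnostics use an
O(N²) spanning tree and are capped at 5000 points. Reassignment is
single-pass — no EM-style refitting, and c-TF-IDF is not updated with
rescued members. Perplexity and lexical diversity follow the package's
own documented definitions and are not comparable across tools that
define them differently.
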