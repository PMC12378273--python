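"""End-to-end orchestration: preprocess, embed, reduce, cluster,
represent, reassign, evaluate — with ablation toggles and parameter
sweeps.

Each run writes a directory of plain-text artifacts (labels, keywords,
document-topic probabilities, metrics, manifest). Toggles disable the
three optimisation stages independently: without dimension tuning the
reducer uses the fixed baseline dimensionality (5); without the
popularity regularizer keywords come from plain class-based TF-IDF;
without probabilistic reassignment noise labels are kept (the
probability matrix is still emitted when topics exist).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import io as stio
from .cluster import NOISE, ClusteringConfig, ClusterResult, fit_clusters
from .embed import EmbedderSpec, EmbeddingMatrix, HashEmbedder, embed_documents
from .metrics import (
    MetricsReport,
    centroid_cosine,
    lexical_diversity,
    npmi,
    outlier_rate,
    perplexity,
    silhouette,
    topic_diversity,
)
from .preprocess import (
    CleanDocument,
    DedupConfig,
    RawDocument,
    clean_corpus,
    deduplicate,
    load_default_stopwords,
)
from .reassign import PRMConfig, build_doc_topic_matrix, reassign_outliers
from .reduce import BASELINE_DIM, DDEOResult, ReductionConfig, reduce, select_dimension
from .represent import (
    PDRConfig,
    extract_topic_keywords,
    frequency_ranks,
    ctfidf,
    pdr_weights,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration with independent stage toggles."""

    use_pdr: bool = True
    use_ddeo: bool = True
    use_prm: bool = True
    dedup: bool = True
    seed: int = 0
    embedder: EmbedderSpec = field(default_factory=EmbedderSpec)
    dedup_cfg: DedupConfig = field(default_factory=DedupConfig)
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    pdr: PDRConfig = field(default_factory=PDRConfig)
    prm: PRMConfig = field(default_factory=PRMConfig)
    top_k: int = 10
    mmr_lambda: float = 0.5
    per_doc_top_m: int = 5

    def reseeded(self) -> "RunConfig":
        """Propagate the run seed into the stage configs."""
        return dataclasses.replace(
            self,
            embedder=dataclasses.replace(self.embedder, seed=self.seed),
            reduction=dataclasses.replace(self.reduction, seed=self.seed),
        )


def default_run_config(seed: int = 0, **overrides: Any) -> RunConfig:
    """Run configuration scaled to the ~1000-document synthetic corpus:
    n_neighbors 15 and min_cluster_size 50 (the corpus-size-relative
    analogue of the 100 used on 64k documents), with a strided dimension
    grid (2..40 step 4) so a full tuned run stays fast on one CPU."""
    cfg = RunConfig(
        seed=seed,
        reduction=ReductionConfig(
            n_neighbors=15, candidate_dims=tuple(range(2, 41, 4)), seed=seed
        ),
        clustering=ClusteringConfig(min_cluster_size=50),
        embedder=EmbedderSpec(dim=256, seed=seed),
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@dataclass
class PipelineResult:
    """In-memory artifacts of one pipeline run."""

    clean_docs: list[CleanDocument]
    embeddings: EmbeddingMatrix
    reduced: EmbeddingMatrix
    ddeo: DDEOResult | None
    clusters_before: ClusterResult
    clusters: ClusterResult
    term_weights: "Any"
    pdr_diagnostics: "Any"
    keywords: list
    doc_topics: "Any"
    metrics: MetricsReport
    dedup_report: list = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return self.clusters.labels


def run_pipeline(
    corpus: str | Path | Sequence[RawDocument],
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline on a corpus (path or in-memory documents).

    Deterministic given seed and backend. If ``out_dir`` is given, all
    artifacts plus a manifest (config hash, library versions) are written
    there.
    """
    cfg = (cfg or RunConfig()).reseeded()
    raw = stio.read_corpus(corpus) if isinstance(corpus, (str, Path)) else list(corpus)

    stopwords = load_default_stopwords()
    clean = [d for d in clean_corpus(raw, stopwords) if d.tokens]
    if not clean:
        raise ValueError("no documents after preprocessing")

    embeddings = embed_documents(clean, cfg.embedder)
    clean = [d for d in clean if d.id in set(embeddings.ids)]

    dedup_report: list = []
    if cfg.dedup:
        clean, dedup_report = deduplicate(clean, embeddings, cfg.dedup_cfg)
        keep = {d.id for d in clean}
        rows = [i for i, did in enumerate(embeddings.ids) if did in keep]
        embeddings = EmbeddingMatrix(
            ids=[embeddings.ids[i] for i in rows], vectors=embeddings.vectors[rows]
        )
    if len(clean) == 0:
        raise ValueError("no documents after preprocessing")

    # --- reduction (tuned or fixed baseline dimensionality) ---
    ddeo_result = None
    if cfg.use_ddeo:
        ddeo_result = select_dimension(embeddings, cfg.reduction, cfg.clustering)
        reduced = ddeo_result.reduced
    else:
        reduced = reduce(embeddings, BASELINE_DIM, cfg.reduction)

    # --- clustering ---
    clusters_before = fit_clusters(reduced, cfg.clustering)

    # --- topic representation ---
    term_weights = None
    pdr_diag = None
    keywords: list = []
    raw_tw = None
    if clusters_before.n_clusters > 0:
        raw_tw = ctfidf(clean, clusters_before.labels)
        if cfg.use_pdr:
            term_weights, pdr_diag = pdr_weights(raw_tw, cfg.pdr)
        else:
            term_weights = raw_tw
        emb = HashEmbedder(dim=cfg.embedder.dim, seed=cfg.embedder.seed)
        keywords = extract_topic_keywords(
            term_weights, emb, top_k=cfg.top_k, mmr_lambda=cfg.mmr_lambda
        )

    # --- probabilistic reassignment ---
    doc_topics = None
    clusters = clusters_before
    if clusters_before.n_clusters > 0:
        space = reduced if cfg.prm.space == "reduced" else embeddings
        doc_topics = build_doc_topic_matrix(space, clusters_before, cfg.prm)
        if cfg.use_prm:
            clusters, _ = reassign_outliers(clusters_before, doc_topics, cfg.prm)

    report = _evaluate(cfg, clean, embeddings, reduced, clusters_before, clusters,
                       term_weights, keywords, doc_topics)

    result = PipelineResult(
        clean_docs=clean,
        embeddings=embeddings,
        reduced=reduced,
        ddeo=ddeo_result,
        clusters_before=clusters_before,
        clusters=clusters,
        term_weights=term_weights,
        pdr_diagnostics=pdr_diag,
        keywords=keywords,
        doc_topics=doc_topics,
        metrics=report,
        dedup_report=dedup_report,
    )
    if out_dir is not None:
        _write_run(Path(out_dir), cfg, result)
    return result


def _evaluate(
    cfg: RunConfig,
    clean: list[CleanDocument],
    embeddings: EmbeddingMatrix,
    reduced: EmbeddingMatrix,
    before: ClusterResult,
    after: ClusterResult,
    term_weights,
    keywords,
    doc_topics,
) -> MetricsReport:
    """Metric suite for one run.

    Keyword metrics (NPMI, TD, LD) use the pre-reassignment clustering —
    reassignment does not alter keyword lists — while the outlier rate
    reflects the final labels and perplexity uses the probability matrix
    with the final assignments. The cosine-similarity diagnostic re-pools
    document vectors with regularized term weights when the regularizer
    is active, so it can register the reweighting.
    """
    notes: dict[str, Any] = {}
    rate, n_noise, n_docs = outlier_rate(after.labels)
    rate_before, n_noise_before, _ = outlier_rate(before.labels)
    notes["outlier_rate_before"] = rate_before
    notes["n_noise_before"] = n_noise_before

    sil = silhouette(reduced, before.labels)
    if sil is None:
        notes["silhouette"] = "undefined: fewer than 2 clusters"

    npmi_val = td_val = ld_val = cs_val = ppl_val = None
    if keywords:
        word_lists = [rep.words for rep in keywords if rep.words]
        if word_lists:
            npmi_val, coverage = npmi(word_lists, clean)
            notes["npmi_pair_coverage"] = coverage
            td_val = topic_diversity(word_lists)
    if term_weights is not None:
        weights_by_topic = {
            t: term_weights.topic_row(t) for t in term_weights.topics
        }
        ld_val = lexical_diversity(
            weights_by_topic, clean, before.labels, cfg.per_doc_top_m
        )
        cs_vectors = embeddings
        if cfg.use_pdr:
            # PDR-aware pooling: weight each token by its maximal
            # regularized topic weight
            emb = HashEmbedder(dim=cfg.embedder.dim, seed=cfg.embedder.seed)
            global_w = {
                w: float(term_weights.weights[:, j].max())
                for j, w in enumerate(term_weights.vocabulary)
            }
            pooled = np.stack(
                [emb.embed_tokens_weighted(d.tokens, global_w) for d in clean]
            )
            cs_vectors = EmbeddingMatrix(ids=[d.id for d in clean], vectors=pooled)
        cs_val = centroid_cosine(cs_vectors, before.labels)
    if doc_topics is not None:
        ppl_val = perplexity(doc_topics.P, after.labels)

    return MetricsReport(
        npmi=npmi_val,
        topic_diversity=td_val,
        perplexity=ppl_val,
        lexical_diversity=ld_val,
        centroid_cosine=cs_val,
        silhouette=sil,
        outlier_rate=rate,
        n_noise=n_noise,
        n_docs=n_docs,
        n_topics=after.n_clusters,
        top_k=cfg.top_k,
        notes=notes,
    )


def _config_dict(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)


def _write_run(out_dir: Path, cfg: RunConfig, result: PipelineResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stio.write_clean_jsonl(result.clean_docs, out_dir / "clean_docs.jsonl")
    if result.dedup_report:
        stio.write_dedup_report(result.dedup_report, out_dir / "dedup_report.tsv")
    stio.write_labels_tsv(
        result.clusters.ids,
        result.clusters.labels,
        result.clusters.outlier_scores,
        out_dir / "labels.tsv",
    )
    if result.keywords:
        decile_terms: set[str] = set()
        if result.term_weights is not None:
            ranks = frequency_ranks(result.term_weights)
            n_dec = max(1, int(np.ceil(cfg.pdr.decile * len(result.term_weights.vocabulary))))
            decile_terms = {t for t, r in ranks.items() if r <= n_dec}
        stio.write_keywords_tsv(
            result.keywords,
            out_dir / "keywords.tsv",
            decile_terms=decile_terms,
            dictionary_terms=set(cfg.pdr.dictionary),
        )
    if result.doc_topics is not None:
        stio.write_doc_topic_tsv(result.doc_topics, out_dir / "doc_topics.tsv")
    if result.ddeo is not None:
        rows = [
            {
                "dimension": d,
                "silhouette": result.ddeo.scores[d],
                "n_clusters": result.ddeo.n_clusters.get(d, ""),
                "outlier_rate": result.ddeo.outlier_rates.get(d, ""),
            }
            for d in sorted(result.ddeo.scores)
        ]
        pd.DataFrame(rows).to_csv(out_dir / "ddeo_sweep.tsv", sep="\t", index=False)
    stio.write_json(result.metrics.to_dict(), out_dir / "metrics.json")
    stio.write_json(_manifest(cfg), out_dir / "manifest.json")


def _manifest(cfg: RunConfig) -> dict:
    import sklearn
    import scipy

    cfg_json = json.dumps(_config_dict(cfg), sort_keys=True)
    return {
        "config": _config_dict(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "pandas": pd.__version__,
        },
    }


SWEEPABLE_KEYS = ("min_cluster_size", "candidate_dims", "alpha", "threshold")


def run_sweep(
    corpus: str | Path | Sequence[RawDocument],
    cfg: RunConfig,
    grid: dict[str, Sequence],
) -> pd.DataFrame:
    """One pipeline run per grid point over a supported parameter.

    Supported keys: min_cluster_size, candidate_dims, alpha, threshold.
    Returns a table with one row per grid point (topic count, outlier
    rate, and all metrics); rows are independent of evaluation order.
    """
    unknown = set(grid) - set(SWEEPABLE_KEYS)
    if unknown:
        raise ValueError(f"unknown sweep keys: {sorted(unknown)}")
    raw = stio.read_corpus(corpus) if isinstance(corpus, (str, Path)) else list(corpus)

    keys = sorted(grid)
    rows = []
    from itertools import product

    for combo in product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        run_cfg = _apply_grid_point(cfg, point)
        result = run_pipeline(raw, run_cfg)
        row = {**point}
        row["n_topics"] = result.clusters.n_clusters
        row["outlier_rate"] = result.metrics.outlier_rate
        row["outlier_rate_before"] = result.metrics.notes["outlier_rate_before"]
        for name in (
            "npmi",
            "topic_diversity",
            "perplexity",
            "lexical_diversity",
            "centroid_cosine",
            "silhouette",
        ):
            row[name] = getattr(result.metrics, name)
        if result.ddeo is not None:
            row["chosen_dim"] = result.ddeo.chosen_dim
        rows.append(row)
    return pd.DataFrame(rows)


def _apply_grid_point(cfg: RunConfig, point: dict) -> RunConfig:
    out = cfg
    for key, value in point.items():
        if key == "min_cluster_size":
            out = dataclasses.replace(
                out, clustering=dataclasses.replace(out.clustering, min_cluster_size=int(value))
            )
        elif key == "candidate_dims":
            dims = tuple(int(v) for v in (value if isinstance(value, (list, tuple)) else [value]))
            out = dataclasses.replace(
                out, reduction=dataclasses.replace(out.reduction, candidate_dims=dims)
            )
        elif key == "alpha":
            out = dataclasses.replace(out, pdr=dataclasses.replace(out.pdr, alpha=float(value)))
        elif key == "threshold":
            out = dataclasses.replace(out, prm=dataclasses.replace(out.prm, threshold=float(value)))
    return out
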