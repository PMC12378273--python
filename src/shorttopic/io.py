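"""Readers and writers for the pipeline's plain-text formats.

Corpora are read from CSV (columns id,text[,timestamp]) or JSONL (one
object per line with the same keys); run artifacts are written as TSV /
JSON so every output stays diffable and inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .embed import EmbeddingMatrix
from .preprocess import CleanDocument, RawDocument
from .reassign import DocTopicMatrix
from .represent import TopicRepresentation


def read_corpus(path: str | Path) -> list[RawDocument]:
    """Read a corpus from CSV or JSONL (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        docs = []
        with path.open() as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                docs.append(
                    RawDocument(
                        id=str(obj["id"]),
                        text=str(obj.get("text", "")),
                        timestamp=obj.get("timestamp"),
                    )
                )
        return docs
    df = pd.read_csv(path, dtype={"id": str, "text": str}, keep_default_na=False)
    if "id" not in df.columns or "text" not in df.columns:
        raise ValueError(f"{path}: corpus CSV needs 'id' and 'text' columns")
    ts = df["timestamp"] if "timestamp" in df.columns else [None] * len(df)
    return [
        RawDocument(id=str(i), text=str(t), timestamp=s if s else None)
        for i, t, s in zip(df["id"], df["text"], ts)
    ]


def write_corpus_csv(docs: Iterable[RawDocument], path: str | Path) -> None:
    rows = [
        {"id": d.id, "text": d.text, **({"timestamp": d.timestamp} if d.timestamp else {})}
        for d in docs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_clean_jsonl(docs: Iterable[CleanDocument], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for d in docs:
            fh.write(
                json.dumps({"id": d.id, "tokens": list(d.tokens), "text_norm": d.text_norm})
                + "\n"
            )


def read_clean_jsonl(path: str | Path) -> list[CleanDocument]:
    docs = []
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                docs.append(CleanDocument(id=obj["id"], tokens=tuple(obj["tokens"])))
    return docs


def write_dedup_report(
    report: Sequence[tuple[str, str, float]], path: str | Path
) -> None:
    pd.DataFrame(report, columns=["dropped_id", "kept_id", "similarity"]).to_csv(
        path, sep="\t", index=False
    )


def write_labels_tsv(
    ids: Sequence[str],
    labels: Sequence[int],
    outlier_scores: Sequence[float] | None,
    path: str | Path,
) -> None:
    df = pd.DataFrame({"id": ids, "label": labels})
    if outlier_scores is not None:
        df["outlier_score"] = outlier_scores
    df.to_csv(path, sep="\t", index=False)


def write_keywords_tsv(
    reps: Sequence[TopicRepresentation],
    path: str | Path,
    *,
    raw_weights: dict[int, dict[str, float]] | None = None,
    decile_terms: set[str] | None = None,
    dictionary_terms: set[str] | None = None,
) -> None:
    rows = []
    for rep in reps:
        for rank, (term, weight) in enumerate(rep.keywords, start=1):
            flags = []
            if decile_terms and term in decile_terms:
                flags.append("decile")
            if dictionary_terms and term in dictionary_terms:
                flags.append("dictionary")
            rows.append(
                {
                    "topic_id": rep.topic_id,
                    "rank": rank,
                    "term": term,
                    "raw_weight": (raw_weights or {}).get(rep.topic_id, {}).get(term, ""),
                    "pdr_weight": weight,
                    "flags": ",".join(flags),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_doc_topic_tsv(P: DocTopicMatrix, path: str | Path) -> None:
    df = pd.DataFrame(P.P, columns=[f"topic_{t}" for t in P.topics])
    df.insert(0, "id", P.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_embeddings_tsv(m: EmbeddingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.vectors, columns=[f"dim_{i}" for i in range(m.dim)])
    df.insert(0, "id", m.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
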