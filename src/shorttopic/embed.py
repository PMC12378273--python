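"""Document embeddings: mean-pooled token vectors behind pluggable backends.

A document vector is the arithmetic mean of its token vectors. Two
backends provide the token/document vectors:

* ``hash-projection`` — each term is mapped to a deterministic unit-norm
  Gaussian direction seeded from a stable digest of (term, seed). Token
  vectors are i.i.d. on the sphere, so distinct terms are nearly
  orthogonal at moderate dimension and documents sharing tokens have
  higher cosine similarity. Fully offline and reproducible.
* ``pretrained-transformer`` — a sentence-transformer model; the model
  performs its own internal pooling, and only document vectors are
  exposed. Requires the optional ``sentence-transformers`` dependency.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import CleanDocument

logger = logging.getLogger(__name__)

DEFAULT_TRANSFORMER = "paraphrase-multilingual-MiniLM-L12-v2"


@dataclass
class EmbeddingMatrix:
    """Per-document dense vectors, one row per document id."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be N x D with one row per id")
        if self.vectors.shape[1] < 2:
            raise ValueError("embedding dimension must be >= 2")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, doc_id: str) -> np.ndarray:
        return self.vectors[self.ids.index(doc_id)]


@dataclass(frozen=True)
class EmbedderSpec:
    """Backend selection: 'hash-projection' (default) or 'pretrained-transformer'."""

    backend: str = "hash-projection"
    model_name: str = DEFAULT_TRANSFORMER
    dim: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("hash-projection", "pretrained-transformer"):
            raise ValueError(f"unknown embedding backend: {self.backend!r}")
        if self.backend == "hash-projection" and self.dim < 2:
            raise ValueError("hash-projection requires dim >= 2")


def hash_embed_token(term: str, dim: int, seed: int) -> np.ndarray:
    """Deterministic unit-norm Gaussian vector for a term.

    The RNG is seeded from a SHA-256 digest of the term together with
    ``seed``, so the same (term, seed) always yields the same vector and
    different seeds give decorrelated embeddings.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    digest = hashlib.sha256(f"{seed}\x00{term}".encode("utf-8")).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


class HashEmbedder:
    """Mean-of-token-vectors embedder over hashed unit directions."""

    def __init__(self, dim: int = 64, seed: int = 0) -> None:
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def token_vector(self, term: str) -> np.ndarray:
        v = self._cache.get(term)
        if v is None:
            v = hash_embed_token(term, self.dim, self.seed)
            self._cache[term] = v
        return v

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        return np.mean([self.token_vector(t) for t in tokens], axis=0)

    def embed_tokens_weighted(
        self, tokens: Sequence[str], weights: dict[str, float]
    ) -> np.ndarray:
        """Weighted token mean; missing weights default to 1. Used for the
        regularizer-aware cosine-similarity diagnostic."""
        w = np.array([weights.get(t, 1.0) for t in tokens], dtype=float)
        if w.sum() <= 0:
            w = np.ones_like(w)
        mat = np.stack([self.token_vector(t) for t in tokens])
        return (w[:, None] * mat).sum(axis=0) / w.sum()


def embed_documents(
    docs: Sequence[CleanDocument], spec: EmbedderSpec
) -> EmbeddingMatrix:
    """Embed documents under ``spec``; empty documents are dropped with a
    logged warning (zero vectors would break cosine geometry downstream)."""
    nonempty = [d for d in docs if d.tokens]
    skipped = len(docs) - len(nonempty)
    if skipped:
        logger.warning("embed_documents: skipping %d empty documents", skipped)
    if not nonempty:
        raise ValueError("no non-empty documents to embed")

    ids = [d.id for d in nonempty]
    if spec.backend == "hash-projection":
        emb = HashEmbedder(dim=spec.dim, seed=spec.seed)
        vectors = np.stack([emb.embed_tokens(d.tokens) for d in nonempty])
    else:
        vectors = _transformer_embed(nonempty, spec)
    return EmbeddingMatrix(ids=ids, vectors=vectors)


def _transformer_embed(
    docs: Sequence[CleanDocument], spec: EmbedderSpec
) -> np.ndarray:
    try:
        from sentence_transformers import SentenceTransformer
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the pretrained-transformer backend requires the optional "
            "'sentence-transformers' dependency (pip install "
            "shorttopic[transformer]); the hash-projection backend runs "
            "without it"
        ) from exc
    model = SentenceTransformer(spec.model_name)  # pragma: no cover
    return np.asarray(
        model.encode([d.text_norm for d in docs], show_progress_bar=False),
        dtype=float,
    )  # pragma: no cover
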