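"""Cleaning, tokenization and near-duplicate removal for short texts.

Raw social-media posts carry URLs, emoji, user sigils and boilerplate
stopwords that swamp the topical signal in texts of only a few tokens.
This module normalises each post into an ordered token sequence and then
drops near-duplicates (retweet-like copies) by exact hash matching on the
normalised text followed by cosine similarity between document embeddings.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Strings starting with http(s):// or www are treated as links and removed
# wholesale (everything up to the next whitespace).
_URL_RE = re.compile(r"(?:https?://|www\.|www\b)\S*", re.IGNORECASE)

# Fixed emoji code-point ranges: emoticons, misc symbols & pictographs,
# transport & map symbols, regional-indicator flags, supplemental symbols,
# plus the BMP misc-symbol/dingbat blocks commonly used as emoji.
_EMOJI_RE = re.compile(
    "["
    "\U0001F600-\U0001F64F"  # emoticons
    "\U0001F300-\U0001F5FF"  # symbols & pictographs
    "\U0001F680-\U0001F6FF"  # transport & map
    "\U0001F1E6-\U0001F1FF"  # regional indicator flags
    "\U0001F900-\U0001F9FF"  # supplemental symbols & pictographs
    "☀-⛿"          # miscellaneous symbols
    "✀-➿"          # dingbats
    "]+"
)

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)

# Suffixes protected from the plural "-s" stripper.
_PLURAL_PROTECT = ("ss", "us", "is")


def load_default_stopwords() -> frozenset[str]:
    """Return the packaged English stopword list."""
    text = (
        resources.files("shorttopic.data").joinpath("stopwords_en.txt").read_text()
    )
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class RawDocument:
    """A raw short text with an opaque id and optional ISO-8601 timestamp."""

    id: str
    text: str
    timestamp: str | None = None


@dataclass(frozen=True)
class CleanDocument:
    """Tokenized, noise-stripped document.

    ``tokens`` is the ordered lowercase term sequence after URL/emoji
    removal, stopword filtering and optional plural normalisation;
    ``text_norm`` is the space-joined form used for hash deduplication.
    """

    id: str
    tokens: tuple[str, ...]
    text_norm: str = field(default="")

    def __post_init__(self) -> None:
        if not self.text_norm:
            object.__setattr__(self, "text_norm", " ".join(self.tokens))


@dataclass(frozen=True)
class DedupConfig:
    """Near-duplicate removal settings.

    ``epsilon`` is the cosine-similarity threshold: a candidate is retained
    only if its similarity to every already-kept document stays below it.
    """

    epsilon: float = 0.95
    use_hash: bool = True
    use_embedding: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")


def _singularize(token: str) -> str:
    if len(token) > 3 and token.endswith("s") and not token.endswith(_PLURAL_PROTECT):
        return token[:-1]
    return token


def clean_text(
    doc: RawDocument,
    stopwords: frozenset[str] | set[str] | None = None,
    *,
    strip_plural_s: bool = True,
) -> CleanDocument:
    """Normalise a raw post into an ordered, noise-free token sequence.

    Steps: lowercase; drop URLs and emoji; strip leading ``@``/``#`` sigils
    from whitespace chunks; split on non-word characters (underscores kept);
    remove stopwords; optionally strip a plural ``-s`` suffix (protected
    endings: -ss, -us, -is); re-filter stopwords created by stripping.

    The operation is deterministic and idempotent on its own output; empty
    input yields an empty token list.
    """
    if stopwords is None:
        stopwords = load_default_stopwords()
    if not stopwords:
        raise ValueError("stopword set must be non-empty")

    text = doc.text.lower()
    text = _URL_RE.sub(" ", text)
    text = _EMOJI_RE.sub(" ", text)

    tokens: list[str] = []
    for chunk in text.split():
        chunk = chunk.lstrip("@#")
        tokens.extend(_TOKEN_RE.findall(chunk))

    tokens = [t for t in tokens if t not in stopwords]
    if strip_plural_s:
        tokens = [_singularize(t) for t in tokens]
        tokens = [t for t in tokens if t not in stopwords]
    return CleanDocument(id=doc.id, tokens=tuple(tokens))


def clean_corpus(
    docs: Iterable[RawDocument],
    stopwords: frozenset[str] | set[str] | None = None,
    *,
    strip_plural_s: bool = True,
) -> list[CleanDocument]:
    if stopwords is None:
        stopwords = load_default_stopwords()
    return [clean_text(d, stopwords, strip_plural_s=strip_plural_s) for d in docs]


def _text_hash(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def deduplicate(
    docs: Sequence[CleanDocument],
    vectors: "EmbeddingMatrix | None" = None,
    cfg: DedupConfig | None = None,
) -> tuple[list[CleanDocument], list[tuple[str, str, float]]]:
    """Drop near-duplicate documents, keeping the earliest of each group.

    Exact duplicates are found by hashing ``text_norm``; remaining
    candidates are compared by cosine similarity of their embedding rows
    against every already-retained document, and dropped when the
    similarity reaches ``cfg.epsilon``. Returns the retained documents and
    a report of ``(dropped_id, kept_id, similarity)`` rows (similarity 1.0
    for hash matches).
    """
    cfg = cfg or DedupConfig()
    if cfg.use_embedding:
        if vectors is None:
            raise ValueError("embedding deduplication requires vectors")
        row_of = {i: k for k, i in enumerate(vectors.ids)}
        missing = [d.id for d in docs if d.id not in row_of]
        if missing:
            raise ValueError(f"vectors missing ids: {missing[:5]}")

    kept: list[CleanDocument] = []
    kept_rows: list[np.ndarray] = []
    report: list[tuple[str, str, float]] = []
    seen_hash: dict[str, str] = {}

    unit = None
    if cfg.use_embedding:
        mat = np.asarray(vectors.vectors, dtype=float)
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        unit = mat / norms

    for doc in docs:
        if cfg.use_hash:
            h = _text_hash(doc.text_norm)
            if h in seen_hash:
                report.append((doc.id, seen_hash[h], 1.0))
                continue
        if cfg.use_embedding and kept_rows:
            row = unit[row_of[doc.id]]
            sims = np.stack(kept_rows) @ row
            j = int(np.argmax(sims))
            if sims[j] >= cfg.epsilon:
                report.append((doc.id, kept[j].id, float(sims[j])))
                continue
        if cfg.use_hash:
            seen_hash[h] = doc.id
        if cfg.use_embedding:
            kept_rows.append(unit[row_of[doc.id]])
        kept.append(doc)

    if report:
        logger.info("deduplicate: dropped %d of %d documents", len(report), len(docs))
    return kept, report
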