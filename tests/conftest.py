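import numpy as np
import pytest

from shorttopic.embed import EmbeddingMatrix
from shorttopic.preprocess import CleanDocument


@pytest.fixture(scope="session")
def stopwords():
    from shorttopic.preprocess import load_default_stopwords

    return load_default_stopwords()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_docs(token_lists, prefix="d"):
    return [
        CleanDocument(id=f"{prefix}{i}", tokens=tuple(toks))
        for i, toks in enumerate(token_lists)
    ]


def make_matrix(vectors, prefix="d"):
    vectors = np.asarray(vectors, dtype=float)
    return EmbeddingMatrix(
        ids=[f"{prefix}{i}" for i in range(vectors.shape[0])], vectors=vectors
    )


@pytest.fixture
def two_blob_matrix(rng):
    """Two well-separated Gaussian blobs of 150 points each (2-D)."""
    a = rng.normal([0, 0], 1.0, size=(150, 2))
    b = rng.normal([20, 0], 1.0, size=(150, 2))
    x = np.vstack([a, b])
    labels = np.array([0] * 150 + [1] * 150)
    return make_matrix(x), labels
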