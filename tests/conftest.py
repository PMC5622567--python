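import numpy as np
import pytest

from dpl_simplify.embeddings import EmbeddingModel
from dpl_simplify.fixtures import FixtureSpec, make_tagged_corpus, make_world


@pytest.fixture
def toy_model():
    """Tiny 2-d model used across unit tests."""
    return EmbeddingModel(
        2,
        {
            "a": np.array([1.0, 0.0]),
            "b": np.array([0.0, 1.0]),
            "c": np.array([1.0, 1.0]),
            "sueño": np.array([2.0, 0.0]),
            "anormal": np.array([0.0, 2.0]),
        },
    )


@pytest.fixture(scope="session")
def small_world():
    """A 20-target planted world, shared read-only by many tests."""
    return make_world(FixtureSpec(n_targets=20, dimension=16, seed=7))


@pytest.fixture(scope="session")
def corpus_world():
    return make_tagged_corpus(FixtureSpec(n_targets=5, dimension=8, seed=7))


def brute_cosine(v1, v2):
    """Oracle cosine, independent of the package implementation."""
    dot = sum(float(a) * float(b) for a, b in zip(v1, v2))
    n1 = sum(float(a) ** 2 for a in v1) ** 0.5
    n2 = sum(float(b) ** 2 for b in v2) ** 0.5
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return dot / (n1 * n2)
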