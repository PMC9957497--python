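import numpy as np
import pytest

from stsearch import Dataset, EmbeddingTree, STSConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_tree():
    """3-vertex path (0,0)-(1,0)-(1,1)."""
    return EmbeddingTree(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]),
                         ((0, 1), (1, 2)))


@pytest.fixture
def star_tree():
    """4-vertex star centered at the origin."""
    emb = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    return EmbeddingTree(emb, ((0, 1), (0, 2), (0, 3)))


def random_tree(rng, k, p=2):
    """Random embedding tree by sequential uniform attachment."""
    emb = rng.standard_normal((k, p))
    edges = tuple((int(rng.integers(v)), v) for v in range(1, k))
    return EmbeddingTree(emb, edges)


@pytest.fixture
def small_dataset(rng):
    X = rng.standard_normal((30, 2))
    return Dataset.from_array(X)


@pytest.fixture
def fast_config():
    """Config with small pools for quick end-to-end tests."""
    return STSConfig(pool_size_L1=4, grow_repeats_L2=8, seed=11)
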