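import numpy as np
import pytest

from ccinet import SyntheticConfig, generate_dataset, split_edges, train
from ccinet.metrics import evaluate_split


@pytest.fixture(scope="session")
def small_data():
    """Small planted dataset shared across read-only tests."""
    cfg = SyntheticConfig(n_cells=300, seed=0)
    dataset, graph, truth = generate_dataset(cfg)
    return dataset, graph, truth


@pytest.fixture(scope="session")
def trained_small(small_data):
    """A quickly trained model + split on the small dataset (read-only)."""
    dataset, graph, _ = small_data
    split = split_edges(graph, test_fraction=0.1, seed=1)
    model = train(dataset, split, epochs=80, seed=0)
    return model, dataset, split


@pytest.fixture(scope="session")
def random_coords():
    rng = np.random.default_rng(42)
    return rng.uniform(0, 50, size=(100, 2))
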