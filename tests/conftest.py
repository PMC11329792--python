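import numpy as np
import pytest

from sfgrad.atlas import Parcel, ParcelAtlas
from sfgrad.matrix import ConnectivityMatrix
from sfgrad.structural import build_sc_stack
from sfgrad.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def toy_atlas():
    """Three parcels with simple integer geometry."""
    return ParcelAtlas(
        [
            Parcel(0, "a", "front", (0.0, 0.0, 0.0), 8.0),
            Parcel(1, "b", "front", (3.0, 4.0, 0.0), 2.0),
            Parcel(2, "c", "back", (0.0, 0.0, 10.0), 4.0),
        ]
    )


def random_connected_graph(rng, n=None):
    """Random connected weighted graph as a ConnectivityMatrix.

    A random spanning tree guarantees connectivity; extra edges are added at
    random with positive weights.
    """
    n = n or int(rng.integers(5, 9))
    w = np.zeros((n, n))
    order = rng.permutation(n)
    for i in range(1, n):
        a, b = order[i], order[int(rng.integers(0, i))]
        w[a, b] = w[b, a] = rng.uniform(0.5, 3.0)
    extra = rng.random((n, n)) < 0.35
    for i in range(n):
        for j in range(i + 1, n):
            if extra[i, j] and w[i, j] == 0:
                w[i, j] = w[j, i] = rng.uniform(0.5, 3.0)
    return ConnectivityMatrix(w)


@pytest.fixture
def graph_factory():
    return random_connected_graph


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset (canonical seed)."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_stack(default_dataset):
    ds = default_dataset
    return build_sc_stack(ds.subject_counts, ds.subject_lengths, ds.atlas)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-size dataset for fast pipeline wiring tests."""
    return generate_dataset(SyntheticConfig(seed=11, n_parcels=40, n_subjects=10, n_terms=24))
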