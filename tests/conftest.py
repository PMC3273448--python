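import numpy as np
import pytest

from arealvar import AdjacencyStructure, ArealCounts, grid_adjacency


@pytest.fixture
def grid3x3():
    return grid_adjacency(3, 3)


@pytest.fixture
def path3():
    """Path graph A - B - C."""
    return AdjacencyStructure.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])


def _random_counts(rng, n=12, mean_e=40.0):
    """Small random areal dataset with positive expecteds."""
    N = rng.uniform(200, 2000, size=n)
    e = mean_e * N / N.mean()
    o = rng.poisson(e * rng.lognormal(0, 0.3, size=n))
    return ArealCounts([f"a{i}" for i in range(n)], o, N, e)


@pytest.fixture
def random_counts():
    """Factory fixture: random_counts(rng, n=..., mean_e=...)."""
    return _random_counts


@pytest.fixture
def counts_rng():
    return np.random.default_rng(42)
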