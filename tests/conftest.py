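import numpy as np
import pytest

from cascadyn import (
    ReducedAdjacency,
    build_empirical_adjacency,
    load_taxonomy,
    parse_case_file,
)


@pytest.fixture(scope="session")
def registry():
    return load_taxonomy()


@pytest.fixture(scope="session")
def cases(registry):
    return parse_case_file(registry=registry)


@pytest.fixture(scope="session")
def empirical(cases, registry):
    """Empirical 19×19 adjacency from the packaged transcription at p=0.1."""
    return build_empirical_adjacency(cases, registry, p=0.1)


@pytest.fixture
def two_cycle():
    """Two perils triggering each other with p=0.1."""
    return ReducedAdjacency(("X", "Y"), [[0.0, 0.1], [0.1, 0.0]])


@pytest.fixture
def chain3():
    """Nilpotent 3-chain A→B→C with p=0.1 on each edge."""
    values = np.zeros((3, 3))
    values[0, 1] = values[1, 2] = 0.1
    return ReducedAdjacency(("A", "B", "C"), values)


@pytest.fixture
def diagonal3():
    """Three independent self-triggering perils with p=0.1."""
    return ReducedAdjacency(("A", "B", "C"), np.eye(3) * 0.1)


def random_substochastic(rng, n, max_row_sum=0.9):
    """Random n×n matrix with every row sum ≤ max_row_sum."""
    values = rng.random((n, n))
    sums = values.sum(axis=1, keepdims=True)
    scale = rng.uniform(0.1, max_row_sum, size=(n, 1))
    return values / sums * scale
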