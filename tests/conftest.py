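import numpy as np
import pytest

from repowalk import AssociationNetwork, WalkConfig, simulate_fixture
from repowalk.heterograph import build_transition
from repowalk.similarity import disease_similarity, drug_similarity


@pytest.fixture
def small_fixture():
    """Planted-block fixture small enough for exhaustive checks."""
    return simulate_fixture(20, 15, 2, 0.6, 0.05, 64, 0.1, seed=7)


@pytest.fixture
def small_transition(small_fixture):
    net, fp, cv = small_fixture
    return build_transition(
        drug_similarity(net, fp), disease_similarity(net, cv), net, 0.8
    )


@pytest.fixture
def walk_config():
    return WalkConfig()


def random_network(rng, n_drugs=None, n_diseases=None, density=0.2):
    """A random bipartite association network with at least one edge."""
    n = n_drugs or int(rng.integers(2, 12))
    m = n_diseases or int(rng.integers(2, 12))
    a = (rng.random((n, m)) < density).astype(np.int8)
    if not a.any():
        a[rng.integers(n), rng.integers(m)] = 1
    return AssociationNetwork(
        tuple(f"c{i}" for i in range(n)), tuple(f"d{j}" for j in range(m)), a
    )


def random_transition(rng, max_nodes=60):
    """A transition matrix built from a random planted fixture."""
    n = int(rng.integers(4, max_nodes // 2))
    m = int(rng.integers(4, max_nodes // 2))
    blocks = int(rng.integers(1, min(n, m, 4) + 1))
    net, fp, cv = simulate_fixture(
        n, m, blocks, 0.5, 0.05, 32, 0.1, seed=int(rng.integers(2**31))
    )
    T = build_transition(
        drug_similarity(net, fp),
        disease_similarity(net, cv),
        net,
        float(rng.uniform(0, 1)),
    )
    return net, T
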