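import numpy as np
import pytest

import minnetrank as m


@pytest.fixture
def triangle_net():
    """The 3-gene worked example: edges g1->g2, g2->g1, g1->g3."""
    return m.InteractionNetwork.from_edges([("g1", "g2"), ("g2", "g1"), ("g1", "g3")])


@pytest.fixture
def mutual_pair():
    return m.InteractionNetwork.from_edges([("g1", "g2"), ("g2", "g1")])


@pytest.fixture(scope="session")
def fixture7():
    """Default planted-driver cohort, seed 7, shared across the session."""
    return m.default_fixture(7)


@pytest.fixture(scope="session")
def diffusion7(fixture7):
    return m.build_diffusion(fixture7.network, 0.48)


def random_directed_net(rng: np.random.Generator, n: int) -> m.InteractionNetwork:
    """Random directed graph with no isolated nodes (for property tests)."""
    genes = [f"n{i:02d}" for i in range(n)]
    edges = set()
    for i in range(n):  # guarantee every gene touches an edge
        j = (i + 1 + rng.integers(n - 1)) % n
        edges.add((genes[i], genes[j]))
    n_extra = int(rng.integers(n, 3 * n))
    for _ in range(n_extra):
        i, j = rng.choice(n, size=2, replace=False)
        edges.add((genes[i], genes[j]))
    return m.InteractionNetwork.from_edges(edges)
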