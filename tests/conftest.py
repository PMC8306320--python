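import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rivernet.io import AbundanceMatrix, CoNetwork
from rivernet.synth import PlantedDesign, generate_planted_counts


@pytest.fixture
def toy_matrix() -> AbundanceMatrix:
    counts = pd.DataFrame(
        [[10, 0, 5], [3, 7, 0], [1, 1, 8]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C"],
    )
    return AbundanceMatrix(counts)


@pytest.fixture(scope="session")
def planted_matrix() -> AbundanceMatrix:
    """Default planted-block community: 2 blocks of 10 taxa at rho 0.9."""
    return generate_planted_counts(PlantedDesign(seed=0))


@pytest.fixture
def triangle_net() -> CoNetwork:
    g = nx.Graph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
        g.add_edge(u, v, sign=1, correlation=0.9, support=2, q_value=0.01)
    return CoNetwork(g)


@pytest.fixture
def two_triangles() -> CoNetwork:
    g = nx.Graph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]:
        g.add_edge(u, v, sign=1, correlation=0.9, support=2, q_value=0.01)
    return CoNetwork(g)


def random_signed_network(n_nodes: int, p: float, seed: int) -> CoNetwork:
    """Random graph with signs/correlations, no isolated nodes guaranteed."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    out = nx.Graph()
    for u, v in g.edges:
        r = rng.uniform(0.8, 1.0) * rng.choice([-1, 1])
        out.add_edge(f"n{u}", f"n{v}", sign=int(np.sign(r)), correlation=float(r),
                     support=2, q_value=float(rng.uniform(0, 0.05)))
    return CoNetwork(out)
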