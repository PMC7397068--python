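import numpy as np
import pandas as pd
import pytest

from heatnet.diffusion import PPINetwork
from heatnet.simulate import SimulationScenario, generate_agent_library


@pytest.fixture
def two_node_net():
    return PPINetwork.from_edges([("a", "b")])


@pytest.fixture
def path_net():
    # a - b - c
    return PPINetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def small_library():
    """150-gene, 3-agent library: one sharer (6 genes), one disjoint agent."""
    scenario = SimulationScenario(
        n_genes=150, k_module=10, n_agents=3, overlaps=[6, 0],
        n_decoy_sets=10, seed=11)
    return generate_agent_library(scenario)


@pytest.fixture
def probe_scores():
    return pd.Series([0.5, 1.2, -1.5, 0.7, 0.0],
                     index=["p1", "p2", "p3", "p4", "p5"])


def random_connected_graph(rng: np.random.Generator, n: int) -> PPINetwork:
    """Random tree plus extra edges: connected, simple, no self-loops."""
    edges = []
    for v in range(1, n):
        edges.append((f"n{int(rng.integers(0, v))}", f"n{v}"))
    for _ in range(n):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            edges.append((f"n{u}", f"n{v}"))
    return PPINetwork.from_edges(edges)
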