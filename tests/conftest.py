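import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from minidriver import ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression():
    """4 genes x 6 samples with 3 normal / 3 tumour columns."""
    data = pd.DataFrame(
        np.arange(24, dtype=float).reshape(4, 6),
        index=["G1", "G2", "G3", "G4"],
        columns=[f"S{i}" for i in range(6)],
    )
    condition = pd.Series(
        ["normal"] * 3 + ["tumour"] * 3, index=data.columns
    )
    return ExpressionMatrix(data, condition)


@pytest.fixture
def twin_cliques():
    """Two disjoint K4s: the canonical Q = 0.5 benchmark graph."""
    g = nx.Graph()
    g.add_edges_from(
        [(a, b) for a, b in nx.complete_graph(["a1", "a2", "a3", "a4"]).edges]
    )
    g.add_edges_from(
        [(a, b) for a, b in nx.complete_graph(["b1", "b2", "b3", "b4"]).edges]
    )
    return g


def random_graph(seed: int, n_max: int = 50) -> nx.Graph:
    """Seeded Erdos-Renyi graph with at least one edge."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.08, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    if g.number_of_edges() == 0:
        g.add_edge(0, 1)
    return g
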