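import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_expression(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


def two_block_graph(
    block_size: int = 20, p_within: float = 0.3, n_cross: int = 4, seed: int = 7
) -> nx.Graph:
    """Planted two-community graph: dense blocks, a few cross-block edges."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(2 * block_size))
    for offset in (0, block_size):
        for i in range(offset, offset + block_size):
            for j in range(i + 1, offset + block_size):
                if rng.random() < p_within:
                    g.add_edge(i, j)
    added = 0
    while added < n_cross:
        u = int(rng.integers(0, block_size))
        v = int(rng.integers(block_size, 2 * block_size))
        if not g.has_edge(u, v):
            g.add_edge(u, v)
            added += 1
    return g


@pytest.fixture
def toy_gene_matrix() -> pd.DataFrame:
    """Small gene-level matrix with clear correlation structure."""
    rng = np.random.default_rng(0)
    base = rng.normal(size=12)
    rows = {
        "IGF2": base + rng.normal(scale=0.05, size=12),
        "DLK1": base + rng.normal(scale=0.05, size=12),
        "MEG3": -base + rng.normal(scale=0.05, size=12),
        "OTHER": rng.normal(size=12),
    }
    return pd.DataFrame(rows).T
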