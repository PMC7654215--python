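import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cpnet.config import SyntheticConfig
from cpnet.netio import InteractionTable


@pytest.fixture
def small_cfg():
    """Desk-scale synthetic universe for fast unit tests."""
    return SyntheticConfig(
        seed=11,
        n_genes=120,
        n_replicates=4,
        frac_expressed=0.1,
        n_proteins=80,
        planted_module_size=5,
        module_spokes=10,
        targets_per_chemical=6,
        n_patients=150,
        n_nuclei=100,
    )


@pytest.fixture
def random_edge_table():
    """Seeded random unit-dialect edge table over 25 proteins."""
    rng = np.random.default_rng(42)
    nodes = [f"P{i:02d}" for i in range(25)]
    rows = set()
    while len(rows) < 60:
        a, b = rng.choice(25, size=2, replace=False)
        rows.add((min(a, b), max(a, b)))
    df = pd.DataFrame(
        [
            {"node_a": nodes[a], "node_b": nodes[b],
             "confidence": float(rng.uniform(0.05, 0.99))}
            for a, b in sorted(rows)
        ]
    )
    return InteractionTable(df)


def random_graph(rng, n_max=30, p=0.15):
    """Seeded Erdos-Renyi graph with string node labels."""
    n = int(rng.integers(5, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
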