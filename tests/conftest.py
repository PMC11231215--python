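import itertools

import numpy as np
import pandas as pd
import pytest

from coexnet.mi_network import WeightedNetwork
from coexnet.pipeline import RunConfig, run_all


def make_network(rows, phenotype=""):
    """Edge-list helper: rows of (a, b) or (a, b, w)."""
    rows = [r if len(r) == 3 else (*r, 1.0) for r in rows]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi"])
    return WeightedNetwork(edges=df, phenotype=phenotype, k_retained=len(df))


def clique(prefix, size, weight=1.0):
    return [
        (f"{prefix}{i}", f"{prefix}{j}", weight)
        for i, j in itertools.combinations(range(size), 2)
    ]


@pytest.fixture(scope="session")
def two_triangles():
    return make_network(clique("a", 3) + clique("b", 3))


@pytest.fixture(scope="session")
def benchmark_report():
    """One full default-configuration run on the benchmark design, shared
    across the tests that interrogate end-to-end behavior."""
    return run_all(RunConfig(synthetic="benchmark", seed=1))


@pytest.fixture(scope="session")
def small_report():
    """Full run on the reduced 3-phenotype design (fast)."""
    return run_all(RunConfig(synthetic="small", seed=3, top_k=700, n_trials=5))


def random_weighted_network(n_nodes, p_edge, rng, weights=True):
    rows = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            w = rng.uniform(0.2, 2.0) if weights else 1.0
            rows.append((f"n{i:02d}", f"n{j:02d}", w))
    if not rows:  # guarantee at least one edge
        rows.append(("n00", "n01", 1.0))
    return make_network(rows)


def planted_partition_network(rng, n_blocks=4, block_size=25, p_in=0.3, p_out=0.01):
    """Unweighted planted-partition graph; block of node i is i // block_size."""
    n = n_blocks * block_size
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if i // block_size == j // block_size else p_out
            if rng.random() < p:
                rows.append((f"n{i:03d}", f"n{j:03d}", 1.0))
    return make_network(rows)
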