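import numpy as np
import pytest

from level2ppi import SimConfig, simulate, toy_network

# The planted-module configuration used by the cross-validation and
# recovery tests: 500 background genes at density 0.01, 20 seeds, 15 hubs,
# 30 level-2-only true candidates attached to hubs with probability 0.6.
PLANTED_CONFIG = SimConfig(
    n_background=500,
    edge_prob=0.01,
    n_seeds=20,
    n_hubs=15,
    n_true_candidates=30,
    attach_prob=0.6,
    rng_seed=7,
)

# A dense uniform random graph whose "seeds" are statistically identical to
# the other genes: the null case for the cross-validation ratio.
NULL_CONFIG = SimConfig(
    n_background=300,
    edge_prob=0.1,
    n_seeds=30,
    n_hubs=0,
    n_true_candidates=0,
    attach_prob=0.0,
    seed_edge_prob=0.1,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def planted_truth():
    return simulate(PLANTED_CONFIG)


@pytest.fixture(scope="session")
def null_truth():
    return simulate(NULL_CONFIG)


@pytest.fixture()
def toy():
    """(network, seeds) of the six-gene worked example."""
    return toy_network()


def random_graph_adjacency(rng: np.random.Generator, max_nodes: int = 100):
    """An independent random graph as (edge list, adjacency dict).

    The adjacency dict is built by plain set insertion, independent of the
    package's graph container, and serves as the brute-force oracle
    substrate.
    """
    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.02, 0.25))
    nodes = [f"N{i}" for i in range(n)]
    edges = []
    adj = {v: set() for v in nodes}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j]))
                adj[nodes[i]].add(nodes[j])
                adj[nodes[j]].add(nodes[i])
    return nodes, edges, adj


def brute_direct(gene, seeds, adj):
    """Oracle: count seeds adjacent to gene, excluding gene itself."""
    return sum(1 for s in set(seeds) - {gene} if s in adj.get(gene, ()))


def brute_indirect(gene, seeds, adj):
    """Oracle: enumerate length-2 paths gene-x-s over all (seed, x) pairs."""
    count = 0
    for s in set(seeds) - {gene}:
        for x in adj.get(gene, ()):
            if x != s and x != gene and s in adj.get(x, ()):
                count += 1
    return count
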