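import networkx as nx
import numpy as np
import pytest

from seedbench import build_fixture, detect_communities, grow_network
from seedbench.netgen import GenerationParams


@pytest.fixture(scope="session")
def small_growth_graph():
    """One sparse high-clustering growth network reused across tests."""
    return grow_network(GenerationParams(200, 2, 0.5, rng_seed=1))


@pytest.fixture(scope="session")
def small_growth_partition(small_growth_graph):
    return detect_communities(small_growth_graph, rng_seed=0)


@pytest.fixture(scope="session")
def tiny_connected_graphs():
    """A mixed bag of connected graphs with at most 8 nodes (exhaustive oracles)."""
    graphs = [
        build_fixture("dyad"),
        build_fixture("path", 5),
        build_fixture("star", 5),
        build_fixture("cycle", 6),
        build_fixture("two_cliques_bridge", 4),
        build_fixture("grid", 2, 4),
        nx.complete_graph(6),
    ]
    rng = np.random.default_rng(7)
    while len(graphs) < 15:
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            graphs.append(g)
    return graphs


def bfs_distances(g, sources):
    """Hand-rolled multi-source BFS used as an independent distance oracle."""
    dist = {v: None for v in g.nodes()}
    frontier = list(sources)
    for v in frontier:
        dist[v] = 0
    d = 0
    while frontier:
        d += 1
        nxt = []
        for v in frontier:
            for u in g[v]:
                if dist[u] is None:
                    dist[u] = d
                    nxt.append(u)
        frontier = nxt
    return dist
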