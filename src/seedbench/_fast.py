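"""C-accelerated graph primitives.

networkx is the package's in-memory container, but a handful of whole-graph
computations (betweenness, closeness, local clustering, shortest-path summaries)
are quadratic-or-worse and dominate run time on the Large batches.  They are
routed through python-igraph here; every function takes and returns plain
Python/networkx objects so callers never see igraph.
"""

from __future__ import annotations

import igraph
import networkx as nx

__all__ = [
    "node_order",
    "to_igraph",
    "mean_clustering",
    "betweenness",
    "closeness",
    "distance_stats",
]


def node_order(g: nx.Graph) -> list:
    """Stable node order used for all igraph round-trips."""
    return sorted(g.nodes())


def to_igraph(g: nx.Graph) -> tuple[igraph.Graph, list]:
    """Convert to igraph; returns (graph, node list) with igraph id = position."""
    nodes = node_order(g)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    return igraph.Graph(n=len(nodes), edges=edges), nodes


def mean_clustering(g: nx.Graph) -> float:
    """Mean local clustering coefficient; degree<2 nodes count as 0."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    ig, _ = to_igraph(g)
    return float(ig.transitivity_avglocal_undirected(mode="zero"))


def betweenness(g: nx.Graph) -> dict:
    """Exact (unnormalised) betweenness centrality per node."""
    ig, nodes = to_igraph(g)
    return dict(zip(nodes, ig.betweenness()))


def closeness(g: nx.Graph) -> dict:
    """Closeness centrality per node (on a connected graph)."""
    ig, nodes = to_igraph(g)
    return dict(zip(nodes, ig.closeness()))


def distance_stats(g: nx.Graph) -> tuple[int, float]:
    """(diameter, mean shortest path length) of a connected graph."""
    ig, nodes = to_igraph(g)
    if len(nodes) == 1:
        return 0, 0.0
    return int(ig.diameter(unconn=False)), float(ig.average_path_length(unconn=False))
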