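"""Community detection and modularity.

Decentralized seeding needs a node → community map; it comes from Louvain
modularity maximisation (resolution 1) with a seeded node-visit order, run once
per network and cached by callers.  The Newman–Girvan modularity

    Q = sum_c [ e_c / Ne - (d_c / (2 Ne))^2 ]

(e_c intra-community edges, d_c total degree inside community c) is implemented
directly here rather than delegated, so it can serve as an independent check of
whatever backs the detector.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import networkx as nx
from networkx.algorithms.community import louvain_communities

from .errors import ParameterError

__all__ = ["Partition", "detect_communities", "modularity", "community_sizes_sorted"]


@dataclass(frozen=True)
class Partition:
    """A hard partition of the node set; community ids are 0..Nc-1."""

    assignment: Mapping
    n_communities: int
    modularity: float
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "assignment", MappingProxyType(dict(self.assignment)))
        ids = set(self.assignment.values())
        if ids != set(range(self.n_communities)):
            raise ParameterError("community ids must be 0..Nc-1 without gaps")

    def community(self, cid: int) -> list:
        return [v for v, c in self.assignment.items() if c == cid]

    def sizes(self) -> dict:
        return dict(Counter(self.assignment.values()))


def modularity(g: nx.Graph, assignment: Mapping) -> float:
    """Newman–Girvan modularity of a node → community assignment."""
    ne = g.number_of_edges()
    if ne == 0:
        raise ParameterError("modularity needs a graph with at least one edge")
    missing = [v for v in g.nodes() if v not in assignment]
    if missing:
        raise ParameterError(f"assignment missing nodes, e.g. {missing[:3]}")
    intra: Counter = Counter()
    degree_sum: Counter = Counter()
    for u, v in g.edges():
        if assignment[u] == assignment[v]:
            intra[assignment[u]] += 1
    for v, d in g.degree():
        degree_sum[assignment[v]] += d
    communities = set(assignment[v] for v in g.nodes())
    return float(
        sum(intra[c] / ne - (degree_sum[c] / (2.0 * ne)) ** 2 for c in communities)
    )


def detect_communities(g: nx.Graph, rng_seed: int = 0) -> Partition:
    """Louvain partition with a seeded visit order; deterministic per seed.

    An edgeless graph degenerates to one singleton community per node (Q = 0
    by convention, since modularity is undefined without edges).
    """
    if g.number_of_nodes() == 0:
        raise ParameterError("empty graph")
    if g.number_of_edges() == 0:
        assignment = {v: i for i, v in enumerate(sorted(g.nodes()))}
        return Partition(assignment, len(assignment), 0.0, rng_seed)
    communities = louvain_communities(g, resolution=1.0, seed=rng_seed)
    # Deterministic relabelling: larger communities first, ties by smallest node.
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = {v: cid for cid, nodes in enumerate(ordered) for v in nodes}
    return Partition(assignment, len(ordered), modularity(g, assignment), rng_seed)


def community_sizes_sorted(p: Partition) -> list[tuple[int, int]]:
    """(community id, size) pairs, descending by size, ties by ascending id."""
    sizes = p.sizes()
    return sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))
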