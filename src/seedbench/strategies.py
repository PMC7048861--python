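"""Seed-node selection strategies.

Ten strategies produce ordered seed sets of a fixed size s.  Five are
centralized (a global per-node score, take the top s): degree, betweenness,
closeness, PageRank, and k-core membership.  Four are decentralized (they
spread seeds across network regions): Vote-Rank, Ambassadors (highest external
degree per community), Community Hubs (highest internal degree per community)
and Random Hubs (highest-degree neighbour of random nodes).  The tenth is a
uniform random draw, the baseline every other strategy is benchmarked against.

Score ties are broken by a seeded uniform draw within the tied block, so
selection is deterministic given ``rng_seed`` while not privileging node ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from ._fast import betweenness as _betweenness
from ._fast import closeness as _closeness
from .community import Partition, community_sizes_sorted
from .errors import StrategyError

__all__ = [
    "SeedSet",
    "VoteRankState",
    "CENTRALIZED_STRATEGIES",
    "DECENTRALIZED_STRATEGIES",
    "ALL_STRATEGIES",
    "select_seeds",
    "external_internal_degree",
    "voterank_trace",
]

CENTRALIZED_STRATEGIES = ("degree", "betweenness", "closeness", "pagerank", "kcore")
DECENTRALIZED_STRATEGIES = ("voterank", "ambassadors", "community_hubs", "random_hubs")
ALL_STRATEGIES = CENTRALIZED_STRATEGIES + DECENTRALIZED_STRATEGIES + ("random",)

#: PageRank damping and convergence tolerance (standard values).
PAGERANK_ALPHA = 0.85
PAGERANK_TOL = 1e-9


@dataclass(frozen=True)
class SeedSet:
    """An ordered set of s distinct seed nodes produced by one strategy."""

    strategy: str
    nodes: tuple
    s: int

    def __post_init__(self):
        if len(self.nodes) != self.s or len(set(self.nodes)) != self.s:
            raise StrategyError(
                f"{self.strategy}: expected {self.s} distinct nodes, got {self.nodes}"
            )

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self):
        return self.s


@dataclass
class VoteRankState:
    """Mutable Vote-Rank bookkeeping: per-node voting ability and picks so far."""

    voting_ability: dict
    selected: list


def _top_by_score(scores: Mapping, s: int, rng: np.random.Generator) -> list:
    """Top-s keys by score, ties resolved by a seeded uniform draw."""
    keys = sorted(scores)
    jitter = dict(zip(keys, rng.random(len(keys))))
    return sorted(keys, key=lambda v: (-scores[v], jitter[v]))[:s]


def external_internal_degree(g: nx.Graph, partition: Partition, v) -> tuple[int, int]:
    """(external, internal) degree of v w.r.t. its community; sums to degree(v)."""
    own = partition.assignment[v]
    external = sum(1 for u in g[v] if partition.assignment[u] != own)
    return external, g.degree(v) - external


def _voterank_step(g: nx.Graph, state: VoteRankState, inv_mean_degree: float,
                   rng: np.random.Generator) -> tuple:
    chosen = set(state.selected)
    scores = {
        v: sum(state.voting_ability[u] for u in g[v])
        for v in g.nodes()
        if v not in chosen
    }
    pick = _top_by_score(scores, 1, rng)[0]
    score = scores[pick]
    state.selected.append(pick)
    state.voting_ability[pick] = 0.0
    for u in g[pick]:
        state.voting_ability[u] = max(0.0, state.voting_ability[u] - inv_mean_degree)
    return pick, score


def voterank_trace(g: nx.Graph, s: int, rng_seed: int = 0) -> list[tuple]:
    """Vote-Rank selection trace: [(node, voting score at selection), ...].

    Every node starts with voting ability 1; a node's score is the sum of its
    neighbours' abilities, so the first pick is always a maximum-degree node.
    Selecting a node zeroes its ability, removes it from future candidacy, and
    lowers each neighbour's ability by 1/<k> (floored at 0), with <k> the mean
    degree of the graph, fixed at its initial value.
    """
    if not 1 <= s <= g.number_of_nodes():
        raise StrategyError(f"s={s} outside [1, {g.number_of_nodes()}]")
    rng = np.random.default_rng(rng_seed)
    mean_degree = 2.0 * g.number_of_edges() / g.number_of_nodes()
    decrement = 1.0 / mean_degree if mean_degree > 0 else 0.0
    state = VoteRankState(dict.fromkeys(g.nodes(), 1.0), [])
    return [_voterank_step(g, state, decrement, rng) for _ in range(s)]


def _kcore_seeds(g: nx.Graph, s: int, rng: np.random.Generator) -> list:
    """s nodes drawn uniformly from the maximal k-core, topping up from the
    (k-1)-core and below when a shell is too small."""
    core = nx.core_number(g)
    picked: list = []
    for k in sorted(set(core.values()), reverse=True):
        shell = sorted(v for v in core if core[v] == k)
        take = min(s - len(picked), len(shell))
        if take > 0:
            idx = rng.choice(len(shell), size=take, replace=False)
            picked.extend(shell[i] for i in idx)
        if len(picked) == s:
            break
    return picked


def _community_cycle(
    g: nx.Graph, partition: Partition, s: int, rng: np.random.Generator, internal: bool
) -> list:
    """Cycle through communities (largest first), picking per community the
    unselected member with the highest internal (Community Hubs) or external
    (Ambassadors) degree; exhausted communities are skipped."""
    order = [cid for cid, _ in community_sizes_sorted(partition)]
    members = {cid: partition.community(cid) for cid in order}
    selected: list = []
    chosen = set()
    while len(selected) < s:
        progressed = False
        for cid in order:
            if len(selected) >= s:
                break
            pool = [v for v in members[cid] if v not in chosen]
            if not pool:
                continue
            scores = {}
            for v in pool:
                ext, internal_deg = external_internal_degree(g, partition, v)
                scores[v] = internal_deg if internal else ext
            pick = _top_by_score(scores, 1, rng)[0]
            selected.append(pick)
            chosen.add(pick)
            progressed = True
        if not progressed:
            raise StrategyError(f"cannot select {s} nodes: communities exhausted")
    return selected


def _random_hubs(g: nx.Graph, s: int, rng: np.random.Generator) -> list:
    nodes = sorted(g.nodes())
    selected: list = []
    chosen = set()
    for _ in range(50 * s):
        if len(selected) == s:
            break
        v = nodes[rng.integers(len(nodes))]
        nbrs = list(g[v])
        if not nbrs:
            continue
        hub = _top_by_score({u: g.degree(u) for u in nbrs}, 1, rng)[0]
        if hub not in chosen:
            selected.append(hub)
            chosen.add(hub)
    if len(selected) < s:
        raise StrategyError(f"random_hubs found only {len(selected)} of {s} hubs")
    return selected


def select_seeds(
    g: nx.Graph,
    strategy: str,
    s: int,
    partition: Partition | None = None,
    rng_seed: int = 0,
) -> SeedSet:
    """Select s seed nodes by a named strategy; deterministic given rng_seed.

    ``partition`` is required for ambassadors and community_hubs.  Centrality
    scores are computed on the graph as given; callers are expected to pass the
    largest connected component.
    """
    if strategy not in ALL_STRATEGIES:
        raise StrategyError(f"unknown strategy {strategy!r}; valid: {ALL_STRATEGIES}")
    n = g.number_of_nodes()
    if not 1 <= s <= n:
        raise StrategyError(f"s={s} outside [1, {n}]")
    rng = np.random.default_rng(rng_seed)

    if strategy == "degree":
        nodes = _top_by_score(dict(g.degree()), s, rng)
    elif strategy == "betweenness":
        nodes = _top_by_score(_betweenness(g), s, rng)
    elif strategy == "closeness":
        nodes = _top_by_score(_closeness(g), s, rng)
    elif strategy == "pagerank":
        pr = nx.pagerank(g, alpha=PAGERANK_ALPHA, tol=PAGERANK_TOL, max_iter=1000)
        nodes = _top_by_score(pr, s, rng)
    elif strategy == "kcore":
        nodes = _kcore_seeds(g, s, rng)
    elif strategy == "voterank":
        nodes = [v for v, _ in voterank_trace(g, s, rng_seed=rng_seed)]
    elif strategy in ("ambassadors", "community_hubs"):
        if partition is None:
            raise StrategyError(f"{strategy} requires a community partition")
        nodes = _community_cycle(g, partition, s, rng, internal=strategy == "community_hubs")
    elif strategy == "random_hubs":
        nodes = _random_hubs(g, s, rng)
    else:  # random
        all_nodes = sorted(g.nodes())
        idx = rng.choice(n, size=s, replace=False)
        nodes = [all_nodes[i] for i in idx]

    return SeedSet(strategy=strategy, nodes=tuple(nodes), s=s)


def seed_count_from_proportion(n_lcc: int, proportion: float) -> int:
    """Seed-set size for loaded networks: round-half-up of p * N_LCC, min 1."""
    return max(1, int(np.floor(proportion * n_lcc + 0.5)))
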