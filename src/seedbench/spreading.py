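"""Cascade susceptible-infected (SI) dynamics.

Interaction-driven SI on an undirected network: at every discrete time step,
each susceptible node picks exactly one of its neighbours uniformly at random;
if that neighbour is infected, the node becomes infected with probability g
(else nothing happens).  Updates are synchronous — all draws in a step see the
infection state at the start of the step, and new infections become infectious
in the next step.  Infected nodes never recover.

Note the dilution this interaction rule implies: a susceptible node with k
neighbours of which i are infected is infected with probability g * i / k per
step, so even at g = 1 the front advances stochastically (a node surrounded by
susceptibles mostly "wastes" its interaction) and the time to full coverage is
bounded below by, but generally exceeds, the largest BFS distance to the seed
set.  The bound is attained when every susceptible node's neighbourhood fills
up as the front arrives (e.g. a star seeded at the hub).

Spreading efficiency of a seed set is the number of steps until every node of
the (connected) network is infected — smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ParameterError, UnreachedError
from .strategies import SeedSet

__all__ = ["SIParams", "SpreadingResult", "run_si", "spreading_efficiency"]

#: Termination guard for tiny contagion probabilities.
DEFAULT_MAX_STEPS = 1_000_000


@dataclass(frozen=True)
class SIParams:
    """g: per-interaction infection probability in (0, 1]; max_steps: guard."""

    g: float
    max_steps: int = DEFAULT_MAX_STEPS
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.g <= 1.0:
            raise ParameterError(f"g must be in (0, 1], got {self.g}")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be >= 1")


@dataclass(frozen=True)
class SpreadingResult:
    """Per-step infected counts (t=0 first) and the time to full coverage."""

    infected_count_by_step: tuple
    time_to_full: int | None
    seeds: SeedSet
    n_nodes: int

    @property
    def reached(self) -> bool:
        return self.time_to_full is not None


def run_si(g_network: nx.Graph, seeds: SeedSet, params: SIParams) -> SpreadingResult:
    """Run one SI cascade from a seed set until full coverage or max_steps.

    The network must be connected (run on the largest connected component);
    all seeds must be nodes of the network.
    """
    nodes = sorted(g_network.nodes())
    n = len(nodes)
    if n == 0:
        raise ParameterError("empty network")
    index = {v: i for i, v in enumerate(nodes)}
    missing = [v for v in seeds if v not in index]
    if missing:
        raise ParameterError(f"seeds outside network: {missing[:3]}")

    # CSR-style adjacency for vectorised neighbour sampling.
    degrees = np.array([g_network.degree(v) for v in nodes], dtype=np.int64)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(degrees, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for u, v in g_network.edges():
        iu, iv = index[u], index[v]
        indices[fill[iu]] = iv
        fill[iu] += 1
        indices[fill[iv]] = iu
        fill[iv] += 1

    rng = np.random.default_rng(params.rng_seed)
    infected = np.zeros(n, dtype=bool)
    infected[[index[v] for v in seeds]] = True
    counts = [int(infected.sum())]
    time_to_full: int | None = 0 if infected.all() else None

    step = 0
    while time_to_full is None and step < params.max_steps:
        step += 1
        sus = np.flatnonzero(~infected)
        active = sus[degrees[sus] > 0]
        picks = indices[indptr[active] + rng.integers(0, degrees[active])]
        hits = infected[picks]
        if params.g < 1.0:
            hits = hits & (rng.random(active.size) < params.g)
        infected[active[hits]] = True
        counts.append(int(infected.sum()))
        if counts[-1] == n:
            time_to_full = step
    return SpreadingResult(
        infected_count_by_step=tuple(counts),
        time_to_full=time_to_full,
        seeds=seeds,
        n_nodes=n,
    )


def spreading_efficiency(result: SpreadingResult) -> int:
    """Steps to full coverage; raises UnreachedError if the run was truncated."""
    if result.time_to_full is None:
        raise UnreachedError(
            f"seed set {result.seeds.strategy!r} did not infect all "
            f"{result.n_nodes} nodes within {len(result.infected_count_by_step) - 1} steps"
        )
    return result.time_to_full
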