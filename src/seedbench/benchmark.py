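"""End-to-end benchmarking of seeding strategies.

Orchestrates networks × strategies × runs: generate (or accept) a batch of
networks, reduce each to its largest connected component, detect communities,
build every strategy's seed set, run repeated SI cascades over a grid of
contagion probabilities, and aggregate two summaries:

* an outperformance ranking — per run, each strategy scores one point for every
  competitor it beats strictly on spreading time; points are summed over runs
  and networks and strategies are ranked 0 (never outperforms) to 9 (beats all
  nine competitors everywhere);
* a degeneracy matrix — the mean Jaccard overlap |A∩B| / |A∪B| between each
  pair of strategies' seed sets, averaged over the batch.  1 on the diagonal by
  construction; high off-diagonal values mean two strategies keep proposing the
  same nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .community import Partition, detect_communities
from .errors import ParameterError, StrategyError
from .netgen import generate_category_batch, largest_connected_component
from .spreading import SIParams, run_si
from .strategies import ALL_STRATEGIES, seed_count_from_proportion, select_seeds

__all__ = [
    "BenchmarkConfig",
    "BenchmarkResult",
    "outperformance_counts",
    "aggregate_ranking",
    "degeneracy_coefficient",
    "degeneracy_matrix",
    "mean_pairwise_degeneracy",
    "mean_degeneracy_vs_others",
    "run_benchmark",
]

RECORD_COLUMNS = [
    "network", "category", "size_class", "strategy", "g", "s", "run",
    "time_to_full", "reached",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of one benchmark experiment.

    Either a generated batch (category + size_class) or a list of prepared
    graphs.  ``s_rule`` is "communities" (s = number of detected communities,
    the default for generated batches) or a sequence of proportions of the LCC
    size (the convention for loaded, empirical-style networks).
    """

    category: str | None = None
    size_class: str | None = None
    graphs: tuple | None = None
    n_networks: int = 30
    n_runs: int = 30
    g_grid: tuple = (0.25, 0.5, 0.75, 1.0)
    s_rule: str | tuple = "communities"
    rng_seed: int = 0
    strategies: tuple = ALL_STRATEGIES
    density_target: float | None = None
    clustering_target: float | None = None

    def __post_init__(self):
        if self.n_networks < 1 or self.n_runs < 1:
            raise ParameterError("n_networks and n_runs must be >= 1")
        if self.graphs is None and (self.category is None or self.size_class is None):
            raise ParameterError("either graphs or category + size_class required")
        if not self.g_grid:
            raise ParameterError("g_grid must be nonempty")


@dataclass
class BenchmarkResult:
    """Raw run records plus the two aggregate views and all intermediates."""

    records: pd.DataFrame
    ranking: pd.DataFrame
    degeneracy: pd.DataFrame
    seed_sets: list  # per network: {(strategy, s): SeedSet}
    partitions: list
    networks: list
    config: BenchmarkConfig


def outperformance_counts(times: Mapping) -> dict:
    """#competitors each strategy strictly beats on spreading time.

    Ties award no point to either side, so with k strategies the counts sum to
    C(k, 2) minus the number of tied pairs.
    """
    if not times:
        raise ParameterError("empty time table")
    return {
        a: sum(1 for b, tb in times.items() if b != a and times[a] < tb)
        for a in times
    }


def aggregate_ranking(records: pd.DataFrame, group_cols: Sequence[str] = ()) -> pd.DataFrame:
    """Sum per-run outperformance counts and rank strategies per group.

    Every (network, g, s, run) cell must contain one record per strategy;
    unreached runs are excluded from that cell's pairwise comparisons.  Ranks
    run from 0 (bottom) to n_strategies - 1 (top); tied totals share the better
    rank.
    """
    group_cols = list(group_cols)
    roster = sorted(records["strategy"].unique())
    unit_cols = group_cols + ["network", "g", "s", "run"]
    rows = []
    for unit_key, unit in records.groupby(unit_cols, sort=False):
        present = set(unit["strategy"])
        if present != set(roster):
            raise ParameterError(
                f"group {unit_key} missing strategies: {sorted(set(roster) - present)}"
            )
        finite = unit[unit["reached"]]
        times = dict(zip(finite["strategy"], finite["time_to_full"]))
        counts = outperformance_counts(times) if times else {}
        group_key = unit_key[: len(group_cols)]
        for strat in roster:
            rows.append((*group_key, strat, counts.get(strat, 0)))
    scored = pd.DataFrame(rows, columns=group_cols + ["strategy", "score"])
    totals = scored.groupby(group_cols + ["strategy"], as_index=False, sort=True)["score"].sum()

    def _rank(block: pd.DataFrame) -> pd.DataFrame:
        block = block.sort_values(["score", "strategy"], ascending=[False, True])
        scores = block["score"].to_numpy()
        block = block.assign(
            rank=[len(roster) - 1 - int((scores > sc).sum()) for sc in scores]
        )
        return block
    if group_cols:
        out = totals.groupby(group_cols, group_keys=False, sort=True)[totals.columns].apply(_rank)
    else:
        out = _rank(totals)
    return out.reset_index(drop=True)


def degeneracy_coefficient(a: Iterable, b: Iterable) -> float:
    """Jaccard overlap |A∩B| / |A∪B| of two nonempty seed sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ParameterError("degeneracy coefficient undefined for empty seed sets")
    return len(sa & sb) / len(sa | sb)


def degeneracy_matrix(seed_sets_by_network: Sequence[Mapping]) -> pd.DataFrame:
    """Mean pairwise degeneracy over a batch; symmetric with unit diagonal.

    ``seed_sets_by_network`` maps strategy name → SeedSet (or node iterable),
    with the same strategy roster for every network.
    """
    if not seed_sets_by_network:
        raise ParameterError("no seed sets given")
    roster = sorted(seed_sets_by_network[0])
    for sets_ in seed_sets_by_network:
        if sorted(sets_) != roster:
            raise StrategyError("strategy roster differs between networks")
    mat = pd.DataFrame(np.eye(len(roster)), index=roster, columns=roster)
    for a, b in itertools.combinations(roster, 2):
        vals = [degeneracy_coefficient(s[a], s[b]) for s in seed_sets_by_network]
        mat.loc[a, b] = mat.loc[b, a] = float(np.mean(vals))
    return mat


def mean_pairwise_degeneracy(matrix: pd.DataFrame, strategies: Sequence[str]) -> float:
    """Mean of the off-diagonal entries among a group of strategies."""
    pairs = list(itertools.combinations(strategies, 2))
    return float(np.mean([matrix.loc[a, b] for a, b in pairs]))


def mean_degeneracy_vs_others(matrix: pd.DataFrame, strategy: str) -> float:
    """Mean overlap of one strategy against every other strategy in the matrix."""
    others = [s for s in matrix.index if s != strategy]
    return float(np.mean([matrix.loc[strategy, o] for o in others]))


def _derived_seed(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] >> 1)


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Run the full pipeline; fully reproducible from ``config.rng_seed``."""
    if config.graphs is not None:
        networks = [largest_connected_component(g) for g in config.graphs]
    else:
        batch = generate_category_batch(
            config.category,
            config.size_class,
            config.n_networks,
            config.rng_seed,
            density_target=config.density_target,
            clustering_target=config.clustering_target,
        )
        networks = [largest_connected_component(g) for g in batch]

    partitions: list[Partition] = []
    seed_sets: list[dict] = []
    rows = []
    for net_idx, lcc in enumerate(networks):
        partition = detect_communities(lcc, rng_seed=_derived_seed(config.rng_seed, net_idx, 101))
        partitions.append(partition)
        if config.s_rule == "communities":
            s_values = [partition.n_communities]
        else:
            s_values = sorted(
                {seed_count_from_proportion(lcc.number_of_nodes(), p) for p in config.s_rule}
            )
        sets_for_net: dict = {}
        for strat_idx, strategy in enumerate(config.strategies):
            for s in s_values:
                try:
                    sets_for_net[(strategy, s)] = select_seeds(
                        lcc, strategy, s, partition=partition,
                        rng_seed=_derived_seed(config.rng_seed, net_idx, strat_idx, s),
                    )
                except StrategyError as exc:
                    raise StrategyError(
                        f"network {net_idx} ({lcc.graph.get('name', '?')}), "
                        f"strategy {strategy}: {exc}"
                    ) from exc
        seed_sets.append(sets_for_net)

        for (strategy, s), seeds in sets_for_net.items():
            strat_idx = config.strategies.index(strategy)
            for g_prob in config.g_grid:
                for run in range(config.n_runs):
                    params = SIParams(
                        g=g_prob,
                        rng_seed=_derived_seed(
                            config.rng_seed, net_idx, strat_idx, s,
                            int(round(g_prob * 10_000)), run,
                        ),
                    )
                    result = run_si(lcc, seeds, params)
                    rows.append((
                        net_idx,
                        lcc.graph.get("category", config.category or ""),
                        lcc.graph.get("size_class", config.size_class or ""),
                        strategy,
                        g_prob,
                        s,
                        run,
                        float(result.time_to_full) if result.reached else float("nan"),
                        result.reached,
                    ))

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    group_cols = ["category", "size_class"] if config.graphs is None else ["network", "g", "s"]
    ranking = aggregate_ranking(records, group_cols)
    # Overlap is evaluated at one size per strategy (the smallest requested);
    # under the "communities" rule there is exactly one size per network anyway.
    per_network = []
    for sets_ in seed_sets:
        by_strategy: dict = {}
        for (strategy, s) in sorted(sets_, key=lambda k: (k[0], k[1])):
            by_strategy.setdefault(strategy, sets_[(strategy, s)])
        per_network.append(by_strategy)
    degeneracy = degeneracy_matrix(per_network)
    return BenchmarkResult(
        records=records,
        ranking=ranking,
        degeneracy=degeneracy,
        seed_sets=seed_sets,
        partitions=partitions,
        networks=networks,
        config=config,
    )
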