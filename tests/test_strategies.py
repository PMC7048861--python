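"""Seed-selection strategies: per-strategy rules, ties, and invariants."""

import networkx as nx
import numpy as np
import pytest

from seedbench import (
    ALL_STRATEGIES,
    StrategyError,
    build_fixture,
    detect_communities,
    external_internal_degree,
    select_seeds,
    voterank_trace,
)


@pytest.fixture(scope="module")
def graph_zoo(small_growth_graph):
    graphs = [
        build_fixture("star", 6),
        build_fixture("cycle", 8),
        build_fixture("two_cliques_bridge", 5),
        build_fixture("grid", 3, 4),
        small_growth_graph,
    ]
    return [(g, detect_communities(g, rng_seed=0)) for g in graphs]


class TestSelectSeedsBasics:
    def test_star_degree_picks_hub(self):
        g = build_fixture("star", 5)
        assert select_seeds(g, "degree", 1, rng_seed=0).nodes == (0,)

    def test_path_betweenness_picks_middle(self):
        g = build_fixture("path", 3)
        assert select_seeds(g, "betweenness", 1, rng_seed=0).nodes == (1,)

    def test_random_with_s_equal_n_returns_all_nodes(self):
        g = build_fixture("cycle", 7)
        seeds = select_seeds(g, "random", 7, rng_seed=1)
        assert set(seeds) == set(g.nodes())

    @pytest.mark.parametrize("strategy", ALL_STRATEGIES)
    def test_full_size_returns_every_node_on_cycle(self, strategy):
        # On a cycle every node is some node's (tied) top neighbour, so even
        # random_hubs can exhaust the graph.
        g = build_fixture("cycle", 9)
        p = detect_communities(g, rng_seed=0)
        seeds = select_seeds(g, strategy, 9, partition=p, rng_seed=4)
        assert set(seeds) == set(g.nodes())

    @pytest.mark.parametrize("strategy", ALL_STRATEGIES)
    def test_invariants_across_graphs(self, strategy, graph_zoo):
        for g, partition in graph_zoo:
            s = min(4, g.number_of_nodes())
            if strategy == "random_hubs":
                # only (tied) highest-degree neighbours are ever reachable
                degrees = dict(g.degree())
                reachable = {
                    u
                    for v in g.nodes()
                    for u in g[v]
                    if degrees[u] == max(degrees[w] for w in g[v])
                }
                s = min(s, len(reachable))
            seeds = select_seeds(g, strategy, s, partition=partition, rng_seed=11)
            assert len(seeds) == s
            assert len(set(seeds)) == s
            assert set(seeds) <= set(g.nodes())
            again = select_seeds(g, strategy, s, partition=partition, rng_seed=11)
            assert seeds.nodes == again.nodes

    def test_unknown_strategy_rejected(self):
        with pytest.raises(StrategyError):
            select_seeds(build_fixture("star", 3), "kshell", 1)

    def test_oversized_s_rejected(self):
        with pytest.raises(StrategyError):
            select_seeds(build_fixture("star", 3), "degree", 10)

    def test_partition_required_for_community_strategies(self):
        with pytest.raises(StrategyError):
            select_seeds(build_fixture("star", 3), "ambassadors", 1)


class TestCentralized:
    def test_degree_seeds_match_independent_top_block(self, small_growth_graph):
        g = small_growth_graph
        s = 10
        seeds = set(select_seeds(g, "degree", s, rng_seed=3))
        degrees = dict(g.degree())
        threshold = sorted(degrees.values(), reverse=True)[s - 1]
        assert all(degrees[v] >= threshold for v in seeds)
        assert {v for v, d in degrees.items() if d > threshold} <= seeds

    def test_tied_scores_resolved_by_seeded_draw(self):
        g = build_fixture("star", 8)  # 8 interchangeable leaves
        picks = {select_seeds(g, "degree", 3, rng_seed=seed).nodes for seed in range(12)}
        assert len(picks) > 1  # different seeds reach different tied leaves
        assert all(p[0] == 0 for p in picks)  # but the hub always leads

    def test_kcore_tops_up_from_lower_shells(self):
        # K5 (core 4) with a pendant chain: asking for 6 must take all of the
        # max core and top up from the next shell down.
        g = nx.complete_graph(5)
        g.add_edges_from([(0, 5), (5, 6), (1, 5), (1, 6), (0, 6)])
        core = nx.core_number(g)
        kmax = max(core.values())
        seeds = set(select_seeds(g, "kcore", 6, rng_seed=2))
        top_shell = {v for v, c in core.items() if c == kmax}
        assert top_shell <= seeds
        assert len(seeds - top_shell) == 6 - len(top_shell)


class TestVoteRank:
    def test_first_pick_is_max_degree_with_score_equal_degree(self, small_growth_graph):
        trace = voterank_trace(small_growth_graph, 1, rng_seed=0)
        node, score = trace[0]
        degrees = dict(small_growth_graph.degree())
        assert degrees[node] == max(degrees.values())
        assert score == pytest.approx(degrees[node])

    def test_star_second_pick_scores_zero(self):
        # Hub first (score 4).  The hub's ability drops to 0 on selection, so
        # every leaf's voting score (= hub ability) is then exactly 0, even
        # though the leaves' own abilities fell to 1 - 1/<k> = 0.375.
        g = build_fixture("star", 4)
        trace = voterank_trace(g, 2, rng_seed=1)
        assert trace[0] == (0, pytest.approx(4.0))
        second, score = trace[1]
        assert second in {1, 2, 3, 4}
        assert score == pytest.approx(0.0)

    def test_five_node_toy_matches_hand_simulation(self):
        # Edges 0-1, 0-2, 0-3, 3-4; <k> = 8/5 so the decrement is 0.625.
        # Step 1: scores 0:3, 3:2, leaves:1 -> pick 0 (score 3); abilities of
        # 1,2,3 drop to 0.375.  Step 2: score(3) = ability(0) + ability(4)
        # = 0 + 1 = 1; score(4) = ability(3) = 0.375; leaves 1,2 score 0.
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (3, 4)])
        trace = voterank_trace(g, 2, rng_seed=0)
        assert trace[0] == (0, pytest.approx(3.0))
        assert trace[1] == (3, pytest.approx(1.0))

    def test_selection_matches_trace(self, small_growth_graph):
        seeds = select_seeds(small_growth_graph, "voterank", 5, rng_seed=6)
        trace = voterank_trace(small_growth_graph, 5, rng_seed=6)
        assert seeds.nodes == tuple(v for v, _ in trace)


class TestCommunityStrategies:
    def test_external_internal_degree_on_bridged_cliques(self):
        g = build_fixture("two_cliques_bridge", 3)
        p = detect_communities(g, rng_seed=0)
        ext, internal = external_internal_degree(g, p, 0)  # bridge endpoint
        assert (ext, internal) == (1, 2)
        ext, internal = external_internal_degree(g, p, 1)  # interior node
        assert (ext, internal) == (0, 2)

    def test_external_plus_internal_equals_degree(self, tiny_connected_graphs):
        for g in tiny_connected_graphs:
            p = detect_communities(g, rng_seed=1)
            for v in g.nodes():
                ext, internal = external_internal_degree(g, p, v)
                assert ext + internal == g.degree(v)
                oracle_ext = sum(
                    1 for u in g[v] if p.assignment[u] != p.assignment[v]
                )
                assert ext == oracle_ext

    @pytest.mark.parametrize("strategy", ["ambassadors", "community_hubs"])
    def test_one_seed_per_community_until_all_represented(self, strategy, small_growth_graph):
        g = small_growth_graph
        p = detect_communities(g, rng_seed=0)
        nc = p.n_communities
        seeds = select_seeds(g, strategy, nc, partition=p, rng_seed=8)
        assert sorted(p.assignment[v] for v in seeds) == list(range(nc))
        # beyond nc seeds the cycle revisits communities, largest first
        more = select_seeds(g, strategy, nc + 2, partition=p, rng_seed=8)
        counts = {}
        for v in more:
            counts[p.assignment[v]] = counts.get(p.assignment[v], 0) + 1
        assert max(counts.values()) == 2 and sum(counts.values()) == nc + 2

    def test_community_hubs_pick_internal_hub_of_each_clique(self):
        g = build_fixture("two_cliques_bridge", 4)
        p = detect_communities(g, rng_seed=0)
        seeds = select_seeds(g, "community_hubs", 2, partition=p, rng_seed=0)
        assert {p.assignment[v] for v in seeds} == {0, 1}

    def test_ambassadors_prefer_bridge_endpoints(self):
        g = build_fixture("two_cliques_bridge", 4)
        p = detect_communities(g, rng_seed=0)
        seeds = select_seeds(g, "ambassadors", 2, partition=p, rng_seed=0)
        assert set(seeds) == {0, 4}  # the only nodes with external degree > 0


class TestRandomHubs:
    def test_hub_of_star_always_found_first(self):
        g = build_fixture("star", 6)
        seeds = select_seeds(g, "random_hubs", 1, rng_seed=5)
        assert seeds.nodes == (0,)

    def test_unreachable_node_raises_after_bounded_draws(self):
        # Pendant node 3 is nobody's highest-degree neighbour, so a full draw
        # is impossible.
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (0, 3)])
        with pytest.raises(StrategyError):
            select_seeds(g, "random_hubs", 4, rng_seed=0)
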