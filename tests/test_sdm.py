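"""Steepest-descent core: distances, selection, guards, statistics, pruning."""

import math

import networkx as nx
import pytest

from conftest import (
    brute_force_max_avg_weight,
    brute_force_shortest_distance,
    random_weighted_graph,
)
from seedscan import sdm
from seedscan.sdm import (
    CandidateNetwork,
    aggregate_score,
    average_weight,
    density,
    descend,
    dijkstra_distances,
    network_score,
    prune_edges,
    rank_networks,
    remove_with_guard,
    seed_distance,
    select_candidate_node,
    select_final,
)


def weighted(edges):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


# -- distances ---------------------------------------------------------------


def test_dijkstra_additive_path_distance():
    g = weighted([("A", "B", 0.9), ("B", "C", 0.9)])
    d = dijkstra_distances(g, "A")
    assert d["C"] == pytest.approx(0.2)
    assert d["A"] == 0.0


def test_dijkstra_unreachable_is_infinite():
    g = weighted([("A", "B", 0.9)])
    g.add_node("Z")
    assert math.isinf(dijkstra_distances(g, "A")["Z"])


def test_dijkstra_matches_exhaustive_path_enumeration():
    for seed in range(15):
        g = random_weighted_graph(seed, n_max=8)
        src = sorted(g.nodes)[0]
        d = dijkstra_distances(g, src)
        for node in g.nodes:
            assert d[node] == pytest.approx(
                brute_force_shortest_distance(g, src, node), abs=1e-12
            )


def test_dijkstra_triangle_inequality():
    for seed in range(5):
        g = random_weighted_graph(seed + 30, n_max=7)
        nodes = sorted(g.nodes)
        dist = {u: dijkstra_distances(g, u) for u in nodes}
        for u in nodes:
            for v in nodes:
                for w in nodes:
                    assert dist[u][v] <= dist[u][w] + dist[w][v] + 1e-12


def test_seed_distance_uses_nearest_seed(worked_example):
    g, seeds = worked_example
    assert seed_distance("N1", seeds, g) == pytest.approx(0.050)
    assert seed_distance("N2", seeds, g) == pytest.approx(0.050)


def test_seed_distance_single_strong_edge():
    g = weighted([("X", "S", 0.999)])
    assert seed_distance("X", ["S"], g) == pytest.approx(0.001)


def test_seed_distance_unreachable_node_is_infinite():
    g = weighted([("S1", "S2", 0.9)])
    g.add_node("X")
    assert math.isinf(seed_distance("X", ["S1", "S2"], g))


def test_aggregate_scores_from_worked_example(worked_example):
    g, seeds = worked_example
    assert aggregate_score("N1", seeds, g) == pytest.approx(2.700)
    assert aggregate_score("N2", seeds, g) == pytest.approx(1.850)


def test_aggregate_score_zero_without_direct_seed_edges():
    g = weighted([("S1", "M", 0.9), ("M", "X", 0.9)])
    assert aggregate_score("X", ["S1"], g) == 0.0


# -- candidate selection and guard -------------------------------------------


def test_distance_phase_selects_farthest_node():
    g = weighted([("S", "N1", 0.95), ("S", "M", 0.9), ("M", "N3", 0.8)])
    node, phase = select_candidate_node(g, ["S"])
    assert (node, phase) == ("N3", "distance")


def test_aggregate_phase_removes_lower_contributor(worked_example):
    g, seeds = worked_example
    node, phase = select_candidate_node(g, seeds)
    assert (node, phase) == ("N2", "aggregate")


def test_equal_criterion_breaks_ties_lexicographically():
    g = weighted([("S", "B", 0.9), ("S", "A", 0.9)])
    node, _ = select_candidate_node(g, ["S"])
    assert node == "A"


def test_guard_accepts_leaf_and_redundant_cut():
    g = weighted([("S1", "X", 0.9), ("X", "S2", 0.9), ("S1", "S2", 0.8), ("S2", "L", 0.7)])
    assert remove_with_guard(g, ["S1", "S2"], "L") is not None
    assert remove_with_guard(g, ["S1", "S2"], "X") is not None


def test_guard_rejects_sole_cut_vertex():
    g = weighted([("S1", "X", 0.9), ("X", "S2", 0.9)])
    assert remove_with_guard(g, ["S1", "S2"], "X") is None


# -- statistics --------------------------------------------------------------


def test_density_complete_graph_equals_mean_weight():
    g = weighted([("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)])
    assert density(g) == pytest.approx(0.9)


def test_density_normalizes_by_possible_edges():
    g = weighted([("A", "B", 0.9)])
    g.add_node("C")
    assert density(g) == pytest.approx(0.3)
    g_empty = nx.Graph()
    g_empty.add_nodes_from("ABC")
    assert density(g_empty) == 0.0
    with pytest.raises(ValueError):
        density(nx.Graph([("A", "A")]))


def test_average_weight_is_mean_of_present_edges():
    g = weighted([("A", "B", 0.8), ("B", "C", 0.999), ("C", "D", 0.9)])
    assert average_weight(g) == pytest.approx((0.8 + 0.999 + 0.9) / 3)
    single = weighted([("A", "B", 0.85)])
    assert average_weight(single) == pytest.approx(0.85)
    with pytest.raises(ValueError):
        average_weight(nx.Graph())


def test_removing_unique_minimum_edge_increases_average():
    g = weighted([("A", "B", 0.8), ("B", "C", 0.999), ("C", "D", 0.9)])
    before = average_weight(g)
    g.remove_edge("A", "B")
    assert average_weight(g) > before


def test_score_is_total_weight_and_w_times_edge_count():
    g = weighted([("A", "B", 0.95), ("B", "C", 0.90)])
    assert network_score(g) == pytest.approx(1.85)
    assert network_score(nx.Graph()) == 0.0
    for seed in range(3):
        h = random_weighted_graph(seed + 60, n_max=7)
        assert network_score(h) == pytest.approx(
            average_weight(h) * h.number_of_edges()
        )


def test_candidate_stats_consistent_with_recomputation():
    g = random_weighted_graph(5, n_max=8)
    cand = CandidateNetwork.from_graph(g)
    d, w, s = cand.recompute()
    assert abs(cand.density - d) < 1e-12
    assert abs(cand.avg_weight - w) < 1e-12
    assert abs(cand.score - s) < 1e-12


# -- descent -----------------------------------------------------------------


def test_descend_recovers_planted_clique(planted_clique):
    g, seeds, clique = planted_clique
    trace, top = descend(g, seeds, size_threshold=12)
    assert top[0].nodes == clique
    sizes = [s.size_after for s in trace.steps]
    assert sizes == sorted(sizes, reverse=True)
    assert not any(s.removed in seeds for s in trace.steps)


def test_descend_trivial_when_only_seeds_remain():
    g = weighted([("S1", "S2", 0.9)])
    trace, top = descend(g, ["S1", "S2"], size_threshold=10)
    assert trace.steps == []
    assert len(top) == 1 and top[0].nodes == {"S1", "S2"}


def test_descend_keep_one_returns_densest_only(planted_clique):
    g, seeds, clique = planted_clique
    _, top = descend(g, seeds, size_threshold=12, keep=1)
    assert len(top) == 1
    assert top[0].nodes == clique


def test_descend_rejects_disconnected_seeds():
    g = weighted([("S1", "A", 0.9), ("S2", "B", 0.9)])
    with pytest.raises(ValueError, match="threshold"):
        descend(g, ["S1", "S2"], size_threshold=10)


def test_descend_records_only_at_or_below_threshold(planted_clique):
    g, seeds, _ = planted_clique
    _, top = descend(g, seeds, size_threshold=5, keep=10)
    assert all(c.size <= 5 for c in top)


def test_select_final_prefers_size_among_dense():
    def cand(names, w):
        g = nx.Graph()
        nodes = [f"{names}{i}" for i in range(len(names))]
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b, weight=w)
        return CandidateNetwork.from_graph(g)

    c10 = cand("ABCDEFGHIJ", 0.91)
    c12 = cand("ABCDEFGHIJKL", 0.88)
    c9 = cand("ABCDEFGHI", 0.95)
    assert select_final([c10, c12, c9]) is c12
    assert select_final([c9]) is c9
    # equal size: higher density wins
    hi = cand("XYZ", 0.95)
    lo = cand("XYZ", 0.80)
    assert select_final([lo, hi]) is hi
    with pytest.raises(ValueError):
        select_final([])


# -- pruning and ranking ------------------------------------------------------


def test_prune_triangle_removes_weakest_then_stops():
    g = weighted([("A", "B", 0.8), ("B", "C", 0.9), ("A", "C", 0.95)])
    pruned = prune_edges(CandidateNetwork.from_graph(g), rng_seed=0)
    assert set(map(frozenset, pruned.graph.edges)) == {
        frozenset({"B", "C"}),
        frozenset({"A", "C"}),
    }
    assert pruned.avg_weight == pytest.approx(0.925)


def test_prune_tree_is_fixed_point():
    g = weighted([("A", "B", 0.6), ("B", "C", 0.7), ("B", "D", 0.9)])
    pruned = prune_edges(CandidateNetwork.from_graph(g), rng_seed=1)
    assert set(map(frozenset, pruned.graph.edges)) == set(map(frozenset, g.edges))


def test_prune_monotone_and_matches_brute_force():
    for seed in range(12):
        g = random_weighted_graph(seed + 100, n_max=7, p=0.5, max_edges=12)
        pruned, w_trace = prune_edges(
            CandidateNetwork.from_graph(g), rng_seed=seed, return_trace=True
        )
        assert all(b >= a - 1e-12 for a, b in zip(w_trace, w_trace[1:]))
        assert nx.is_connected(pruned.graph)
        assert set(pruned.graph.nodes) == set(g.nodes)
        assert pruned.avg_weight == pytest.approx(brute_force_max_avg_weight(g), abs=1e-9)


def test_prune_deterministic_under_seed():
    g = weighted(
        [("A", "B", 0.8), ("B", "C", 0.8), ("C", "D", 0.8), ("D", "A", 0.8),
         ("A", "C", 0.8)]
    )
    first = prune_edges(CandidateNetwork.from_graph(g), rng_seed=7)
    second = prune_edges(CandidateNetwork.from_graph(g), rng_seed=7)
    assert set(first.graph.edges) == set(second.graph.edges)


def test_rank_networks_orders_by_score():
    def cand(score_edges):
        g = nx.Graph()
        for i, w in enumerate(score_edges):
            g.add_edge(f"a{i}", f"b{i}", weight=w)
            g.add_edge(f"b{i}", f"a{i+1}" if i + 1 < len(score_edges) else "a0",
                       weight=w)
        if not nx.is_connected(g):
            comps = list(nx.connected_components(g))
            for c1, c2 in zip(comps, comps[1:]):
                g.add_edge(next(iter(c1)), next(iter(c2)), weight=0.5)
        return CandidateNetwork.from_graph(g)

    a, b, c = cand([0.9]), cand([0.9, 0.8]), cand([0.9, 0.9, 0.9])
    ranked = rank_networks([a, b, c], top_n=2)
    assert ranked[0].score >= ranked[1].score
    assert len(ranked) == 2
    assert len(rank_networks([a, b], top_n=10)) == 2
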