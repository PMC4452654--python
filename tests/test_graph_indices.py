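"""Wiener and Randić indices against closed forms and BFS oracles."""

import math

import numpy as np
import pytest

from treatcycles.graph_indices import (
    UNREACHABLE,
    find_extremal,
    index_table,
    is_disconnected,
    randic_directed,
    randic_in,
    randic_index,
    randic_out,
    randic_undirected,
    shortest_path_distance,
    wiener_index,
)

from helpers import (
    directed_cycle_graph,
    directed_path,
    make_cycle,
    oracle_wiener,
)


def _random_cycle(rng, n_max=8, p_lo=0.1, p_hi=0.6):
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"V{i}" for i in range(n)]
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    keep = rng.random(len(pairs)) < rng.uniform(p_lo, p_hi)
    return make_cycle([p for p, k in zip(pairs, keep) if k], extra_nodes=nodes)


def test_shortest_path_distance_modes_and_unreachability():
    p3 = directed_path(3)  # U0 -> U1 -> U2
    assert shortest_path_distance(p3, "U0", "U2", "undirected") == 2
    assert shortest_path_distance(p3, "U2", "U0", "directed") == UNREACHABLE
    assert shortest_path_distance(p3, "U0", "U2", "directed") == 2
    assert shortest_path_distance(p3, "U1", "U1") == 0
    with pytest.raises(ValueError):
        shortest_path_distance(p3, "U0", "nope")
    with pytest.raises(ValueError):
        shortest_path_distance(p3, "U0", "U1", mode="sideways")


def test_wiener_trivial_graphs():
    assert wiener_index(directed_path(1)) == 0.0
    assert wiener_index(directed_path(2)) == 1.0


@pytest.mark.parametrize("n", range(2, 11))
def test_wiener_on_paths_matches_closed_form(n):
    assert wiener_index(directed_path(n)) == pytest.approx(n * (n * n - 1) / 6)


def test_wiener_matches_independent_bfs_oracle_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(200):
        g = _random_cycle(rng)
        nodes = list(g.graph.nodes)
        edges = list(g.graph.edges)
        assert wiener_index(g) == pytest.approx(oracle_wiener(nodes, edges))


def test_wiener_on_disconnected_graph_sums_reachable_pairs_only():
    g = make_cycle([("A", "B")], extra_nodes=["C"])
    assert is_disconnected(g)
    assert wiener_index(g) == 1.0  # only the A-B pair is reachable


def test_wiener_strictly_increases_with_a_pendant_vertex():
    for n in range(2, 8):
        path = directed_path(n)
        extended = directed_path(n + 1)  # path plus a pendant at the end
        assert wiener_index(extended) > wiener_index(path)


def test_randic_single_edge_unit_degrees():
    assert randic_index({"A": 1, "B": 1}, [("A", "B")]) == 1.0


@pytest.mark.parametrize("n", range(3, 11))
def test_randic_undirected_path_closed_form(n):
    expected = (n - 3) / 2 + math.sqrt(2)
    assert randic_undirected(directed_path(n)) == pytest.approx(expected)


def test_randic_zero_degree_edges_contribute_nothing():
    p3 = directed_path(3)
    # in-degrees: U0=0 so (U0,U1) contributes 0; (U1,U2) contributes 1
    assert randic_in(p3) == pytest.approx(1.0)
    assert randic_out(p3) == pytest.approx(1.0)
    assert randic_directed(p3) == pytest.approx(1.0)


def test_randic_in_on_two_cycle_counts_both_edges():
    two_cycle = make_cycle([("A", "B"), ("B", "A")])
    assert randic_in(two_cycle) == pytest.approx(2.0)


@pytest.mark.parametrize("n", range(2, 11))
def test_directed_randic_of_directed_cycle_equals_order(n):
    assert randic_directed(directed_cycle_graph(n)) == pytest.approx(float(n))


def test_empty_graph_scores_zero_everywhere():
    g = directed_path(1)
    assert randic_directed(g) == 0.0
    assert randic_undirected(g) == 0.0


def test_directed_randic_is_mean_of_in_and_out_variants():
    rng = np.random.default_rng(7)
    for _ in range(300):
        g = _random_cycle(rng)
        assert randic_directed(g) == (randic_in(g) + randic_out(g)) / 2.0


def test_randic_is_invariant_under_vertex_relabelling():
    rng = np.random.default_rng(11)
    for _ in range(50):
        g = _random_cycle(rng)
        nodes = list(g.graph.nodes)
        shuffled = list(nodes)
        rng.shuffle(shuffled)
        mapping = dict(zip(nodes, shuffled))
        relabelled = make_cycle(
            [(mapping[u], mapping[v]) for u, v in g.graph.edges],
            extra_nodes=shuffled,
        )
        assert randic_directed(relabelled) == pytest.approx(randic_directed(g))
        assert wiener_index(relabelled) == pytest.approx(wiener_index(g))


def test_extremal_search_orders_paths_by_wiener():
    cycles = [directed_path(5), directed_path(2), directed_path(3)]
    ext = find_extremal(cycles, "wiener")
    assert ext.min_graph is cycles[1] and ext.min_value == 1.0
    assert ext.max_graph is cycles[0] and ext.max_value == 20.0


def test_extremal_singleton_and_ties():
    lone = directed_path(2)
    ext = find_extremal([lone], "wiener")
    assert ext.min_graph is ext.max_graph is lone

    twin_a, twin_b = directed_path(3), directed_path(3)
    ext = find_extremal([twin_a, twin_b], "randic_directed")
    assert ext.min_graphs == (twin_a, twin_b)  # ties kept in input order


def test_extremal_skips_empty_graphs_and_rejects_all_empty():
    ext = find_extremal([directed_path(1), directed_path(2)], "wiener")
    assert ext.min_graph.n_edges == 1
    with pytest.raises(ValueError, match="at least one edge"):
        find_extremal([directed_path(1)], "wiener")
    with pytest.raises(ValueError, match="unknown index"):
        find_extremal([directed_path(2)], "zagreb")


def test_index_table_has_one_scored_row_per_graph(worked_cycles):
    by_case, joined = worked_cycles
    frame = index_table(list(by_case.values()))
    assert len(frame) == 7
    row = frame[frame["case_ids"] == "FAL00002"].iloc[0]
    assert row["wiener"] == 1.0
    assert row["randic_undirected"] == 1.0
    assert not row["disconnected"]
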