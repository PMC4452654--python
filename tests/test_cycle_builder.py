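"""Graph construction: durations, edge weights, case and joined cycles."""

import datetime as dt

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treatcycles.cycle_builder import (
    build_case_cycle,
    edge_weight,
    join_cycles,
    stay_duration,
    write_edgelist_tsv,
    write_graphml,
)
from treatcycles.records_io import CaseRecordSet, StayRecord, group_into_cases

from helpers import case_from_units


def _rec(unit, acq, out, patient="P1", case="C1"):
    return StayRecord(patient, case, unit, acq, out)


def test_stay_duration_worked_values():
    d = dt.date
    assert stay_duration(_rec("FRY4", d(2005, 11, 3), d(2005, 11, 4))) == 1
    assert stay_duration(_rec("FRH1", d(2005, 11, 4), d(2005, 11, 10))) == 6
    assert stay_duration(_rec("KIBE", d(2005, 11, 4), d(2005, 11, 4))) == 0


@pytest.mark.parametrize(
    "dur_start,dur_target,expected",
    [(1, 6, 6), (4, 4, 1), (12, 3, 10), (0, 0, 1)],
)
def test_edge_weight_is_absolute_duration_difference_plus_one(
    dur_start, dur_target, expected
):
    d0 = dt.date(2010, 1, 1)
    start = _rec("A", d0, d0 + dt.timedelta(days=dur_start))
    target = _rec("B", start.outgoing_date,
                  start.outgoing_date + dt.timedelta(days=dur_target))
    assert edge_weight(start, target) == expected


def test_single_relocation_case_builds_two_vertex_one_edge_graph(worked_cycles):
    by_case, _ = worked_cycles
    g = by_case["FAL00002"]
    assert (g.n_vertices, g.n_edges) == (2, 1)
    assert g.edge_weight("FRY4", "FRH1") == 6
    assert g.edge_multiplicity("FRY4", "FRH1") == 1


def test_single_record_case_builds_empty_graph(worked_cycles):
    by_case, _ = worked_cycles
    g = by_case["FAL00001"]
    assert (g.n_vertices, g.n_edges) == (1, 0)
    assert g.units == {"KIBE"}


def test_three_stay_case_vertex_set_and_edge_weights(worked_cycles):
    by_case, _ = worked_cycles
    g = by_case["FAL00009"]
    assert g.units == {"KIB3", "FRH1", "FRGS"}
    assert g.n_vertices == 3 and g.n_edges == 2
    assert sorted(d["weight"] for _, _, d in g.graph.edges(data=True)) == [3, 12]


def test_unit_revisit_creates_directed_cycle():
    case = group_into_cases(case_from_units(["A", "B", "A"]))[0]
    g = build_case_cycle(case)
    assert g.units == {"A", "B"}
    assert set(g.graph.edges) == {("A", "B"), ("B", "A")}


def test_consecutive_same_unit_is_continued_stay_not_self_loop():
    case = group_into_cases(case_from_units(["A", "A", "B"]))[0]
    g = build_case_cycle(case)
    assert set(g.graph.edges) == {("A", "B")}
    assert nx.number_of_selfloops(g.graph) == 0


def test_repeated_transition_increments_multiplicity_keeps_first_weight():
    # A(1d) -> B(3d) -> A(3d) -> B(9d): edge A->B occurs twice
    case = group_into_cases(
        case_from_units(["A", "B", "A", "B"], durations=[1, 3, 3, 9])
    )[0]
    g = build_case_cycle(case)
    assert g.edge_multiplicity("A", "B") == 2
    assert g.edge_weight("A", "B") == 3  # |3-1|+1 from the first occurrence
    assert g.edge_weight("B", "A") == 1


def test_empty_case_is_a_contract_violation():
    with pytest.raises(ValueError):
        CaseRecordSet("C", "P", ())


@settings(derandomize=True, max_examples=100)
@given(
    units=st.lists(st.sampled_from("ABCDEF"), min_size=1, max_size=8),
    durations=st.lists(st.integers(min_value=0, max_value=14), min_size=8, max_size=8),
)
def test_case_graph_structural_invariants(units, durations):
    case = group_into_cases(case_from_units(units, durations=durations))[0]
    g = build_case_cycle(case)
    assert g.n_vertices == len(set(units))
    assert g.n_edges <= len(units) - 1
    assert all(d["weight"] >= 1 for _, _, d in g.graph.edges(data=True))
    assert nx.number_of_selfloops(g.graph) == 0
    if g.n_vertices > 1:
        assert nx.is_weakly_connected(g.graph)


def test_join_merges_shared_units(worked_cycles):
    by_case, _ = worked_cycles
    joined = join_cycles([by_case["FAL00002"], by_case["FAL00009"]], "PAT00001")
    assert joined.units == {"FRY4", "FRH1", "KIB3", "FRGS"}
    assert joined.n_vertices == 4 and joined.n_edges == 3
    assert joined.case_ids == ("FAL00002", "FAL00009")


def test_join_of_single_graph_is_identity(worked_cycles):
    by_case, _ = worked_cycles
    g = by_case["FAL00002"]
    j = join_cycles([g], "PAT00001")
    assert j.units == g.units
    assert set(j.graph.edges) == set(g.graph.edges)


def test_join_is_idempotent_and_order_insensitive_on_structure(worked_cycles):
    by_case, _ = worked_cycles
    a, b = by_case["FAL00002"], by_case["FAL00013"]
    ab = join_cycles([a, b], "PAT00001")
    ba = join_cycles([b, a], "PAT00001")
    aab = join_cycles([a, a, b], "PAT00001")
    assert ab.units == ba.units == aab.units
    assert set(ab.graph.edges) == set(ba.graph.edges) == set(aab.graph.edges)


def test_join_of_disjoint_graphs_is_disconnected(worked_cycles):
    by_case, _ = worked_cycles
    joined = join_cycles([by_case["FAL00002"], by_case["FAL00001"]], "PAT00001")
    assert not nx.is_weakly_connected(joined.graph)


def test_join_rejects_mixed_patients(worked_cycles):
    by_case, _ = worked_cycles
    with pytest.raises(ValueError, match="patient"):
        join_cycles([by_case["FAL00002"]], "PAT99999")
    with pytest.raises(ValueError):
        join_cycles([], "PAT00001")


def test_join_merged_edge_weight_comes_from_earliest_case():
    early = build_case_cycle(
        group_into_cases(case_from_units(["A", "B"], case="C1", durations=[1, 3]))[0]
    )
    late = build_case_cycle(
        group_into_cases(case_from_units(["A", "B"], case="C2", durations=[1, 9]))[0]
    )
    j = join_cycles([early, late], "P1")
    assert j.edge_weight("A", "B") == 3  # earliest case's weight
    assert j.edge_multiplicity("A", "B") == 2


def test_exports_preserve_edges_and_labels(tmp_path, worked_cycles):
    by_case, _ = worked_cycles
    g = by_case["FAL00009"]
    tsv = tmp_path / "g.tsv"
    write_edgelist_tsv(g, tsv)
    lines = tsv.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["source_unit", "target_unit", "weight", "multiplicity"]
    assert len(lines) == 1 + g.n_edges

    gml = tmp_path / "g.graphml"
    write_graphml(g, gml)
    back = nx.read_graphml(gml)
    assert set(back.edges) == set(g.graph.edges)
    assert back.graph["patient_id"] == "PAT00001"
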