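"""Structural classification of treatment cycles and cohort summaries.

Categories:

``empty``
    no edges (the case involved no relocation);
``linear_2``
    a directed path on exactly two vertices (one relocation);
``linear_long``
    a directed path on more than two vertices;
``cyclic``
    contains a directed cycle (the patient returned to a unit already
    visited in the same case);
``other``
    acyclic but not a single directed path (branching or disconnected),
    which arises mainly in joined per-patient graphs.

Connectivity is weak connectivity of the underlying undirected graph;
a graph counts as connected when it has exactly one weak component
(hence no isolated vertices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .cycle_builder import TreatmentCycle

EMPTY = "empty"
LINEAR_2 = "linear_2"
LINEAR_LONG = "linear_long"
CYCLIC = "cyclic"
OTHER = "other"

CATEGORIES = (EMPTY, LINEAR_2, LINEAR_LONG, CYCLIC, OTHER)


@dataclass(frozen=True)
class CycleClass:
    """Structural category and connectivity facts of one graph."""

    category: str
    is_weakly_connected: bool
    n_weak_components: int
    n_vertices: int
    n_edges: int


def _is_directed_path(g: nx.DiGraph) -> bool:
    """True iff the graph is a single directed path covering all vertices.

    Degree conditions: a unique start (out-degree 1, in-degree 0), a
    unique end (in-degree 1, out-degree 0), every other vertex with one
    incoming and one outgoing edge.  Together with acyclicity these
    force one spanning path.
    """
    if g.number_of_nodes() < 2:
        return False
    starts = ends = 0
    for v in g.nodes:
        din, dout = g.in_degree(v), g.out_degree(v)
        if (din, dout) == (0, 1):
            starts += 1
        elif (din, dout) == (1, 0):
            ends += 1
        elif (din, dout) != (1, 1):
            return False
    return starts == 1 and ends == 1


def classify_cycle(g: TreatmentCycle) -> CycleClass:
    """Classify one treatment cycle structurally.

    Empty graphs (no edges) come first; then directed-cycle detection;
    then the directed-path test splitting linear graphs by order;
    everything else (acyclic, branching or disconnected) is ``other``.
    """
    graph = g.graph
    n_comp = nx.number_weakly_connected_components(graph) if graph.number_of_nodes() else 0
    connected = n_comp == 1
    if graph.number_of_edges() == 0:
        category = EMPTY
    elif not nx.is_directed_acyclic_graph(graph):
        category = CYCLIC
    elif _is_directed_path(graph):
        category = LINEAR_2 if graph.number_of_nodes() == 2 else LINEAR_LONG
    else:
        category = OTHER
    return CycleClass(
        category=category,
        is_weakly_connected=connected,
        n_weak_components=n_comp,
        n_vertices=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
    )


@dataclass(frozen=True)
class PopulationSummary:
    """Counts for one population of graphs (per-case or joined)."""

    n_graphs: int
    n_with_more_than_one_vertex: int
    n_connected: int
    n_disconnected: int
    n_linear_2: int
    n_linear_long: int
    n_cyclic: int
    n_other: int

    def validate(self) -> None:
        if self.n_connected + self.n_disconnected != self.n_with_more_than_one_vertex:
            raise AssertionError("connectivity counts do not partition |V|>1 graphs")
        cats = self.n_linear_2 + self.n_linear_long + self.n_cyclic + self.n_other
        if cats != self.n_with_more_than_one_vertex:
            raise AssertionError("category counts do not partition |V|>1 graphs")


@dataclass(frozen=True)
class CohortSummary:
    """Per-case and joined population summaries, side by side."""

    cases: PopulationSummary
    joined: PopulationSummary

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("# treatment cycles", "n_graphs"),
            ("# treatment cycles with |V| > 1", "n_with_more_than_one_vertex"),
            ("# connected treatment cycles", "n_connected"),
            ("# disconnected treatment cycles", "n_disconnected"),
            ("# linear treatment cycles with |V| = 2", "n_linear_2"),
            ("# linear treatment cycles with |V| > 2", "n_linear_long"),
            ("# cyclic treatment cycles", "n_cyclic"),
            ("# other treatment cycles with |V| > 1", "n_other"),
        ]
        return pd.DataFrame(
            {
                "feature": [label for label, _ in rows],
                "individual_cases": [getattr(self.cases, attr) for _, attr in rows],
                "joined": [getattr(self.joined, attr) for _, attr in rows],
            }
        )


def summarize_population(cycles: Iterable[TreatmentCycle]) -> PopulationSummary:
    """Tabulate one population; connectivity and categories only for |V|>1.

    Multi-vertex graphs without edges (possible after a union of
    edgeless cases with distinct units) fall into the ``other`` column
    so the category columns partition the |V|>1 row exactly.
    """
    n_graphs = n_multi = n_conn = n_disc = 0
    n_l2 = n_ll = n_cyc = n_other = 0
    for cyc in cycles:
        cls = classify_cycle(cyc)
        n_graphs += 1
        if cls.n_vertices <= 1:
            continue
        n_multi += 1
        if cls.is_weakly_connected:
            n_conn += 1
        else:
            n_disc += 1
        if cls.category == LINEAR_2:
            n_l2 += 1
        elif cls.category == LINEAR_LONG:
            n_ll += 1
        elif cls.category == CYCLIC:
            n_cyc += 1
        else:
            n_other += 1
    summary = PopulationSummary(
        n_graphs=n_graphs,
        n_with_more_than_one_vertex=n_multi,
        n_connected=n_conn,
        n_disconnected=n_disc,
        n_linear_2=n_l2,
        n_linear_long=n_ll,
        n_cyclic=n_cyc,
        n_other=n_other,
    )
    summary.validate()
    return summary


def summarize_cohort(
    case_cycles: Sequence[TreatmentCycle],
    joined_cycles: Sequence[TreatmentCycle],
) -> CohortSummary:
    """Summaries for the per-case and the joined population."""
    return CohortSummary(
        cases=summarize_population(case_cycles),
        joined=summarize_population(joined_cycles),
    )


def classification_table(cycles: Iterable[TreatmentCycle]) -> pd.DataFrame:
    """Per-graph classification table (one row per graph)."""
    rows = []
    for cyc in cycles:
        cls = classify_cycle(cyc)
        rows.append(
            {
                "patient_id": cyc.patient_id,
                "case_ids": "+".join(cyc.case_ids),
                "category": cls.category,
                "n_vertices": cls.n_vertices,
                "n_edges": cls.n_edges,
                "n_weak_components": cls.n_weak_components,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "case_ids",
            "category",
            "n_vertices",
            "n_edges",
            "n_weak_components",
        ],
    )
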