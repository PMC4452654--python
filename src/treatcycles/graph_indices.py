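"""Topological indices on treatment cycles.

Two index families are provided.  The Wiener index

    W(G) = 1/2 * sum_i sum_j d(v_i, v_j)

is half the sum of shortest-path hop distances over all ordered vertex
pairs, a classical measure of structural branching; it is evaluated on
the underlying undirected graph, because on a directed path the reverse
distances are undefined.  The Randić connectivity index

    R(G) = sum over edges (u, v) of (k_u * k_v)^(-1/2)

scores how the edges distribute over vertex degrees.  For directed
graphs the Randić index is evaluated twice over the directed edge set —
once with in-degrees and once with out-degrees — and averaged:

    R_fin(G) = (R_in(G) + R_out(G)) / 2.

An edge whose endpoint degree product is zero (an endpoint of a path
has in- or out-degree 0) contributes nothing; without this convention
R_fin would be undefined on every linear graph.

Edge weights (day labels) never enter the indices: distances are hop
counts, degrees are edge counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence, Tuple

import networkx as nx
import pandas as pd

from .cycle_builder import TreatmentCycle

#: Sentinel distance for unreachable vertex pairs.
UNREACHABLE = math.inf


def shortest_path_distance(
    g: TreatmentCycle, v_i: str, v_j: str, mode: str = "undirected"
) -> float:
    """Hop count of the shortest path between two vertices.

    ``mode='undirected'`` ignores edge directions; ``mode='directed'``
    respects them.  Returns :data:`UNREACHABLE` (infinity) when no path
    exists.  Edge weights are labels, not lengths, and are ignored.
    """
    graph = g.graph
    if v_i not in graph or v_j not in graph:
        raise ValueError(f"vertex not in graph: {v_i!r} or {v_j!r}")
    if mode == "undirected":
        graph = graph.to_undirected(as_view=True)
    elif mode != "directed":
        raise ValueError(f"unknown mode {mode!r}")
    try:
        return float(nx.shortest_path_length(graph, v_i, v_j))
    except nx.NetworkXNoPath:
        return UNREACHABLE


def wiener_index(g: TreatmentCycle) -> float:
    """Wiener index on the underlying undirected graph.

    Half the sum of d(v_i, v_j) over ordered pairs; on a disconnected
    graph only mutually reachable pairs contribute (use
    :func:`is_disconnected` or the per-graph table to flag those).
    """
    und = g.graph.to_undirected(as_view=True)
    total = 0
    for _, lengths in nx.all_pairs_shortest_path_length(und):
        total += sum(lengths.values())
    return total / 2.0


def is_disconnected(g: TreatmentCycle) -> bool:
    """True when the underlying undirected graph has several components."""
    if g.n_vertices == 0:
        return False
    return nx.number_connected_components(g.graph.to_undirected(as_view=True)) > 1


def randic_index(
    degrees: Mapping[str, int], edges: Iterable[Tuple[str, str]]
) -> float:
    """Randić sum over an explicit degree assignment and edge set.

    Each edge (u, v) contributes ``(degrees[u] * degrees[v]) ** -0.5``;
    edges with a zero degree product contribute 0.
    """
    total = 0.0
    for u, v in edges:
        prod = degrees[u] * degrees[v]
        if prod > 0:
            total += prod ** -0.5
    return total


def randic_undirected(g: TreatmentCycle) -> float:
    """Classical Randić index of the underlying undirected graph."""
    und = g.graph.to_undirected(as_view=True)
    return randic_index(dict(und.degree()), und.edges())


def randic_in(g: TreatmentCycle) -> float:
    """Randić sum over directed edges using in-degrees."""
    return randic_index(dict(g.graph.in_degree()), g.graph.edges())


def randic_out(g: TreatmentCycle) -> float:
    """Randić sum over directed edges using out-degrees."""
    return randic_index(dict(g.graph.out_degree()), g.graph.edges())


def randic_directed(g: TreatmentCycle) -> float:
    """Directed Randić index: mean of the in- and out-degree variants."""
    return (randic_in(g) + randic_out(g)) / 2.0


INDEX_FUNCTIONS: Mapping[str, Callable[[TreatmentCycle], float]] = {
    "wiener": wiener_index,
    "randic_undirected": randic_undirected,
    "randic_in": randic_in,
    "randic_out": randic_out,
    "randic_directed": randic_directed,
}


@dataclass(frozen=True)
class ExtremalResult:
    """Graphs attaining the minimum and maximum of one index."""

    index_name: str
    min_value: float
    max_value: float
    min_graphs: tuple  # all ties, in provenance order
    max_graphs: tuple

    @property
    def min_graph(self) -> TreatmentCycle:
        return self.min_graphs[0]

    @property
    def max_graph(self) -> TreatmentCycle:
        return self.max_graphs[0]


def find_extremal(
    cycles: Sequence[TreatmentCycle], index_name: str
) -> ExtremalResult:
    """Locate the graphs of minimal and maximal index value.

    Empty graphs (no edges) are excluded — every index is trivially 0
    there.  Ties keep input (provenance) order; the first tie is the
    representative.
    """
    if index_name not in INDEX_FUNCTIONS:
        raise ValueError(
            f"unknown index {index_name!r}; choose from {sorted(INDEX_FUNCTIONS)}"
        )
    func = INDEX_FUNCTIONS[index_name]
    scored = [(cyc, func(cyc)) for cyc in cycles if cyc.n_edges >= 1]
    if not scored:
        raise ValueError("no graphs with at least one edge to rank")
    values = [v for _, v in scored]
    vmin, vmax = min(values), max(values)
    return ExtremalResult(
        index_name=index_name,
        min_value=vmin,
        max_value=vmax,
        min_graphs=tuple(c for c, v in scored if v == vmin),
        max_graphs=tuple(c for c, v in scored if v == vmax),
    )


def index_table(cycles: Iterable[TreatmentCycle]) -> pd.DataFrame:
    """Per-graph index table: order, size, Wiener and Randić variants."""
    rows = []
    for cyc in cycles:
        rows.append(
            {
                "patient_id": cyc.patient_id,
                "case_ids": "+".join(cyc.case_ids),
                "n_vertices": cyc.n_vertices,
                "n_edges": cyc.n_edges,
                "disconnected": is_disconnected(cyc),
                "wiener": wiener_index(cyc),
                "randic_undirected": randic_undirected(cyc),
                "randic_in": randic_in(cyc),
                "randic_out": randic_out(cyc),
                "randic_directed": randic_directed(cyc),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "case_ids",
            "n_vertices",
            "n_edges",
            "disconnected",
            "wiener",
            "randic_undirected",
            "randic_in",
            "randic_out",
            "randic_directed",
        ],
    )
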