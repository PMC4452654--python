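"""Construction of treatment-cycle graphs from grouped stay records.

A treatment cycle is a directed graph whose vertices are the nursing
organizational units occupied during one hospital case and whose edges
are the relocations (transfers) between consecutive units.  Each edge
carries a weight in days derived from the stay durations at its two
endpoints, and a multiplicity counting how often the same directed
relocation occurred.  The per-patient "joined" cycle is the
graph-theoretical union of all of that patient's case graphs, merging
vertices by unit code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import networkx as nx

from .records_io import CaseRecordSet, StayRecord


@dataclass
class TreatmentCycle:
    """A directed, vertex- and edge-labelled relocation graph.

    Vertices of ``graph`` are unit codes (the vertex labelling is
    injective: one vertex per distinct unit).  Edges carry two integer
    attributes: ``weight`` (days, always >= 1) and ``multiplicity``
    (number of occurrences of that directed relocation, >= 1).  There
    are no self-loops: consecutive stays in the same unit are a
    continued stay, not a relocation.
    """

    graph: nx.DiGraph
    patient_id: str
    case_ids: tuple = ()

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def units(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def is_empty(self) -> bool:
        """Empty in the domain sense: at least one vertex, no edges."""
        return self.n_edges == 0

    @property
    def provenance(self) -> str:
        return f"{self.patient_id}:{'+'.join(self.case_ids)}"

    def edge_weight(self, source: str, target: str) -> int:
        return int(self.graph.edges[source, target]["weight"])

    def edge_multiplicity(self, source: str, target: str) -> int:
        return int(self.graph.edges[source, target]["multiplicity"])


def stay_duration(record: StayRecord) -> int:
    """Length of one stay in whole days (outgoing minus acquisition)."""
    return (record.outgoing_date - record.acquisition_date).days


def edge_weight(start: StayRecord, target: StayRecord) -> int:
    """Weight of the relocation edge from ``start``'s unit to ``target``'s.

    The absolute difference of the two stay durations, plus one — so a
    transfer between stays of 1 and 6 days weighs ``|6 - 1| + 1 = 6``
    and every edge weight is at least 1.
    """
    return abs(stay_duration(target) - stay_duration(start)) + 1


def build_case_cycle(case: CaseRecordSet) -> TreatmentCycle:
    """Build the treatment cycle of a single case.

    One vertex per distinct unit code; a directed edge for each
    consecutive record pair with differing units, weighted by
    :func:`edge_weight`.  A repeated directed relocation increments the
    edge multiplicity and keeps the weight of its first occurrence.
    A single-record case yields the one-vertex empty graph.
    """
    if len(case.records) < 1:
        raise ValueError("case must contain at least one record")
    g = nx.DiGraph()
    for rec in case.records:
        g.add_node(rec.unit_code)
    for prev, nxt in zip(case.records, case.records[1:]):
        if prev.unit_code == nxt.unit_code:
            continue  # continued stay, not a relocation
        u, v = prev.unit_code, nxt.unit_code
        if g.has_edge(u, v):
            g.edges[u, v]["multiplicity"] += 1
        else:
            g.add_edge(u, v, weight=edge_weight(prev, nxt), multiplicity=1)
    return TreatmentCycle(graph=g, patient_id=case.patient_id, case_ids=(case.case_id,))


def join_cycles(cycles: Sequence[TreatmentCycle], patient_id: str) -> TreatmentCycle:
    """Graph-theoretical union of one patient's case cycles.

    Vertices merge by unit code; directed edge sets unite, with
    multiplicities summed and the weight of a merged edge taken from the
    earliest contributing cycle (the first in ``cycles``; pass cases in
    chronological order).  Disjoint case graphs make the joined graph
    disconnected.
    """
    cycles = list(cycles)
    if not cycles:
        raise ValueError("cannot join an empty collection of cycles")
    for c in cycles:
        if c.patient_id != patient_id:
            raise ValueError(
                f"cycle of patient {c.patient_id!r} cannot join patient {patient_id!r}"
            )
    g = nx.DiGraph()
    case_ids: list[str] = []
    for cycle in cycles:
        for cid in cycle.case_ids:
            if cid not in case_ids:
                case_ids.append(cid)
        for node in cycle.graph.nodes:
            g.add_node(node)
        for u, v, data in cycle.graph.edges(data=True):
            if g.has_edge(u, v):
                g.edges[u, v]["multiplicity"] += data["multiplicity"]
            else:
                g.add_edge(u, v, weight=data["weight"], multiplicity=data["multiplicity"])
    return TreatmentCycle(graph=g, patient_id=patient_id, case_ids=tuple(case_ids))


def build_cohort(
    cases: Sequence[CaseRecordSet],
) -> tuple[list[TreatmentCycle], list[TreatmentCycle]]:
    """Build all per-case cycles and all per-patient joined cycles.

    Returns ``(case_cycles, joined_cycles)``; joined cycles appear in
    order of each patient's first case.
    """
    case_cycles = [build_case_cycle(c) for c in cases]
    by_patient: dict[str, list[TreatmentCycle]] = {}
    for cyc in case_cycles:
        by_patient.setdefault(cyc.patient_id, []).append(cyc)
    joined = [join_cycles(cycs, pid) for pid, cycs in by_patient.items()]
    return case_cycles, joined


def write_edgelist_tsv(cycle: TreatmentCycle, dest: Union[str, Path]) -> None:
    """Edge list as TSV: source_unit, target_unit, weight, multiplicity.

    Isolated vertices are appended as source-only rows so the vertex set
    round-trips.
    """
    lines = ["source_unit\ttarget_unit\tweight\tmultiplicity"]
    for u, v, data in sorted(cycle.graph.edges(data=True)):
        lines.append(f"{u}\t{v}\t{data['weight']}\t{data['multiplicity']}")
    for node in sorted(cycle.graph.nodes):
        if cycle.graph.degree(node) == 0:
            lines.append(f"{node}\t\t\t")
    Path(dest).write_text("\n".join(lines) + "\n")


def write_graphml(cycle: TreatmentCycle, dest: Union[str, Path]) -> None:
    """GraphML export with unit labels and edge weights as attributes."""
    g = cycle.graph.copy()
    g.graph["patient_id"] = cycle.patient_id
    g.graph["case_ids"] = ",".join(cycle.case_ids)
    for node in g.nodes:
        g.nodes[node]["unit_code"] = node
    nx.write_graphml(g, str(dest))
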