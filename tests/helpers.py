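"""Shared construction helpers and independent oracles for the tests.

The oracles here are deliberately hand-rolled (adjacency dicts, DFS,
permutation search) so they share no code path with the package's
networkx-based implementation.
"""

from __future__ import annotations

import datetime as dt
from itertools import permutations

import networkx as nx

from treatcycles.cycle_builder import TreatmentCycle
from treatcycles.records_io import StayRecord


def make_cycle(edges, extra_nodes=(), patient="P1", cases=("C1",), weight=1):
    """Build a TreatmentCycle directly from a directed edge list."""
    g = nx.DiGraph()
    for u, v in edges:
        g.add_edge(u, v, weight=weight, multiplicity=1)
    for n in extra_nodes:
        g.add_node(n)
    return TreatmentCycle(graph=g, patient_id=patient, case_ids=tuple(cases))


def directed_path(n, prefix="U"):
    """Directed path U0 -> U1 -> ... -> U(n-1)."""
    nodes = [f"{prefix}{i}" for i in range(n)]
    if n == 1:
        return make_cycle([], extra_nodes=nodes)
    return make_cycle(list(zip(nodes, nodes[1:])))


def directed_cycle_graph(n, prefix="U"):
    """Directed cycle U0 -> U1 -> ... -> U(n-1) -> U0."""
    nodes = [f"{prefix}{i}" for i in range(n)]
    edges = list(zip(nodes, nodes[1:])) + [(nodes[-1], nodes[0])]
    return make_cycle(edges)


def case_from_units(units, patient="P1", case="C1", start=dt.date(2010, 1, 1),
                    durations=None):
    """Stay records visiting ``units`` in order with given stay durations."""
    durations = durations or [1] * len(units)
    records = []
    acq = start
    for unit, dur in zip(units, durations):
        out = acq + dt.timedelta(days=dur)
        records.append(StayRecord(patient, case, unit, acq, out))
        acq = out
    return records


# ---------------------------------------------------------------- oracles

def oracle_has_directed_cycle(nodes, edges):
    """DFS three-colour cycle detection on an adjacency dict."""
    adj = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {n: WHITE for n in nodes}

    def visit(u):
        colour[u] = GREY
        for v in adj[u]:
            if colour[v] == GREY:
                return True
            if colour[v] == WHITE and visit(v):
                return True
        colour[u] = BLACK
        return False

    return any(colour[n] == WHITE and visit(n) for n in nodes)


def oracle_is_directed_path(nodes, edges):
    """True iff some vertex ordering makes the edge set exactly a path."""
    nodes = list(nodes)
    if len(nodes) < 2 or len(edges) != len(nodes) - 1:
        return False
    edge_set = set(edges)
    for perm in permutations(nodes):
        if set(zip(perm, perm[1:])) == edge_set:
            return True
    return False


def oracle_category(nodes, edges):
    """Structural category by brute force, mirroring the classifier's contract."""
    if not edges:
        return "empty"
    if oracle_has_directed_cycle(nodes, edges):
        return "cyclic"
    if oracle_is_directed_path(nodes, edges):
        return "linear_2" if len(nodes) == 2 else "linear_long"
    return "other"


def oracle_wiener(nodes, edges):
    """All-pairs BFS on the undirected adjacency dict, reachable pairs only."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    total = 0
    for src in nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        total += sum(dist.values())
    return total / 2.0
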