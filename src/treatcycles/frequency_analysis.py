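"""Occurrence counts of units and directed transitions across a cohort.

Two counting rules, matching their different uses:

* unit frequencies count a unit once per graph that passes a structural
  filter (by default the cyclic graphs) — "in how many of these graphs
  does ward X appear";
* transition frequencies count every consecutive record-level
  relocation across all cases, so a transfer that happened three times
  in one case contributes three.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cycle_builder import TreatmentCycle
from .records_io import CaseRecordSet
from .structure_classifier import CYCLIC, classify_cycle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyTable:
    """Labelled counts plus a deterministic descending ranking."""

    scope: str
    entries: dict

    @property
    def ranking(self) -> list:
        """(label, count) pairs, count descending, ties lexicographic."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))

    def __getitem__(self, label) -> int:
        return self.entries[label]

    def __len__(self) -> int:
        return len(self.entries)


def unit_frequencies(
    cycles: Iterable[TreatmentCycle],
    categories: Sequence[str] = (CYCLIC,),
    min_count: int = 1,
) -> FrequencyTable:
    """Count, per unit, the graphs of the given categories containing it.

    Each unit is counted once per graph (vertex occurrence, not record
    occurrence).  ``min_count`` drops rare units from the table, e.g.
    ``min_count=2`` keeps only units seen in more than one graph.
    """
    counter: Counter = Counter()
    n_kept = 0
    for cyc in cycles:
        if classify_cycle(cyc).category not in categories:
            continue
        n_kept += 1
        counter.update(cyc.units)
    if n_kept == 0:
        logger.warning("no graphs matched categories %s; empty table", list(categories))
    entries = {u: c for u, c in counter.items() if c >= min_count}
    return FrequencyTable(scope="units_in_" + "+".join(categories), entries=entries)


def transition_frequencies(cases: Iterable[CaseRecordSet]) -> FrequencyTable:
    """Count every consecutive differing-unit relocation across all cases.

    Counts are per occurrence: the sum over the table equals the total
    number of consecutive record pairs with differing units.
    """
    counter: Counter = Counter()
    for case in cases:
        for prev, nxt in zip(case.records, case.records[1:]):
            if prev.unit_code != nxt.unit_code:
                counter[(prev.unit_code, nxt.unit_code)] += 1
    return FrequencyTable(scope="transitions_cohort_wide", entries=dict(counter))


def unit_frequency_frame(table: FrequencyTable) -> pd.DataFrame:
    """Unit frequency table as a two-column frame (unit, frequency)."""
    return pd.DataFrame(
        [{"unit": label, "frequency": count} for label, count in table.ranking],
        columns=["unit", "frequency"],
    )


def transition_frequency_frame(table: FrequencyTable) -> pd.DataFrame:
    """Ranked transitions as (rank, frequency, source_unit, target_unit)."""
    rows = []
    for rank, ((src, dst), count) in enumerate(table.ranking, start=1):
        rows.append(
            {"rank": rank, "frequency": count, "source_unit": src, "target_unit": dst}
        )
    return pd.DataFrame(rows, columns=["rank", "frequency", "source_unit", "target_unit"])
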