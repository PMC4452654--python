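"""Synthetic stay-record cohorts with planted graph structure.

The generator emits spreadsheet-shaped cohorts with the statistical
profile of a paediatric diabetes service: a few hundred patients, most
cases consisting of a single stay (an empty graph — no relocation), a
minority with one relocation, few with longer chains, and rare returns
to an already-visited unit which plant directed cycles.  Alongside the
records it emits a ground-truth label per case so recovery of the
planted structure by the graph pipeline can be tested exactly.

Default proportions target roughly 12–13 % of case graphs having more
than one vertex, with 2-vertex linear graphs dominating the non-empty
ones, mirroring the cohort scale the pipeline is designed for
(about 300 patients, about 1,200 cases, about 1,500 records).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .records_io import StayRecord

#: Unit codes seen in the domain: intensive care (KIPI), paediatric
#: wards (KIB*, KIBE), outpatient/clinic codes and others.
DEFAULT_UNIT_ALPHABET: Tuple[str, ...] = (
    "FRGS",
    "FRH1",
    "FRY4",
    "HNSO",
    "KIB1",
    "KIB2",
    "KIB3",
    "KIB4",
    "KIBE",
    "KII2",
    "KIN3",
    "KIPI",
    "MEM1",
)

#: Records per case: overwhelmingly single-stay cases, a ~10.5 % share
#: of two-stay cases and a thin tail up to five stays, so that about
#: 12.6 % of case graphs are non-empty.
DEFAULT_RECORDS_PER_CASE: Tuple[Tuple[int, float], ...] = (
    (1, 0.874),
    (2, 0.105),
    (3, 0.012),
    (4, 0.005),
    (5, 0.004),
)

#: Stay durations in whole days: same-day discharges are rare, one to
#: fourteen days uniform otherwise.
DEFAULT_STAY_DURATION: Tuple[Tuple[int, float], ...] = ((0, 0.02),) + tuple(
    (d, 0.07) for d in range(1, 15)
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``mean_cases_per_patient`` drives a truncated geometric case count
    per patient; ``revisit_prob`` is the chance that a stay from the
    third record of a case onwards returns to an earlier unit of the
    same case, planting a directed cycle.  ``transition_bias`` maps
    (source, target) unit pairs to relative sampling weights, to
    concentrate transfers e.g. on intensive-care-to-ward moves.
    """

    n_patients: int = 298
    mean_cases_per_patient: float = 4.0
    max_cases_per_patient: int = 15
    records_per_case: Tuple[Tuple[int, float], ...] = DEFAULT_RECORDS_PER_CASE
    revisit_prob: float = 0.03
    unit_alphabet: Tuple[str, ...] = DEFAULT_UNIT_ALPHABET
    transition_bias: Optional[Mapping[Tuple[str, str], float]] = None
    stay_duration: Tuple[Tuple[int, float], ...] = DEFAULT_STAY_DURATION
    start_date: _dt.date = _dt.date(2005, 1, 1)
    end_date: _dt.date = _dt.date(2013, 12, 31)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not self.unit_alphabet:
            raise ValueError("unit alphabet must be non-empty")
        if not 0.0 <= self.revisit_prob <= 1.0:
            raise ValueError("revisit_prob must lie in [0, 1]")
        if self.mean_cases_per_patient < 1.0:
            raise ValueError("mean_cases_per_patient must be >= 1")
        if self.max_cases_per_patient < 1:
            raise ValueError("max_cases_per_patient must be >= 1")
        for dist, name in (
            (self.records_per_case, "records_per_case"),
            (self.stay_duration, "stay_duration"),
        ):
            probs = [p for _, p in dist]
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must be a distribution")
        max_records = max(n for n, _ in self.records_per_case)
        if max_records > len(self.unit_alphabet):
            raise ValueError("unit alphabet smaller than longest possible case")
        if self.end_date <= self.start_date:
            raise ValueError("end_date must follow start_date")


@dataclass(frozen=True)
class CaseTruth:
    """Planted structure of one generated case."""

    patient_id: str
    case_id: str
    category: str  # empty / linear_2 / linear_long / cyclic
    n_records: int
    transitions: Tuple[Tuple[str, str], ...]


def _sample_categorical(rng: np.random.Generator, dist: Sequence[Tuple[int, float]]) -> int:
    values = [v for v, _ in dist]
    probs = np.asarray([p for _, p in dist], dtype=float)
    return int(rng.choice(values, p=probs / probs.sum()))


def _next_unit(
    rng: np.random.Generator,
    current: str,
    candidates: Sequence[str],
    bias: Optional[Mapping[Tuple[str, str], float]],
) -> str:
    if not candidates:
        raise ValueError("no candidate units to choose from")
    if bias:
        weights = np.asarray(
            [bias.get((current, c), 1.0) for c in candidates], dtype=float
        )
        weights = weights / weights.sum()
        return str(rng.choice(list(candidates), p=weights))
    return str(rng.choice(list(candidates)))


def _case_unit_sequence(
    rng: np.random.Generator, spec: CohortSpec, n_records: int
) -> tuple[list, str]:
    """Draw the unit sequence of one case and its implied category."""
    alphabet = list(spec.unit_alphabet)
    first = str(rng.choice(alphabet))
    units = [first]
    planted_cycle = False
    for i in range(1, n_records):
        current = units[-1]
        earlier = [u for u in set(units[:-1]) if u != current]
        if earlier and rng.random() < spec.revisit_prob:
            units.append(_next_unit(rng, current, sorted(earlier), spec.transition_bias))
            planted_cycle = True
        else:
            fresh = [u for u in alphabet if u not in units]
            units.append(_next_unit(rng, current, fresh, spec.transition_bias))
    if planted_cycle:
        category = "cyclic"
    elif n_records == 1:
        category = "empty"
    elif n_records == 2:
        category = "linear_2"
    else:
        category = "linear_long"
    return units, category


def generate_cohort(spec: CohortSpec) -> tuple[list, list]:
    """Generate a cohort of stay records plus its ground truth.

    Deterministic given ``spec.seed``.  Stays within a case never
    overlap: each acquisition date is on or after the previous outgoing
    date.  Returns ``(records, truths)`` where ``truths`` holds one
    :class:`CaseTruth` per case.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p_geom = min(1.0, 1.0 / spec.mean_cases_per_patient)
    horizon_days = (spec.end_date - spec.start_date).days

    records: list[StayRecord] = []
    truths: list[CaseTruth] = []
    case_counter = 0
    for p in range(1, spec.n_patients + 1):
        patient_id = f"PAT{p:05d}"
        n_cases = min(int(rng.geometric(p_geom)), spec.max_cases_per_patient)
        for _ in range(n_cases):
            case_counter += 1
            case_id = f"FAL{case_counter:05d}"
            n_records = _sample_categorical(rng, spec.records_per_case)
            units, category = _case_unit_sequence(rng, spec, n_records)

            # dates: leave room for the longest possible case
            slack = max(horizon_days - 120, 1)
            acq = spec.start_date + _dt.timedelta(days=int(rng.integers(0, slack)))
            case_records = []
            for unit in units:
                duration = _sample_categorical(rng, spec.stay_duration)
                out = acq + _dt.timedelta(days=duration)
                case_records.append(
                    StayRecord(
                        patient_id=patient_id,
                        case_id=case_id,
                        unit_code=unit,
                        acquisition_date=acq,
                        outgoing_date=out,
                    )
                )
                gap = int(rng.integers(0, 3))
                acq = out + _dt.timedelta(days=gap)
            records.extend(case_records)
            transitions = tuple(
                (a, b) for a, b in zip(units, units[1:]) if a != b
            )
            truths.append(
                CaseTruth(
                    patient_id=patient_id,
                    case_id=case_id,
                    category=category,
                    n_records=n_records,
                    transitions=transitions,
                )
            )
    return records, truths


def write_ground_truth(truths: Sequence[CaseTruth], dest: Union[str, Path]) -> None:
    """Ground truth as JSON, one object per case."""
    payload = [
        {
            "patient_id": t.patient_id,
            "case_id": t.case_id,
            "category": t.category,
            "n_records": t.n_records,
            "transitions": [list(pair) for pair in t.transitions],
        }
        for t in truths
    ]
    Path(dest).write_text(json.dumps(payload, indent=1) + "\n")


def worked_example_fixture() -> list:
    """The seven-case worked example for patient PAT00001.

    Case FAL00002 carries its documented dates (two stays in late 2005,
    durations 1 and 6 days, relocation weight 6).  The other six cases
    carry synthetic, date-consistent stays invented for this fixture;
    case FAL00009 is constructed with stay durations 1, 3 and 14 days
    so its two relocation weights are 3 and 12.
    """
    d = _dt.date

    def rec(case: str, unit: str, acq: _dt.date, out: _dt.date) -> StayRecord:
        return StayRecord("PAT00001", case, unit, acq, out)

    return [
        rec("FAL00001", "KIBE", d(2005, 1, 12), d(2005, 1, 15)),
        rec("FAL00002", "FRY4", d(2005, 11, 3), d(2005, 11, 4)),
        rec("FAL00002", "FRH1", d(2005, 11, 4), d(2005, 11, 10)),
        rec("FAL00004", "KIB3", d(2006, 3, 2), d(2006, 3, 5)),
        rec("FAL00007", "KIN3", d(2007, 6, 10), d(2007, 6, 11)),
        rec("FAL00009", "KIB3", d(2008, 2, 1), d(2008, 2, 2)),
        rec("FAL00009", "FRH1", d(2008, 2, 2), d(2008, 2, 5)),
        rec("FAL00009", "FRGS", d(2008, 2, 5), d(2008, 2, 19)),
        rec("FAL00013", "HNSO", d(2009, 4, 3), d(2009, 4, 4)),
        rec("FAL00013", "KIB3", d(2009, 4, 4), d(2009, 4, 6)),
        rec("FAL00015", "MEM1", d(2010, 8, 20), d(2010, 8, 22)),
    ]
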