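"""Reading, validating and writing hospital stay-record spreadsheets.

A stay record is one spreadsheet row: a patient identifier, a case
(treatment-episode) identifier, the code of the nursing organizational
unit the patient occupied, and the acquisition (admission to the unit)
and outgoing (departure from the unit) dates.  A patient may have many
cases; a case may have many records, one per unit occupied.
"""

from __future__ import annotations

import csv as _csv
import datetime as _dt
import io
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Column headers as they appear in the source spreadsheet.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "patient_id": "Patient ID",
    "case_id": "Case",
    "unit_code": "Nursing term",
    "acquisition_date": "Acquisition Date OE",
    "outgoing_date": "Outgoing Date pfl. OE",
}

#: Day-first dotted dates, the dialect of the source export.
DEFAULT_DATE_FORMAT = "%d.%m.%Y"

#: ISO-8601, used for normalized output.
ISO_DATE_FORMAT = "%Y-%m-%d"


class StayRecordFormatError(ValueError):
    """The input file cannot be interpreted at all (e.g. missing column)."""


@dataclass(frozen=True)
class StayRecord:
    """One stay of one patient in one nursing organizational unit.

    Invariants: identifiers and the unit code are non-empty, and the
    outgoing date is never before the acquisition date.
    """

    patient_id: str
    case_id: str
    unit_code: str
    acquisition_date: _dt.date
    outgoing_date: _dt.date

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not self.unit_code:
            raise ValueError("unit_code must be non-empty")
        if self.outgoing_date < self.acquisition_date:
            raise ValueError(
                f"outgoing date {self.outgoing_date} precedes acquisition "
                f"date {self.acquisition_date}"
            )


@dataclass(frozen=True)
class CaseRecordSet:
    """All stay records of one case, in temporal order."""

    case_id: str
    patient_id: str
    records: tuple

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("a case must contain at least one record")
        for r in self.records:
            if r.case_id != self.case_id or r.patient_id != self.patient_id:
                raise ValueError(
                    "all records of a case must share its patient and case id"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class RowIssue:
    """A per-row validation problem, keyed by the 1-based file row."""

    row: int
    message: str


@dataclass
class ReadResult:
    """Validated records plus the per-row issues collected on the way."""

    records: list = field(default_factory=list)
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_stay_records(
    source: Union[str, Path, io.TextIOBase],
    column_map: Mapping[str, str] | None = None,
    date_format: str = DEFAULT_DATE_FORMAT,
    delimiter: str | None = None,
) -> ReadResult:
    """Parse a stay-record CSV into validated :class:`StayRecord` objects.

    Parameters
    ----------
    source
        Path or open text stream of a delimited file with a header row.
    column_map
        Maps the five logical field names to the file's column headers;
        defaults to :data:`DEFAULT_COLUMNS`.
    date_format
        ``strptime`` format of both date columns (default day-first dotted).
    delimiter
        Field separator; ``None`` autodetects comma vs semicolon.

    Rows violating the record invariants are rejected and reported in
    ``result.errors`` with their file row numbers; the file order of the
    accepted records is preserved.  A missing mapped column raises
    :class:`StayRecordFormatError`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    try:
        frame = pd.read_csv(
            source,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return ReadResult()
    except _csv.Error:
        # the dialect sniffer cannot handle blank input
        return ReadResult()
    except pd.errors.ParserError as exc:
        raise StayRecordFormatError(f"cannot parse input: {exc}") from exc

    frame.columns = [str(c).strip() for c in frame.columns]
    missing = [h for h in cols.values() if h not in frame.columns]
    if missing:
        raise StayRecordFormatError(
            f"missing required column(s): {missing}; found {list(frame.columns)}"
        )

    result = ReadResult()
    seen: dict[tuple, int] = {}
    for idx in range(len(frame)):
        file_row = idx + 2  # header is row 1
        values = {k: str(frame.iloc[idx][h]).strip() for k, h in cols.items()}
        try:
            acq = _dt.datetime.strptime(values["acquisition_date"], date_format).date()
            out = _dt.datetime.strptime(values["outgoing_date"], date_format).date()
        except ValueError as exc:
            result.errors.append(RowIssue(file_row, f"unparseable date: {exc}"))
            continue
        try:
            record = StayRecord(
                patient_id=values["patient_id"],
                case_id=values["case_id"],
                unit_code=values["unit_code"],
                acquisition_date=acq,
                outgoing_date=out,
            )
        except ValueError as exc:
            result.errors.append(RowIssue(file_row, str(exc)))
            continue

        key = (record.patient_id, record.case_id, record.unit_code, acq, out)
        if key in seen:
            # duplicates may encode genuine re-admissions: keep, but flag
            msg = f"duplicate of row {seen[key]} kept: {key}"
            result.warnings.append(RowIssue(file_row, msg))
            logger.warning("row %d: %s", file_row, msg)
        else:
            seen[key] = file_row
        result.records.append(record)
    return result


def write_stay_records(
    records: Iterable[StayRecord],
    dest: Union[str, Path, io.TextIOBase],
    column_map: Mapping[str, str] | None = None,
    date_format: str = ISO_DATE_FORMAT,
    delimiter: str = ",",
) -> None:
    """Write records as delimited text; ISO-8601 dates by default.

    Writing then reading with the same dialect is the identity on all
    record fields.
    """
    records = list(records)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = pd.DataFrame(
        {
            cols["patient_id"]: [r.patient_id for r in records],
            cols["case_id"]: [r.case_id for r in records],
            cols["unit_code"]: [r.unit_code for r in records],
            cols["acquisition_date"]: [
                r.acquisition_date.strftime(date_format) for r in records
            ],
            cols["outgoing_date"]: [
                r.outgoing_date.strftime(date_format) for r in records
            ],
        }
    )
    frame.to_csv(dest, sep=delimiter, index=False)


def group_into_cases(records: Sequence[StayRecord]) -> list:
    """Partition records into per-case sets, each in temporal order.

    Grouping key is the (patient, case) pair; groups appear in order of
    first appearance in the input.  Within a case, records sort by
    acquisition date, ties broken by outgoing date, then by original
    input position (stable).
    """
    buckets: "OrderedDict[tuple, list]" = OrderedDict()
    for pos, rec in enumerate(records):
        buckets.setdefault((rec.patient_id, rec.case_id), []).append((pos, rec))

    cases = []
    for (patient_id, case_id), entries in buckets.items():
        entries.sort(key=lambda e: (e[1].acquisition_date, e[1].outgoing_date, e[0]))
        cases.append(
            CaseRecordSet(
                case_id=case_id,
                patient_id=patient_id,
                records=tuple(rec for _, rec in entries),
            )
        )
    return cases


def overlapping_stays(case: CaseRecordSet) -> list:
    """Pairs of consecutive records whose stays overlap in time.

    The next stay normally begins on or after the previous outgoing
    date; overlaps are reported (not rejected) so a validation log can
    surface them.
    """
    overlaps = []
    for prev, nxt in zip(case.records, case.records[1:]):
        if nxt.acquisition_date < prev.outgoing_date:
            overlaps.append((prev, nxt))
    return overlaps
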