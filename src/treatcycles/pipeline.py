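"""End-to-end pipeline: records -> graphs -> classification -> reports.

Orchestrates the library stages over either a stay-record CSV or a
synthetic cohort specification and writes a reproducible report bundle
(normalized records, per-graph exports, cohort summary, index table,
extremal report, frequency tables, run log) into an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from . import cycle_builder, frequency_analysis, graph_indices, records_io
from . import structure_classifier as sc
from . import synthetic_data

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Fatal pipeline condition (unreadable input, no valid records)."""


@dataclass
class PipelineConfig:
    """What to run and where; exactly one input source must be set."""

    input_csv: Optional[Union[str, Path]] = None
    synthetic_spec: Optional[synthetic_data.CohortSpec] = None
    outdir: Union[str, Path] = "treatcycles_report"
    column_map: Optional[Mapping[str, str]] = None
    date_format: str = records_io.DEFAULT_DATE_FORMAT
    delimiter: Optional[str] = None
    seed: int = 0
    export_graphs: bool = False  # per-graph GraphML/TSV exports
    analyses: Sequence[str] = ("classify", "indices", "frequencies", "extremal")

    def validate(self) -> None:
        if (self.input_csv is None) == (self.synthetic_spec is None):
            raise ValueError("set exactly one of input_csv / synthetic_spec")


@dataclass
class ReportBundle:
    """Paths of the written artefacts plus the in-memory results."""

    outdir: Path
    paths: dict = field(default_factory=dict)
    summary: Optional[sc.CohortSummary] = None
    n_records: int = 0
    n_cases: int = 0
    n_patients: int = 0
    n_validation_errors: int = 0


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all configured stages and write the report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # ingest
    if config.input_csv is not None:
        source = Path(config.input_csv)
        if not source.exists():
            raise PipelineError(f"input file not found: {source}")
        result = records_io.read_stay_records(
            source,
            column_map=config.column_map,
            date_format=config.date_format,
            delimiter=config.delimiter,
        )
        records = result.records
        for issue in result.errors:
            log(f"row {issue.row}: REJECTED: {issue.message}")
        for issue in result.warnings:
            log(f"row {issue.row}: warning: {issue.message}")
        n_errors = len(result.errors)
    else:
        spec = dataclasses.replace(config.synthetic_spec, seed=config.seed)
        records, truths = synthetic_data.generate_cohort(spec)
        synthetic_data.write_ground_truth(truths, outdir / "ground_truth.json")
        n_errors = 0
    if not records:
        raise PipelineError("no valid stay records in input")

    bundle = ReportBundle(outdir=outdir, n_records=len(records), n_validation_errors=n_errors)

    normalized = outdir / "records_normalized.csv"
    records_io.write_stay_records(records, normalized)
    bundle.paths["records"] = normalized

    # graphs
    cases = records_io.group_into_cases(records)
    for case in cases:
        for prev, nxt in records_io.overlapping_stays(case):
            log(
                f"case {case.case_id}: overlapping stays "
                f"{prev.unit_code}({prev.acquisition_date}..{prev.outgoing_date}) / "
                f"{nxt.unit_code}({nxt.acquisition_date}..{nxt.outgoing_date})"
            )
    case_cycles, joined_cycles = cycle_builder.build_cohort(cases)
    bundle.n_cases = len(case_cycles)
    bundle.n_patients = len(joined_cycles)
    log(f"{len(records)} records, {len(case_cycles)} case graphs, "
        f"{len(joined_cycles)} joined graphs")

    if config.export_graphs:
        graph_dir = outdir / "graphs"
        graph_dir.mkdir(exist_ok=True)
        for cyc in case_cycles:
            stem = f"case_{cyc.patient_id}_{cyc.case_ids[0]}"
            cycle_builder.write_edgelist_tsv(cyc, graph_dir / f"{stem}.tsv")
            cycle_builder.write_graphml(cyc, graph_dir / f"{stem}.graphml")
        for cyc in joined_cycles:
            stem = f"joined_{cyc.patient_id}"
            cycle_builder.write_edgelist_tsv(cyc, graph_dir / f"{stem}.tsv")
            cycle_builder.write_graphml(cyc, graph_dir / f"{stem}.graphml")
        bundle.paths["graphs"] = graph_dir

    # classification and summary
    if "classify" in config.analyses:
        summary = sc.summarize_cohort(case_cycles, joined_cycles)
        summary.cases.validate()
        summary.joined.validate()
        bundle.summary = summary
        path = outdir / "cohort_summary.csv"
        summary.to_frame().to_csv(path, index=False)
        bundle.paths["summary"] = path
        for name, cycles in (("cases", case_cycles), ("joined", joined_cycles)):
            tpath = outdir / f"classification_{name}.tsv"
            sc.classification_table(cycles).to_csv(tpath, sep="\t", index=False)
            bundle.paths[f"classification_{name}"] = tpath
        log(
            f"case graphs: {summary.cases.n_with_more_than_one_vertex} with |V|>1 "
            f"({summary.cases.n_linear_2} linear-2, {summary.cases.n_linear_long} "
            f"linear-long, {summary.cases.n_cyclic} cyclic, {summary.cases.n_other} other)"
        )

    # indices
    if "indices" in config.analyses:
        path = outdir / "index_table.csv"
        graph_indices.index_table(case_cycles + joined_cycles).to_csv(path, index=False)
        bundle.paths["indices"] = path

    if "extremal" in config.analyses:
        report = {}
        for index_name in ("wiener", "randic_directed"):
            try:
                ext = graph_indices.find_extremal(case_cycles, index_name)
            except ValueError as exc:
                report[index_name] = {"error": str(exc)}
                continue
            report[index_name] = {
                "min_value": ext.min_value,
                "max_value": ext.max_value,
                "min_graphs": [c.provenance for c in ext.min_graphs],
                "max_graphs": [c.provenance for c in ext.max_graphs],
            }
        path = outdir / "extremal.json"
        path.write_text(json.dumps(report, indent=1) + "\n")
        bundle.paths["extremal"] = path

    # frequencies
    if "frequencies" in config.analyses:
        units = frequency_analysis.unit_frequencies(case_cycles)
        upath = outdir / "unit_frequencies.csv"
        frequency_analysis.unit_frequency_frame(units).to_csv(upath, index=False)
        bundle.paths["unit_frequencies"] = upath
        transitions = frequency_analysis.transition_frequencies(cases)
        tpath = outdir / "transition_frequencies.csv"
        frequency_analysis.transition_frequency_frame(transitions).to_csv(
            tpath, index=False
        )
        bundle.paths["transition_frequencies"] = tpath

    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    bundle.paths["log"] = log_path
    return bundle
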