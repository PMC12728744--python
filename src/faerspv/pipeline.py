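"""End-to-end pipeline: quarters in, signal/onset/descriptive tables out.

Stages mirror the standard spontaneous-report workflow: read → case-level
deduplication → deleted-case removal → target-cohort selection →
(report, PT) event table → SOC- and PT-level disproportionality with the
four-algorithm battery → unintended-AE annotation against a label PT
list → time-to-onset → descriptive characterisation → sex-stratified
signals.  A manifest records the report funnel (raw → deduplicated →
target cohort → event records), input hashes, the config and package
versions, so a run is auditable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
from typing import Dict, List, Optional, Sequence, Set

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__ as _pkg_version
from .cohort import build_event_table, build_report_cases, select_target_reports
from .dedup import apply_deletions, deduplicate
from .describe import describe_cohort, stratified_signals, yearly_trend
from .io import (
    VocabularyMap,
    normalize_pt,
    read_deletion_list,
    read_table,
    write_signal_table,
)
from .onset import OnsetRecord, compute_onset, summarize_onset
from .records import DemoRecord, DrugRecord, RoleCode, TherRecord
from .stats import signal_table

logger = logging.getLogger("faerspv")

__all__ = ["PipelineConfig", "run_pipeline", "flag_unintended", "analyze_extract"]

TABLE_FILES = {
    "DEMO": "DEMO.txt", "DRUG": "DRUG.txt", "REAC": "REAC.txt",
    "THER": "THER.txt", "INDI": "INDI.txt", "OUTC": "OUTC.txt",
}


class PipelineConfig(BaseModel):
    """Declarative run configuration (YAML on disk; CLI flags override
    keys one-to-one)."""

    quarters: List[str]
    vocabulary: str
    outdir: str
    deleted_list: Optional[str] = None
    expected_pts: Optional[str] = None
    keywords: List[str] = Field(default_factory=lambda: ["donepezil"])
    role: str = "PS"
    zero_cell_policy: str = "undefined"
    unmapped_policy: str = "unmapped"
    onset_date_field: str = "event_dt"
    subgroup_contrast: str = "within_stratum"
    top_k_subgroup: Optional[int] = 30
    top_k_descriptive: int = 5
    trend_groups: Dict[str, List[str]] = Field(
        default_factory=lambda: {"USA": ["US", "USA"], "GBR": ["GB", "GBR"]}
    )
    trend_scale_factor: float = 0.25
    min_count: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def flag_unintended(table: pd.DataFrame, expected_pts: Set[str]) -> pd.DataFrame:
    """Annotate a PT-level signal table with ``unintended`` = the PT is
    absent from the expected (drug-label) list, compared after
    normalisation.  An empty expected set marks everything unintended."""
    expected = {normalize_pt(p) for p in expected_pts}
    out = table.copy()
    out["unintended"] = ~out["pt"].astype(str).map(normalize_pt).isin(expected)
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def target_onset_records(
    demo: Sequence[DemoRecord],
    drugs: Sequence[DrugRecord],
    thers: Sequence[TherRecord],
    targets: Set[int],
    keywords: Sequence[str],
    role: RoleCode = RoleCode.PS,
) -> List[OnsetRecord]:
    """Time-to-onset for each target report.

    Therapy start is taken from the THER rows linked (via drug sequence)
    to the keyword-matched suspect drug; when several qualify, the
    earliest full start date is used.  The event date comes from the DEMO
    record.
    """
    from .cohort import match_drug

    seqs_by_pid: Dict[int, Set[int]] = {}
    for d in drugs:
        if d.primaryid in targets and d.role_code == role and match_drug(d, keywords):
            seqs_by_pid.setdefault(d.primaryid, set()).add(d.drug_seq)
    start_by_pid: Dict[int, object] = {}
    for t in thers:
        seqs = seqs_by_pid.get(t.primaryid)
        if seqs is None or t.dsg_drug_seq not in seqs or t.start_dt is None:
            continue
        prev = start_by_pid.get(t.primaryid)
        if t.start_dt.is_full and (
            prev is None or not prev.is_full or t.start_dt.to_date() < prev.to_date()
        ):
            start_by_pid[t.primaryid] = t.start_dt
        elif prev is None:
            start_by_pid[t.primaryid] = t.start_dt
    event_by_pid = {r.primaryid: r.event_dt for r in demo if r.primaryid in targets}
    records = []
    for pid in sorted(targets):
        records.append(
            compute_onset(event_by_pid.get(pid), start_by_pid.get(pid), primaryid=pid)
        )
    return records


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full pipeline and write all output tables.

    Returns a result dict with the main in-memory objects (event table,
    signal tables, onset summary, cohort summary, manifest).  Any fatal
    stage error removes partial outputs and re-raises with the stage
    name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    created: List[str] = []
    stage = "setup"
    try:
        # ---- read ----------------------------------------------------------
        stage = "read"
        tables: Dict[str, list] = {k: [] for k in TABLE_FILES}
        load_reports = []
        input_hashes = {}
        for qdir in config.quarters:
            for kind, fname in TABLE_FILES.items():
                path = os.path.join(qdir, fname)
                if not os.path.exists(path):
                    if kind in ("DEMO", "DRUG", "REAC"):
                        raise FileNotFoundError(f"required table missing: {path}")
                    continue
                recs, rep = read_table(path, kind)
                tables[kind].extend(recs)
                load_reports.append(rep)
                input_hashes[path] = _sha256(path)
        vocab = VocabularyMap.from_file(config.vocabulary)
        input_hashes[config.vocabulary] = _sha256(config.vocabulary)

        # ---- dedup ---------------------------------------------------------
        stage = "deduplication"
        dedup = deduplicate(tables["DEMO"])
        if config.deleted_list:
            deleted = read_deletion_list(config.deleted_list)
            dedup = apply_deletions(dedup, deleted)
            input_hashes[config.deleted_list] = _sha256(config.deleted_list)
        else:
            logger.info("no deleted-case list supplied; deletion step skipped")
        retained = dedup.retained_primaryids

        # ---- cohort --------------------------------------------------------
        stage = "cohort"
        role = RoleCode(config.role)
        targets = select_target_reports(tables["DRUG"], retained, config.keywords, role)
        events = build_event_table(
            tables["REAC"], retained, targets, vocab, config.unmapped_policy
        )

        # ---- signals -------------------------------------------------------
        stage = "signals"
        soc_table = signal_table(events, level="SOC", min_count=config.min_count,
                                 zero_cell_policy=config.zero_cell_policy)
        pt_table = signal_table(events, level="PT", min_count=config.min_count,
                                zero_cell_policy=config.zero_cell_policy)
        if config.expected_pts:
            with open(config.expected_pts, "r", encoding="utf-8") as fh:
                expected = {line.strip() for line in fh if line.strip()}
            input_hashes[config.expected_pts] = _sha256(config.expected_pts)
            pt_table = flag_unintended(pt_table, expected)

        # ---- onset ---------------------------------------------------------
        stage = "onset"
        onset_records = target_onset_records(
            tables["DEMO"], tables["DRUG"], tables["THER"], targets,
            config.keywords, role,
        )
        onset_summary = summarize_onset(onset_records)

        # ---- descriptive ---------------------------------------------------
        stage = "descriptive"
        cases = build_report_cases(
            tables["DEMO"], retained, targets, tables["OUTC"], tables["INDI"]
        )
        target_cases = [c for c in cases if c.is_target]
        cohort_summary = describe_cohort(target_cases, top_k=config.top_k_descriptive)
        trend = yearly_trend(
            target_cases,
            {k: set(v) for k, v in config.trend_groups.items()},
            config.trend_scale_factor,
        )

        # ---- subgroup ------------------------------------------------------
        stage = "subgroup"
        subgroup = {
            s: stratified_signals(
                events, cases, s, top_k=config.top_k_subgroup,
                contrast=config.subgroup_contrast,
                zero_cell_policy=config.zero_cell_policy,
                min_count=config.min_count,
            )
            for s in ("female", "male")
        }

        # ---- write ---------------------------------------------------------
        stage = "write"
        manifest = {
            "package_version": _pkg_version,
            "config": config.model_dump(),
            "input_sha256": input_hashes,
            "load_reports": [
                {"table": r.table, "lines_read": r.lines_read,
                 "records_kept": r.records_kept, "records_skipped": r.records_skipped,
                 "skip_reasons": dict(r.skip_reasons)}
                for r in load_reports
            ],
            "funnel": {
                "raw_reports": dedup.n_input,
                "removed_as_duplicate": dedup.removed_as_duplicate,
                "removed_as_deleted": dedup.removed_as_deleted,
                "deduplicated_reports": len(retained),
                "target_reports": len(targets),
                "event_records": int(len(events)),
                "target_event_records": int(events["is_target"].sum()) if len(events) else 0,
            },
        }
        logger.info("funnel: %s", json.dumps(manifest["funnel"]))

        def _out(name):
            p = os.path.join(outdir, name)
            created.append(p)
            return p

        write_signal_table(soc_table.rename(columns={"soc": "soc"}), _out("signals_soc.tsv"))
        write_signal_table(pt_table, _out("signals_pt.tsv"))
        pt_table.to_json(_out("signals_pt.json"), orient="records", indent=1)
        with open(_out("onset_summary.json"), "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(onset_summary), fh, indent=1)
        pd.DataFrame(
            {"bin": list(onset_summary.bin_counts),
             "count": list(onset_summary.bin_counts.values())}
        ).to_csv(_out("onset_bins.tsv"), sep="\t", index=False)
        with open(_out("cohort_summary.json"), "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(cohort_summary), fh, indent=1)
        trend.to_csv(_out("yearly_trend.tsv"), sep="\t", index=False)
        for s, tab in subgroup.items():
            write_signal_table(tab, _out(f"signals_{s}.tsv"))
        with open(_out("manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

        return {
            "events": events,
            "soc_table": soc_table,
            "pt_table": pt_table,
            "onset_records": onset_records,
            "onset_summary": onset_summary,
            "cohort_summary": cohort_summary,
            "trend": trend,
            "subgroup": subgroup,
            "manifest": manifest,
            "dedup": dedup,
            "targets": targets,
        }
    except Exception as exc:
        for p in created:
            if os.path.exists(p):
                os.remove(p)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def analyze_extract(extract, keywords: Optional[Sequence[str]] = None,
                    zero_cell_policy: str = "undefined"):
    """In-memory analysis of a synthetic extract (no file round-trip):
    dedup → deletions → cohort → event table.  Returns ``(events, dedup,
    targets)``; the signal batteries run on ``events`` as usual.

    Used for repeated-simulation studies where writing and re-reading the
    ASCII files thousands of times would dominate the runtime; the file
    route is exercised separately.
    """
    cfg = extract.config
    keywords = list(keywords) if keywords else [cfg.target_drugname.lower()]
    dd = deduplicate(extract.demo[["primaryid", "caseid", "fda_dt"]])
    dd = apply_deletions(dd, extract.truth.deleted_caseids)
    retained = dd.retained_primaryids
    targets = select_target_reports(extract.drug, retained, keywords)
    events = build_event_table(extract.reac, retained, targets, extract.vocab)
    return events, dd, targets
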