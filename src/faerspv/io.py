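"""Readers and writers for the FAERS ASCII dialect.

FAERS quarterly files are ``$``-delimited with a header row and no quoting
mechanism; a free-text field containing ``$`` shifts every later column, so
such lines are skipped and counted rather than guessed at.  Only the
primaryid-era schema (2004 Q1 onward restructured files) is supported.
Column names are matched case-insensitively and a few era synonyms are
aliased (``gndr_cod`` for ``sex``, ``role_cod``/``role_code`` …).
"""

from __future__ import annotations

import decimal
import os
from typing import Optional, Sequence, Union

import pandas as pd

from .records import (
    AgeCode,
    DemoRecord,
    DrugRecord,
    IndiRecord,
    LoadReport,
    OutcRecord,
    OutcomeCode,
    PartialDate,
    ReacRecord,
    RoleCode,
    Sex,
    TherRecord,
    parse_partial_date,
)

__all__ = [
    "read_table",
    "read_vocabulary",
    "read_deletion_list",
    "write_table",
    "write_signal_table",
    "read_signal_table",
    "VocabularyMap",
    "normalize_pt",
    "round_half_up",
    "FormatError",
]

DELIM = "$"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC")

# canonical column -> accepted header aliases (lowercased)
_ALIASES = {
    "primaryid": ("primaryid",),
    "caseid": ("caseid",),
    "fda_dt": ("fda_dt",),
    "event_dt": ("event_dt",),
    "sex": ("sex", "gndr_cod"),
    "age": ("age",),
    "age_cod": ("age_cod", "age_code"),
    "occp_cod": ("occp_cod", "occp_code", "reporter_occupation"),
    "occr_country": ("occr_country", "reporter_country", "country"),
    "drug_seq": ("drug_seq", "drugseq"),
    "role_cod": ("role_cod", "role_code"),
    "drugname": ("drugname",),
    "prod_ai": ("prod_ai",),
    "pt": ("pt",),
    "dsg_drug_seq": ("dsg_drug_seq",),
    "start_dt": ("start_dt",),
    "end_dt": ("end_dt",),
    "outc_cod": ("outc_cod", "outc_code"),
    "indi_drug_seq": ("indi_drug_seq",),
    "indi_pt": ("indi_pt", "indication_pt"),
}

# required key columns per table kind
_REQUIRED = {
    "DEMO": ("primaryid", "caseid"),
    "DRUG": ("primaryid", "caseid", "drugname"),
    "REAC": ("primaryid", "caseid", "pt"),
    "THER": ("primaryid", "caseid", "dsg_drug_seq"),
    "INDI": ("primaryid", "caseid", "indi_pt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
}

_OCCUPATIONS = {
    "MD": "physician",
    "PH": "pharmacist",
    "HP": "other health professional",
    "CN": "consumer/other",
    "OT": "consumer/other",
    "LW": "consumer/other",
}


class FormatError(ValueError):
    """Fatal file-format problem (missing key column, unreadable header)."""


def normalize_pt(pt: str) -> str:
    """Normalise a MedDRA preferred-term string for joins: trim, collapse
    internal whitespace, casefold.  Display casing is kept elsewhere."""
    return " ".join(pt.split()).casefold()


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals, the convention
    used in published signal tables (banker's rounding would turn 2.265
    into 2.26)."""
    if x != x or x in (float("inf"), float("-inf")):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _resolve_columns(header: Sequence[str], table_kind: str) -> dict:
    lower = [h.strip().lower() for h in header]
    pos = {}
    for canon, aliases in _ALIASES.items():
        for a in aliases:
            if a in lower:
                pos[canon] = lower.index(a)
                break
    missing = [c for c in _REQUIRED[table_kind] if c not in pos]
    if missing:
        raise FormatError(
            f"{table_kind} table is missing required column(s): {', '.join(missing)}"
        )
    return pos


def _get(parts: Sequence[str], pos: dict, col: str) -> Optional[str]:
    i = pos.get(col)
    if i is None or i >= len(parts):
        return None
    v = parts[i].strip()
    return v or None


def _int_or_none(v: Optional[str]) -> Optional[int]:
    if v is None:
        return None
    try:
        return int(v)
    except ValueError:
        return None


def read_table(path: Union[str, os.PathLike], table_kind: str):
    """Read one FAERS ASCII table into typed records.

    Returns ``(records, load_report)``.  Unknown columns are ignored,
    missing values become the missing sentinel of the field, and lines
    that cannot be parsed are skipped and counted in the load report —
    never silently dropped.  A missing *required* column is a fatal
    :class:`FormatError`.
    """
    table_kind = table_kind.upper()
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}; expected one of {TABLE_KINDS}")
    report = LoadReport(table=table_kind)
    records: list = []
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, no header")
        header = header_line.rstrip("\n").rstrip("\r").split(DELIM)
        pos = _resolve_columns(header, table_kind)
        ncols = len(header)
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            report.lines_read += 1
            parts = line.split(DELIM)
            if len(parts) != ncols:
                report.skip("field_count_mismatch")
                continue
            rec = _parse_record(parts, pos, table_kind, report)
            if rec is None:
                continue
            records.append(rec)
            report.records_kept += 1
    return records, report


def _parse_record(parts, pos, table_kind, report):
    primaryid = _int_or_none(_get(parts, pos, "primaryid"))
    caseid = _int_or_none(_get(parts, pos, "caseid"))
    if primaryid is None or caseid is None:
        report.skip("bad_key")
        return None
    if table_kind == "DEMO":
        fda_dt = parse_partial_date(_get(parts, pos, "fda_dt"))
        raw_fda = _get(parts, pos, "fda_dt")
        if raw_fda is not None and fda_dt is None:
            report.value_fixes["fda_dt_unparseable"] += 1
        raw_event = _get(parts, pos, "event_dt")
        event_dt = parse_partial_date(raw_event)
        if raw_event is not None and event_dt is None:
            report.value_fixes["event_dt_unparseable"] += 1
        sex_raw = _get(parts, pos, "sex")
        sex = Sex(sex_raw) if sex_raw in ("F", "M") else Sex.UNK
        age_value = None
        raw_age = _get(parts, pos, "age")
        if raw_age is not None:
            try:
                age_value = float(raw_age)
            except ValueError:
                report.value_fixes["age_unparseable"] += 1
        age_cod_raw = _get(parts, pos, "age_cod")
        try:
            age_code = AgeCode(age_cod_raw) if age_cod_raw else None
        except ValueError:
            age_code = None
            report.value_fixes["age_cod_unknown"] += 1
        occ_raw = _get(parts, pos, "occp_cod")
        occupation = _OCCUPATIONS.get(occ_raw, occ_raw.lower() if occ_raw else None)
        return DemoRecord(
            primaryid=primaryid,
            caseid=caseid,
            fda_dt=fda_dt,
            event_dt=event_dt,
            sex=sex,
            age_value=age_value,
            age_code=age_code,
            reporter_occupation=occupation,
            country=_get(parts, pos, "occr_country"),
        )
    if table_kind == "DRUG":
        drugname = _get(parts, pos, "drugname")
        if drugname is None:
            report.skip("empty_drugname")
            return None
        role_raw = _get(parts, pos, "role_cod")
        try:
            role = RoleCode(role_raw) if role_raw else None
        except ValueError:
            role = None
            report.value_fixes["role_cod_unknown"] += 1
        return DrugRecord(
            primaryid=primaryid,
            caseid=caseid,
            drug_seq=_int_or_none(_get(parts, pos, "drug_seq")) or 1,
            role_code=role,
            drugname=drugname,
            prod_ai=_get(parts, pos, "prod_ai"),
        )
    if table_kind == "REAC":
        pt = _get(parts, pos, "pt")
        if pt is None:
            report.skip("empty_pt")
            return None
        return ReacRecord(primaryid=primaryid, caseid=caseid, pt=pt)
    if table_kind == "THER":
        return TherRecord(
            primaryid=primaryid,
            caseid=caseid,
            dsg_drug_seq=_int_or_none(_get(parts, pos, "dsg_drug_seq")) or 1,
            start_dt=parse_partial_date(_get(parts, pos, "start_dt")),
            end_dt=parse_partial_date(_get(parts, pos, "end_dt")),
        )
    if table_kind == "OUTC":
        raw = _get(parts, pos, "outc_cod")
        try:
            code = OutcomeCode(raw)
        except ValueError:
            report.skip("unknown_outcome_code")
            return None
        return OutcRecord(primaryid=primaryid, caseid=caseid, outcome_code=code)
    if table_kind == "INDI":
        pt = _get(parts, pos, "indi_pt")
        if pt is None:
            report.skip("empty_indication")
            return None
        return IndiRecord(
            primaryid=primaryid,
            caseid=caseid,
            indi_drug_seq=_int_or_none(_get(parts, pos, "indi_drug_seq")) or 1,
            indication_pt=pt,
        )
    raise AssertionError(table_kind)


_WRITE_COLUMNS = {
    "DEMO": ("primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod", "occp_cod", "occr_country"),
    "DRUG": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "REAC": ("primaryid", "caseid", "pt"),
    "THER": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
    "INDI": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
}

_OCC_TO_CODE = {
    "physician": "MD",
    "pharmacist": "PH",
    "other health professional": "HP",
    "consumer/other": "CN",
}


def _render(v) -> str:
    if v is None:
        return ""
    if isinstance(v, PartialDate):
        return v.render()
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(getattr(v, "value", v))


def write_table(records: Sequence, path: Union[str, os.PathLike], table_kind: str) -> None:
    """Write typed records back to the ``$``-delimited dialect (round-trips
    with :func:`read_table`)."""
    table_kind = table_kind.upper()
    cols = _WRITE_COLUMNS[table_kind]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(DELIM.join(cols) + "\n")
        for r in records:
            row = []
            for c in cols:
                if c == "age":
                    row.append(_render(r.age_value))
                elif c == "age_cod":
                    row.append(_render(r.age_code))
                elif c == "occp_cod":
                    row.append(_render(_OCC_TO_CODE.get(r.reporter_occupation, r.reporter_occupation)))
                elif c == "occr_country":
                    row.append(_render(r.country))
                elif c == "role_cod":
                    row.append(_render(r.role_code))
                elif c == "outc_cod":
                    row.append(_render(r.outcome_code))
                elif c == "indi_pt":
                    row.append(_render(r.indication_pt))
                else:
                    row.append(_render(getattr(r, c)))
            fh.write(DELIM.join(row) + "\n")


class VocabularyMap:
    """PT → SOC lookup with case-insensitive, whitespace-normalised keys.

    The MedDRA dictionary itself is licensed, so the map is always
    user-supplied (or synthetic): two columns, tab-delimited,
    ``pt<TAB>soc``.
    """

    def __init__(self, mapping: dict):
        self._map = {normalize_pt(k): v for k, v in mapping.items()}
        self._display = {normalize_pt(k): k for k in mapping}

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self._map

    def lookup(self, pt: str, default: Optional[str] = None) -> Optional[str]:
        return self._map.get(normalize_pt(pt), default)

    def items(self):
        return ((self._display[k], v) for k, v in self._map.items())

    def to_file(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pt\tsoc\n")
            for pt, soc in sorted(self.items()):
                fh.write(f"{pt}\t{soc}\n")

    @classmethod
    def from_file(cls, path: Union[str, os.PathLike]) -> "VocabularyMap":
        mapping = {}
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
            if first and first.split("\t")[0].strip().lower() != "pt":
                parts = first.rstrip("\n").split("\t")
                if len(parts) >= 2:
                    mapping[parts[0].strip()] = parts[1].strip()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0].strip():
                    mapping[parts[0].strip()] = parts[1].strip()
        return cls(mapping)


def read_vocabulary(path: Union[str, os.PathLike]) -> VocabularyMap:
    """Read the two-column ``pt<TAB>soc`` vocabulary map."""
    return VocabularyMap.from_file(path)


def read_deletion_list(path: Union[str, os.PathLike]) -> set:
    """Read the optional deleted-case list: one caseid per line."""
    deleted = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.isdigit():
                deleted.add(int(line))
    return deleted


SIGNAL_COLUMNS = [
    "soc", "pt", "a", "b", "c", "d",
    "ror", "ror_low", "ror_high", "prr", "chi2",
    "ic", "ic025", "ebgm", "ebgm05",
    "ror_sig", "prr_sig", "bcpnn_sig", "mgps_sig", "all_four",
]


def write_signal_table(table: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    """Write a signal table as tab-delimited text.

    Columns follow the fixed order of :data:`SIGNAL_COLUMNS` (extra
    columns such as ``unintended`` are appended); full float precision is
    kept and a 2-decimal half-up ``ror_display`` column mirrors the
    rounding convention of published tables.
    """
    df = table.copy()
    cols = [c for c in SIGNAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols and c != "ror_display"]
    df = df[cols]
    if "ror" in df.columns:
        df["ror_display"] = df["ror"].map(lambda x: f"{round_half_up(x, 2):.2f}" if x == x else "")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_signal_table(path: Union[str, os.PathLike]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
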