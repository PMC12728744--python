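"""Target-drug cohort extraction and event-table assembly.

A report belongs to the target cohort when any of its drug entries
matches a keyword (case-insensitive substring of the drug name or the
active ingredient) *and* carries the primary-suspect role (PS) — the
"first suspect" convention of disproportionality studies.  The counting
unit downstream is the distinct (report, PT) pair: one report contributes
once per unique preferred term, and a target report's PS match labels
*all* of its PTs as target records.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Set, Union

import pandas as pd

from .io import VocabularyMap, normalize_pt
from .records import (
    DemoRecord,
    DrugRecord,
    IndiRecord,
    OutcRecord,
    ReacRecord,
    RoleCode,
    Sex,
)

__all__ = [
    "ReportCase",
    "match_drug",
    "select_target_reports",
    "build_event_table",
    "age_to_years",
    "age_bin",
    "build_report_cases",
    "AGE_BINS",
]

# conversion of FAERS age units to years
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_BINS = ("<18", "18-64", "65-84", ">=85", "unknown")


@dataclass
class ReportCase:
    """One deduplicated ICSR with the demographics used downstream."""

    primaryid: int
    caseid: int
    is_target: bool
    sex: Sex = Sex.UNK
    age_years: Optional[float] = None
    country: Optional[str] = None
    reporter_occupation: Optional[str] = None
    report_year: Optional[int] = None
    outcomes: Set[str] = field(default_factory=set)
    indications: Set[str] = field(default_factory=set)


def match_drug(record: DrugRecord, keywords: Sequence[str]) -> bool:
    """True iff any keyword appears (case-insensitively, after whitespace
    normalisation) inside the drug name or the active-ingredient field."""
    if not keywords:
        raise ValueError("keywords must be non-empty")
    hay = [normalize_pt(record.drugname)]
    if record.prod_ai:
        hay.append(normalize_pt(record.prod_ai))
    for kw in keywords:
        k = normalize_pt(kw)
        if any(k in h for h in hay):
            return True
    return False


def select_target_reports(
    drugs: Union[Sequence[DrugRecord], pd.DataFrame],
    retained: Set[int],
    keywords: Sequence[str],
    role: RoleCode = RoleCode.PS,
) -> Set[int]:
    """Primaryids (among the retained set) with at least one keyword-matched
    drug entry in the required role (primary suspect by default)."""
    if isinstance(drugs, pd.DataFrame):
        if len(drugs) == 0:
            return set()
        name = drugs["drugname"].astype(str).str.lower()
        ai = drugs.get("prod_ai")
        ai = ai.astype(str).str.lower() if ai is not None else name
        hit = pd.Series(False, index=drugs.index)
        for kw in keywords:
            k = str(kw).lower()
            hit |= name.str.contains(k, regex=False) | ai.str.contains(k, regex=False)
        hit &= drugs["role_cod" if "role_cod" in drugs.columns else "role_code"].astype(str) == role.value
        pids = set(int(p) for p in drugs.loc[hit, "primaryid"].unique())
        return pids & retained
    out: Set[int] = set()
    for r in drugs:
        if r.primaryid in retained and r.role_code == role and match_drug(r, keywords):
            out.add(r.primaryid)
    return out


def build_event_table(
    reactions: Union[Sequence[ReacRecord], pd.DataFrame],
    retained: Set[int],
    targets: Set[int],
    vocab: VocabularyMap,
    unmapped_policy: str = "unmapped",
) -> pd.DataFrame:
    """Assemble the (report, PT) event table.

    One row per distinct (retained primaryid, normalised PT) with columns
    ``primaryid``, ``pt`` (normalised), ``pt_display`` (verbatim casing of
    the first occurrence), ``soc`` and ``is_target``.  PTs absent from the
    vocabulary get SOC ``UNMAPPED`` under the default policy, or raise
    under ``unmapped_policy='fatal'``.
    """
    if unmapped_policy not in ("unmapped", "fatal"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    if isinstance(reactions, pd.DataFrame):
        df = reactions[["primaryid", "pt"]].copy()
    else:
        df = pd.DataFrame(
            {"primaryid": [r.primaryid for r in reactions], "pt": [r.pt for r in reactions]}
        )
    if len(df) == 0:
        return pd.DataFrame(columns=["primaryid", "pt", "pt_display", "soc", "is_target"])
    df = df[df["primaryid"].isin(retained)]
    df["pt_display"] = df["pt"].astype(str)
    df["pt"] = df["pt_display"].map(normalize_pt)
    df = df.drop_duplicates(["primaryid", "pt"], keep="first")
    socs = df["pt"].map(lambda p: vocab.lookup(p))
    if socs.isna().any():
        if unmapped_policy == "fatal":
            missing = sorted(df.loc[socs.isna(), "pt_display"].unique())
            raise KeyError(f"PTs absent from vocabulary: {missing[:10]}")
        socs = socs.fillna("UNMAPPED")
    df["soc"] = socs
    df["is_target"] = df["primaryid"].isin(targets)
    df = df.sort_values(["primaryid", "pt"], kind="mergesort").reset_index(drop=True)
    return df[["primaryid", "pt", "pt_display", "soc", "is_target"]]


def age_to_years(age_value: Optional[float], age_code) -> Optional[float]:
    """Convert a FAERS (value, unit) age to years; negative or missing
    values give None.  A value with no unit code is taken as years."""
    if age_value is None or age_value != age_value:
        return None
    if age_value < 0:
        return None
    code = getattr(age_code, "value", age_code)
    factor = _AGE_FACTORS.get(code, 1.0) if code else 1.0
    return float(age_value) * factor


def age_bin(years: Optional[float]) -> str:
    if years is None:
        return "unknown"
    if years < 18:
        return "<18"
    if years < 65:
        return "18-64"
    if years < 85:
        return "65-84"
    return ">=85"


def build_report_cases(
    demo: Sequence[DemoRecord],
    retained: Set[int],
    targets: Set[int],
    outcomes: Sequence[OutcRecord] = (),
    indications: Sequence[IndiRecord] = (),
) -> list:
    """One :class:`ReportCase` per retained primaryid, with outcomes and
    indications attached and age converted to years once."""
    outc_by_pid: dict = {}
    for o in outcomes:
        outc_by_pid.setdefault(o.primaryid, set()).add(o.outcome_code.value)
    indi_by_pid: dict = {}
    for i in indications:
        indi_by_pid.setdefault(i.primaryid, set()).add(i.indication_pt)
    cases = []
    for r in demo:
        if r.primaryid not in retained:
            continue
        cases.append(
            ReportCase(
                primaryid=r.primaryid,
                caseid=r.caseid,
                is_target=r.primaryid in targets,
                sex=r.sex,
                age_years=age_to_years(r.age_value, r.age_code),
                country=r.country,
                reporter_occupation=r.reporter_occupation,
                report_year=r.report_year,
                outcomes=outc_by_pid.get(r.primaryid, set()),
                indications=indi_by_pid.get(r.primaryid, set()),
            )
        )
    return cases
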