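"""Descriptive cohort characterisation and sex-stratified signals.

Covers the clinical-characterisation table of a pharmacovigilance study
(sex, age bins, serious outcomes, top reporting countries, indications,
reporter occupations, yearly trend) and the sex-subgroup signal analysis:
the full four-algorithm battery evaluated separately within female and
within male reports (target drug versus all other drugs restricted to
that sex).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .cohort import ReportCase, age_bin, AGE_BINS
from .records import OutcomeCode, Sex
from .stats import signal_table

__all__ = ["CohortSummary", "describe_cohort", "yearly_trend", "stratified_signals"]


@dataclass
class CohortSummary:
    """Counts and percentages over the deduplicated target cohort.

    Percentages are of the cohort size; every categorical block's counts
    sum to the cohort size (top-k blocks list only the k largest levels
    but keep the full counts internally).
    """

    n: int
    sex: Dict[str, Tuple[int, float]]
    age_bins: Dict[str, Tuple[int, float]]
    outcomes: Dict[str, Tuple[int, float]]
    top_countries: List[Tuple[str, int, float]]
    top_indications: List[Tuple[str, int, float]]
    reporters: Dict[str, Tuple[int, float]]
    reports_per_year: Dict[int, int]


def _pct(count: int, n: int) -> float:
    return 100.0 * count / n if n else 0.0


def _topk(counter: Counter, k: int, n: int) -> List[Tuple[str, int, float]]:
    # ties broken by name for determinism
    items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(name, cnt, _pct(cnt, n)) for name, cnt in items[:k]]


def describe_cohort(cases: Sequence[ReportCase], top_k: int = 5) -> CohortSummary:
    """Characterise a cohort of report cases (typically the target cohort)."""
    n = len(cases)
    sex_counts = Counter(c.sex.value for c in cases)
    sex = {s: (sex_counts.get(s, 0), _pct(sex_counts.get(s, 0), n)) for s in ("F", "M", "UNK")}
    bin_counts = Counter(age_bin(c.age_years) for c in cases)
    age_bins = {b: (bin_counts.get(b, 0), _pct(bin_counts.get(b, 0), n)) for b in AGE_BINS}
    outc_counts: Counter = Counter()
    for c in cases:
        for o in c.outcomes:
            outc_counts[o] += 1
    outcomes = {
        o.value: (outc_counts.get(o.value, 0), _pct(outc_counts.get(o.value, 0), n))
        for o in OutcomeCode
    }
    country_counts = Counter(c.country for c in cases if c.country)
    indi_counts: Counter = Counter()
    for c in cases:
        for i in c.indications:
            indi_counts[i] += 1
    rep_counts = Counter(c.reporter_occupation or "missing" for c in cases)
    reporters = {
        r: (cnt, _pct(cnt, n))
        for r, cnt in sorted(rep_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    years = Counter(c.report_year for c in cases if c.report_year)
    return CohortSummary(
        n=n,
        sex=sex,
        age_bins=age_bins,
        outcomes=outcomes,
        top_countries=_topk(country_counts, top_k, n),
        top_indications=_topk(indi_counts, top_k, n),
        reporters=reporters,
        reports_per_year={int(y): int(cnt) for y, cnt in sorted(years.items())},
    )


def yearly_trend(
    cases: Sequence[ReportCase],
    groups: Optional[Dict[str, Iterable[str]]] = None,
    scale_factor: float = 1.0,
) -> pd.DataFrame:
    """Reports per year, per named country group, plus the scaled total.

    ``groups`` maps a label to a set of ISO-3 country codes (e.g.
    ``{"USA": {"US", "USA"}, "GBR": {"GB", "GBR"}}``); the ``total_scaled``
    column is the all-country total multiplied by ``scale_factor`` (a
    study may shrink the total series, e.g. to a quarter, to keep it on
    the same axis as single-country series).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    groups = {k: set(v) for k, v in (groups or {}).items()}
    years = sorted({c.report_year for c in cases if c.report_year})
    rows = []
    for y in years:
        in_year = [c for c in cases if c.report_year == y]
        row = {"year": y, "total": len(in_year), "total_scaled": len(in_year) * scale_factor}
        for label, countries in groups.items():
            row[label] = sum(1 for c in in_year if c.country in countries)
        rows.append(row)
    cols = ["year", "total", "total_scaled"] + list(groups)
    return pd.DataFrame(rows, columns=cols)


def stratified_signals(
    events: pd.DataFrame,
    cases: Sequence[ReportCase],
    stratum: str,
    top_k: Optional[int] = 30,
    all_four_only: bool = False,
    min_count: int = 1,
    contrast: str = "within_stratum",
    zero_cell_policy: str = "undefined",
) -> pd.DataFrame:
    """Sex-stratified signal battery.

    Default contrast ``within_stratum``: restrict the event table to
    reports of the given sex and run target-drug-vs-other-drugs
    disproportionality inside that stratum.  The alternative contrast
    ``between_sex`` compares female vs male reporting *within* target
    reports (the stratum labels the numerator sex).  Unknown-sex reports
    never enter a stratum.  Rows are sorted by ``a`` descending; the
    ``top_k`` most frequent rows are kept (None keeps all), optionally
    only those meeting all four signal criteria.
    """
    stratum = stratum.lower()
    if stratum not in ("female", "male"):
        raise ValueError("stratum must be 'female' or 'male'")
    sex_value = "F" if stratum == "female" else "M"
    sex_of = {c.primaryid: c.sex.value for c in cases}

    if contrast == "within_stratum":
        mask = events["primaryid"].map(sex_of) == sex_value
        sub = events[mask]
        if len(sub) == 0 or not sub["is_target"].any():
            return _empty_subgroup(stratum)
        table = signal_table(sub, level="PT", min_count=min_count,
                             zero_cell_policy=zero_cell_policy)
    elif contrast == "between_sex":
        other = "M" if sex_value == "F" else "F"
        sexes = events["primaryid"].map(sex_of)
        sub = events[events["is_target"] & sexes.isin([sex_value, other])].copy()
        if len(sub) == 0:
            return _empty_subgroup(stratum)
        sub["is_target"] = (sexes.loc[sub.index] == sex_value).to_numpy()
        table = signal_table(sub, level="PT", min_count=min_count,
                             zero_cell_policy=zero_cell_policy)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    table.insert(0, "stratum", stratum)
    if all_four_only:
        table = table[table["all_four"]]
    if top_k is not None:
        table = table.head(top_k)
    return table.reset_index(drop=True)


def _empty_subgroup(stratum: str) -> pd.DataFrame:
    from .io import SIGNAL_COLUMNS

    cols = ["stratum"] + [c for c in SIGNAL_COLUMNS if c != "soc"]
    return pd.DataFrame(columns=cols)
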