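"""Time-to-onset analysis: days from therapy initiation to the adverse event.

Only reports where both the therapy start date and the event date are
full calendar dates enter the summary; month- or year-precision dates are
excluded rather than imputed (imputing a mid-month day would fabricate
onsets), and events dated before the therapy start are excluded as
pre-treatment.  The distribution is summarised by mean, median and IQR
(linear interpolation between order statistics, the convention that
yields fractional quartiles such as 265.75) plus 30-day bins up to one
year and a ">360 days" tail bin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from .records import PartialDate

__all__ = ["OnsetRecord", "OnsetSummary", "compute_onset", "summarize_onset", "ONSET_BINS"]

# bins: 0-30, 31-60, ..., 331-360, >360  (first bin includes day 0..30)
ONSET_BINS = ("0-30", "31-60", "61-90", "91-120", "121-150", "151-180",
              "181-210", "211-240", "241-270", "271-300", "301-330", "331-360", ">360")


@dataclass
class OnsetRecord:
    primaryid: int
    onset_days: Optional[int]
    included: bool
    exclusion_reason: Optional[str] = None  # pre_treatment | partial_date | missing_date


@dataclass
class OnsetSummary:
    n_input: int
    n_included: int
    n_excluded: Dict[str, int]
    mean_days: Optional[float]
    median_days: Optional[float]
    iqr: Optional[Tuple[float, float]]
    bin_counts: Dict[str, int]
    fraction_first_month: Optional[float]
    fraction_over_one_year: Optional[float]


def compute_onset(
    event_dt: Optional[PartialDate],
    start_dt: Optional[PartialDate],
    primaryid: int = 0,
) -> OnsetRecord:
    """Onset for one report.  Total function: missing dates give reason
    ``missing_date``, partial-precision dates ``partial_date``, events
    before therapy start ``pre_treatment``."""
    if event_dt is None or start_dt is None:
        return OnsetRecord(primaryid, None, False, "missing_date")
    if not (event_dt.is_full and start_dt.is_full):
        return OnsetRecord(primaryid, None, False, "partial_date")
    delta = (event_dt.to_date() - start_dt.to_date()).days
    if delta < 0:
        return OnsetRecord(primaryid, None, False, "pre_treatment")
    return OnsetRecord(primaryid, delta, True)


def _bin_label(days: int) -> str:
    if days > 360:
        return ">360"
    if days <= 30:
        return "0-30"
    i = (days - 1) // 30  # 31..60 -> 1, 61..90 -> 2, ...
    lo = i * 30 + 1
    return f"{lo}-{lo + 29}"


def summarize_onset(records: Iterable[OnsetRecord]) -> OnsetSummary:
    """Distribution summary over the included records.

    With zero included records every statistic is None and the bin counts
    are all zero (an empty summary, not an exception).
    """
    records = list(records)
    excluded = Counter(r.exclusion_reason for r in records if not r.included)
    days = np.array([r.onset_days for r in records if r.included], dtype=float)
    bins = {label: 0 for label in ONSET_BINS}
    if days.size == 0:
        return OnsetSummary(
            n_input=len(records), n_included=0, n_excluded=dict(excluded),
            mean_days=None, median_days=None, iqr=None, bin_counts=bins,
            fraction_first_month=None, fraction_over_one_year=None,
        )
    for d in days:
        bins[_bin_label(int(d))] += 1
    q1, med, q3 = np.percentile(days, [25, 50, 75])  # linear interpolation
    return OnsetSummary(
        n_input=len(records),
        n_included=int(days.size),
        n_excluded=dict(excluded),
        mean_days=float(days.mean()),
        median_days=float(med),
        iqr=(float(q1), float(q3)),
        bin_counts=bins,
        fraction_first_month=float((days <= 30).mean()),
        fraction_over_one_year=float((days > 365).mean()),
    )
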