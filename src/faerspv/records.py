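"""Typed records for FAERS-style quarterly extracts.

A quarterly FAERS extract is a set of ``$``-delimited ASCII tables (DEMO,
DRUG, REAC, THER, INDI, OUTC) keyed by ``primaryid`` (a report *version*)
and ``caseid`` (the underlying patient case).  This module defines one
lightweight dataclass per table plus the partial-date type that FAERS date
fields require: a date field may carry a full day, only a year-month, only
a year, or nothing at all.
"""

from __future__ import annotations

import datetime as _dt
import functools
from collections import Counter
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "PartialDate",
    "parse_partial_date",
    "Sex",
    "RoleCode",
    "AgeCode",
    "OutcomeCode",
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "TherRecord",
    "OutcRecord",
    "IndiRecord",
    "LoadReport",
    "to_frame",
]


class Sex(str, Enum):
    F = "F"
    M = "M"
    UNK = "UNK"


class RoleCode(str, Enum):
    """FAERS drug role: primary suspect, secondary suspect, concomitant, interacting."""

    PS = "PS"
    SS = "SS"
    C = "C"
    I = "I"


class AgeCode(str, Enum):
    DEC = "DEC"
    YR = "YR"
    MON = "MON"
    WK = "WK"
    DY = "DY"
    HR = "HR"


class OutcomeCode(str, Enum):
    """Serious-outcome codes of the OUTC table."""

    DE = "DE"  # death
    HO = "HO"  # hospitalization (initial or prolonged)
    DS = "DS"  # disability
    LT = "LT"  # life-threatening
    CA = "CA"  # congenital anomaly
    RI = "RI"  # required intervention
    OT = "OT"  # other serious


@functools.total_ordering
@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to full, month or year precision.

    Ordering is lexicographic on ``(year, month, day)`` with missing
    components treated as 0, so a year-only date sorts before any date
    within that year.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.month is None and self.day is not None:
            raise ValueError("day without month")

    @property
    def is_full(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> _dt.date:
        if not self.is_full:
            raise ValueError(f"{self} is not a full calendar date")
        return _dt.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def render(self) -> str:
        """Render back to the FAERS digit string (YYYY, YYYYMM or YYYYMMDD)."""
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def __lt__(self, other: "PartialDate") -> bool:  # type: ignore[override]
        return self.sort_key() < other.sort_key()


def parse_partial_date(raw: object) -> Optional[PartialDate]:
    """Parse a FAERS date field into a :class:`PartialDate`, or ``None``.

    Total function: 8 digits give a full date, 6 a year-month, 4 a bare
    year; anything else — including impossible calendar dates such as month
    13 or February 30 — maps to ``None``.
    """
    if raw is None:
        return None
    if isinstance(raw, PartialDate):
        return raw
    if isinstance(raw, float):
        if raw != raw:  # NaN
            return None
        raw = int(raw)
    s = str(raw).strip()
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            y, m, d = int(s[:4]), int(s[4:6]), int(s[6:])
            _dt.date(y, m, d)  # calendar validation
            return PartialDate(y, m, d)
        if len(s) == 6:
            y, m = int(s[:4]), int(s[4:])
            if not 1 <= m <= 12:
                return None
            return PartialDate(y, m)
        if len(s) == 4:
            y = int(s)
            if y == 0:
                return None
            return PartialDate(y)
    except ValueError:
        return None
    return None


@dataclass
class DemoRecord:
    primaryid: int
    caseid: int
    fda_dt: Optional[PartialDate] = None
    event_dt: Optional[PartialDate] = None
    sex: Sex = Sex.UNK
    age_value: Optional[float] = None
    age_code: Optional[AgeCode] = None
    reporter_occupation: Optional[str] = None
    country: Optional[str] = None

    @property
    def report_year(self) -> Optional[int]:
        """Year the report reached the FDA (from FDA_DT)."""
        return self.fda_dt.year if self.fda_dt is not None else None


@dataclass
class DrugRecord:
    primaryid: int
    caseid: int
    drug_seq: int
    role_code: Optional[RoleCode]
    drugname: str
    prod_ai: Optional[str] = None


@dataclass
class ReacRecord:
    primaryid: int
    caseid: int
    pt: str


@dataclass
class TherRecord:
    primaryid: int
    caseid: int
    dsg_drug_seq: int
    start_dt: Optional[PartialDate] = None
    end_dt: Optional[PartialDate] = None

    @property
    def inconsistent(self) -> bool:
        """True when both dates are full and the therapy ends before it starts."""
        if self.start_dt is None or self.end_dt is None:
            return False
        if not (self.start_dt.is_full and self.end_dt.is_full):
            return False
        return self.end_dt.to_date() < self.start_dt.to_date()


@dataclass
class OutcRecord:
    primaryid: int
    caseid: int
    outcome_code: OutcomeCode


@dataclass
class IndiRecord:
    primaryid: int
    caseid: int
    indi_drug_seq: int
    indication_pt: str


@dataclass
class LoadReport:
    """Accounting for one table load: every input line is kept or counted skipped."""

    table: str
    lines_read: int = 0
    records_kept: int = 0
    records_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)
    value_fixes: Counter = field(default_factory=Counter)

    def skip(self, reason: str) -> None:
        self.records_skipped += 1
        self.skip_reasons[reason] += 1

    @property
    def conserved(self) -> bool:
        return self.lines_read == self.records_kept + self.records_skipped


def to_frame(records: Sequence) -> pd.DataFrame:
    """Convert a homogeneous sequence of record dataclasses to a DataFrame.

    Enum fields become their string values; PartialDate fields stay as
    objects (use ``.render()`` for serialisation).
    """
    if not records:
        return pd.DataFrame()
    cols = [f.name for f in fields(records[0])]
    data = {}
    for c in cols:
        vals = [getattr(r, c) for r in records]
        data[c] = [v.value if isinstance(v, Enum) else v for v in vals]
    df = pd.DataFrame(data)
    if isinstance(records[0], DemoRecord):
        df["report_year"] = [r.report_year for r in records]
    return df
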