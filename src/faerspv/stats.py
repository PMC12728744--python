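"""Disproportionality statistics on the pharmacovigilance fourfold table.

For one drug–event pair the spontaneous-report database collapses to

    =============  ==========  =========
    .              target AE   other AE
    =============  ==========  =========
    target drug    a           b
    other drugs    c           d
    =============  ==========  =========

with N = a+b+c+d (the counting unit is the distinct (report, PT) record).
Four classical signal-detection statistics are computed in their
simplified, non-shrinkage forms:

* ROR  = ad/bc, with log-normal 95% CI
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
* PRR  = a(c+d)/(c(a+b)), with Pearson χ² (no continuity correction);
* IC   = log₂(a·N/((a+c)(a+b))), the information component of the BCPNN
  family; its lower bound IC025 is the log₂ of the log-normal lower bound
  of the same observed/expected ratio;
* EBGM = a·N/((a+c)(a+b)), the geometric-mean observed/expected ratio of
  the MGPS family, with EBGM05 the log-normal lower bound.

IC and EBGM are the same quantity on log₂ versus linear scale, so
EBGM = 2^IC holds identically — a useful internal consistency check.
No Bayesian shrinkage (gamma-Poisson mixture, BCPNN posterior) is
applied; these are the simplified point estimates.

Signal criteria (all four must hold for the conjunction flag):

* ROR:   lower 95% bound > 1 and a ≥ 3
* PRR:   PRR > 2, χ² > 4 and a > 3
* BCPNN: IC025 > 0
* MGPS:  EBGM05 > 2 and N > 0
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "SignalMetrics",
    "build_contingency",
    "compute_ror",
    "compute_prr",
    "compute_ic",
    "compute_ebgm",
    "compute_metrics",
    "classify_signal",
    "signal_table",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Fourfold table of nonnegative integer counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.N <= 0:
            raise ValueError("empty table (N = 0)")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalMetrics:
    """Point estimates, interval bounds and per-algorithm signal flags.

    Undefined quantities (zero cells without correction) are NaN and force
    the corresponding flag to False; ``ic`` is −∞ when a = 0.
    """

    a: int
    N: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ror_sig: bool = False
    prr_sig: bool = False
    bcpnn_sig: bool = False
    mgps_sig: bool = False
    all_four: bool = False


def _as_arrays(a, b, c, d):
    return (np.asarray(a, dtype=float), np.asarray(b, dtype=float),
            np.asarray(c, dtype=float), np.asarray(d, dtype=float))


def _metrics_arrays(a, b, c, d, zero_cell_policy: str = "undefined") -> dict:
    """Vectorised evaluation of all four statistics.

    ``zero_cell_policy``: "undefined" leaves zero-cell quantities NaN;
    "haldane" adds 0.5 to every cell of tables containing a zero
    (Haldane–Anscombe correction) before evaluation.
    """
    if zero_cell_policy not in ("undefined", "haldane"):
        raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    a, b, c, d = _as_arrays(a, b, c, d)
    a0 = a.copy()  # raw counts drive the a-based criteria
    if zero_cell_policy == "haldane":
        has_zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        a = np.where(has_zero, a + 0.5, a)
        b = np.where(has_zero, b + 0.5, b)
        c = np.where(has_zero, c + 0.5, c)
        d = np.where(has_zero, d + 0.5, d)
    N = a + b + c + d

    with np.errstate(divide="ignore", invalid="ignore"):
        all_pos = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        se = np.where(all_pos, np.sqrt(1 / np.where(a > 0, a, 1)
                                       + 1 / np.where(b > 0, b, 1)
                                       + 1 / np.where(c > 0, c, 1)
                                       + 1 / np.where(d > 0, d, 1)), np.nan)

        ror = np.where(all_pos, (a * d) / (b * c), np.nan)
        ror_low = np.exp(np.log(ror) - _Z * se)
        ror_high = np.exp(np.log(ror) + _Z * se)

        prr_ok = (c > 0) & (a + b > 0)
        prr = np.where(prr_ok, a * (c + d) / (c * (a + b)), np.nan)

        margins_ok = (a + b > 0) & (c + d > 0) & (a + c > 0) & (b + d > 0)
        chi2 = np.where(
            margins_ok,
            (a * d - b * c) ** 2 * N
            / np.where(margins_ok, (a + b) * (c + d) * (a + c) * (b + d), 1),
            np.nan,
        )

        oe_ok = (a + c > 0) & (a + b > 0)
        ebgm = np.where(oe_ok, a * N / ((a + c) * (a + b)), np.nan)
        ic = np.where(oe_ok, np.log2(np.where(ebgm > 0, ebgm, np.nan)), np.nan)
        ic = np.where(oe_ok & (a == 0), -np.inf, ic)
        ebgm05 = np.exp(np.log(np.where(ebgm > 0, ebgm, np.nan)) - _Z * se)
        ic025 = np.log2(ebgm05)
        ic025 = np.where(oe_ok & (a == 0), -np.inf, ic025)

    return {
        "a": a0, "N_eff": N, "se": se,
        "ror": ror, "ror_low": ror_low, "ror_high": ror_high,
        "prr": prr, "chi2": chi2,
        "ic": ic, "ic025": ic025, "ebgm": ebgm, "ebgm05": ebgm05,
    }


def _flags_arrays(m: dict) -> dict:
    a = m["a"]
    N = m["N_eff"]
    with np.errstate(invalid="ignore"):
        ror_sig = np.nan_to_num(m["ror_low"], nan=-np.inf) > 1
        ror_sig &= a >= 3
        prr_sig = (np.nan_to_num(m["prr"], nan=-np.inf) > 2) \
            & (np.nan_to_num(m["chi2"], nan=-np.inf) > 4) & (a > 3)
        bcpnn_sig = np.nan_to_num(m["ic025"], nan=-np.inf) > 0
        mgps_sig = (np.nan_to_num(m["ebgm05"], nan=-np.inf) > 2) & (N > 0)
    all_four = ror_sig & prr_sig & bcpnn_sig & mgps_sig
    return {
        "ror_sig": ror_sig, "prr_sig": prr_sig,
        "bcpnn_sig": bcpnn_sig, "mgps_sig": mgps_sig, "all_four": all_four,
    }


def compute_ror(t: ContingencyTable, zero_cell_policy: str = "undefined"):
    """Reporting odds ratio with its 95% CI; NaN triple if any cell is zero
    (unless the Haldane correction is enabled)."""
    m = _metrics_arrays(t.a, t.b, t.c, t.d, zero_cell_policy)
    return float(m["ror"]), float(m["ror_low"]), float(m["ror_high"])


def compute_prr(t: ContingencyTable, zero_cell_policy: str = "undefined"):
    """Proportional reporting ratio and Pearson χ² without continuity
    correction."""
    m = _metrics_arrays(t.a, t.b, t.c, t.d, zero_cell_policy)
    return float(m["prr"]), float(m["chi2"])


def compute_ic(t: ContingencyTable, zero_cell_policy: str = "undefined"):
    """Information component (log₂ observed/expected) and its lower bound."""
    m = _metrics_arrays(t.a, t.b, t.c, t.d, zero_cell_policy)
    return float(m["ic"]), float(m["ic025"])


def compute_ebgm(t: ContingencyTable, zero_cell_policy: str = "undefined"):
    """Geometric-mean observed/expected ratio (simplified EBGM) and its
    lower bound."""
    m = _metrics_arrays(t.a, t.b, t.c, t.d, zero_cell_policy)
    return float(m["ebgm"]), float(m["ebgm05"])


def compute_metrics(t: ContingencyTable, zero_cell_policy: str = "undefined") -> SignalMetrics:
    """All four statistics plus signal flags for one table."""
    m = _metrics_arrays(t.a, t.b, t.c, t.d, zero_cell_policy)
    f = _flags_arrays(m)
    return SignalMetrics(
        a=t.a, N=t.N,
        ror=float(m["ror"]), ror_ci_low=float(m["ror_low"]), ror_ci_high=float(m["ror_high"]),
        prr=float(m["prr"]), chi2=float(m["chi2"]),
        ic=float(m["ic"]), ic025=float(m["ic025"]),
        ebgm=float(m["ebgm"]), ebgm05=float(m["ebgm05"]),
        ror_sig=bool(f["ror_sig"]), prr_sig=bool(f["prr_sig"]),
        bcpnn_sig=bool(f["bcpnn_sig"]), mgps_sig=bool(f["mgps_sig"]),
        all_four=bool(f["all_four"]),
    )


def classify_signal(m: SignalMetrics) -> SignalMetrics:
    """(Re)compute the per-algorithm signal flags on a metrics object."""
    arrays = {
        "a": np.asarray(float(m.a)), "N_eff": np.asarray(float(m.N)),
        "ror_low": np.asarray(m.ror_ci_low), "prr": np.asarray(m.prr),
        "chi2": np.asarray(m.chi2), "ic025": np.asarray(m.ic025),
        "ebgm05": np.asarray(m.ebgm05),
    }
    f = _flags_arrays(arrays)
    m.ror_sig = bool(f["ror_sig"])
    m.prr_sig = bool(f["prr_sig"])
    m.bcpnn_sig = bool(f["bcpnn_sig"])
    m.mgps_sig = bool(f["mgps_sig"])
    m.all_four = bool(f["all_four"])
    return m


def build_contingency(events: pd.DataFrame, target: str, level: str = "PT") -> ContingencyTable:
    """Fourfold table for one PT (or SOC) from an event table.

    ``events`` must carry one row per distinct (report, PT) with columns
    ``pt``, ``soc`` and boolean ``is_target``; at SOC level records are
    counted by their ``soc`` value, so a report with two PTs in the same
    SOC contributes two records.
    """
    if level not in ("PT", "SOC"):
        raise ValueError("level must be 'PT' or 'SOC'")
    col = "pt" if level == "PT" else "soc"
    from .io import normalize_pt

    values = events[col].astype(str)
    hit = values.map(normalize_pt) == normalize_pt(target)
    tgt = events["is_target"].astype(bool)
    a = int((hit & tgt).sum())
    b = int((~hit & tgt).sum())
    c = int((hit & ~tgt).sum())
    d = int((~hit & ~tgt).sum())
    return ContingencyTable(a, b, c, d)


def signal_table(
    events: pd.DataFrame,
    level: str = "PT",
    min_count: int = 1,
    zero_cell_policy: str = "undefined",
) -> pd.DataFrame:
    """Batch-evaluate the four algorithms for every PT (or SOC).

    Returns one row per event value with counts a/b/c/d, all statistics,
    interval bounds and flags, sorted by ``a`` descending then name for
    determinism.  Equals per-table scalar evaluation by construction (the
    same vectorised kernel runs both).
    """
    if level not in ("PT", "SOC"):
        raise ValueError("level must be 'PT' or 'SOC'")
    col = "pt" if level == "PT" else "soc"
    tgt = events["is_target"].astype(bool).to_numpy()
    n_t = int(tgt.sum())
    n_o = int(len(events) - n_t)

    counts = (
        events.assign(_t=tgt)
        .groupby([col, "_t"], observed=True)
        .size()
        .unstack("_t", fill_value=0)
        .reindex(columns=[True, False], fill_value=0)
    )
    a = counts[True].to_numpy()
    c = counts[False].to_numpy()
    b = n_t - a
    d = n_o - c

    m = _metrics_arrays(a, b, c, d, zero_cell_policy)
    f = _flags_arrays(m)

    out = pd.DataFrame({col: counts.index.astype(str)})
    if level == "PT" and "soc" in events.columns:
        soc_of_pt = events.drop_duplicates("pt").set_index("pt")["soc"]
        out["soc"] = out["pt"].map(soc_of_pt)
    out["a"], out["b"], out["c"], out["d"] = a, b, c, d
    for k in ("ror", "ror_low", "ror_high", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05"):
        out[k] = m[k]
    for k, v in f.items():
        out[k] = v
    out = out[out["a"] >= min_count]
    out = out.sort_values(["a", col], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
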