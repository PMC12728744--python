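"""Case-level deduplication of individual case safety reports (ICSRs).

A FAERS case (``caseid``) may appear as several report versions
(``primaryid``) as follow-up information arrives.  The FDA-recommended
rule keeps, per case, the version with the latest ``FDA_DT``; ties on
``FDA_DT`` are broken by the highest ``primaryid``.  Cases on the
quarterly deleted-case lists are then removed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .records import DemoRecord, PartialDate

__all__ = ["DedupResult", "deduplicate", "apply_deletions", "IntegrityError"]


class IntegrityError(ValueError):
    """Input violates a structural precondition (e.g. duplicate primaryid)."""


@dataclass
class DedupResult:
    """Outcome of deduplication; counts conserve the input size:
    ``n_input = len(retained_primaryids) + removed_as_duplicate + removed_as_deleted``."""

    retained_primaryids: set
    retained_caseids: dict  # primaryid -> caseid for the retained version
    removed_as_duplicate: int
    removed_as_deleted: int = 0
    n_input: int = 0

    @property
    def conserved(self) -> bool:
        return self.n_input == (
            len(self.retained_primaryids) + self.removed_as_duplicate + self.removed_as_deleted
        )


def _date_key(v) -> int:
    """Sortable integer for an FDA_DT value; missing sorts before any real
    date so a dated version always beats an undated one."""
    if v is None:
        return -1
    if isinstance(v, PartialDate):
        return v.year * 10000 + (v.month or 0) * 100 + (v.day or 0)
    if isinstance(v, float):
        return -1 if v != v else int(v)
    return int(v)


def deduplicate(demo: Union[pd.DataFrame, Sequence[DemoRecord]]) -> DedupResult:
    """Apply the case-level retention rule.

    Accepts either a sequence of :class:`~faerspv.records.DemoRecord` or a
    DataFrame with ``primaryid``, ``caseid`` and ``fda_dt`` columns
    (``fda_dt`` as YYYYMMDD integers, ``PartialDate`` objects or NaN).
    For each ``caseid`` exactly one ``primaryid`` is retained: the argmax
    under the lexicographic order (fda_dt, primaryid).  The result is
    invariant to input row order and idempotent.
    """
    if isinstance(demo, pd.DataFrame):
        pid = demo["primaryid"].to_numpy()
        cid = demo["caseid"].to_numpy()
        key = np.array([_date_key(v) for v in demo["fda_dt"]], dtype=np.int64)
    else:
        pid = np.array([r.primaryid for r in demo], dtype=np.int64)
        cid = np.array([r.caseid for r in demo], dtype=np.int64)
        key = np.array([_date_key(r.fda_dt) for r in demo], dtype=np.int64)

    n = len(pid)
    if n == 0:
        return DedupResult(set(), {}, 0, 0, 0)
    if len(np.unique(pid)) != n:
        raise IntegrityError("duplicate primaryid values in DEMO input")

    # lexicographic argmax per caseid: sort ascending, keep last per group
    order = np.lexsort((pid, key, cid))
    cid_sorted = cid[order]
    last_of_group = np.r_[cid_sorted[1:] != cid_sorted[:-1], True]
    keep_idx = order[last_of_group]
    retained = set(int(p) for p in pid[keep_idx])
    retained_caseids = {int(pid[i]): int(cid[i]) for i in keep_idx}
    return DedupResult(
        retained_primaryids=retained,
        retained_caseids=retained_caseids,
        removed_as_duplicate=n - len(retained),
        removed_as_deleted=0,
        n_input=n,
    )


def apply_deletions(result: DedupResult, deleted_caseids: Iterable[int]) -> DedupResult:
    """Remove retained reports whose case is on the deleted-case list."""
    deleted = set(deleted_caseids)
    keep = {p: c for p, c in result.retained_caseids.items() if c not in deleted}
    n_removed = len(result.retained_caseids) - len(keep)
    return DedupResult(
        retained_primaryids=set(keep),
        retained_caseids=keep,
        removed_as_duplicate=result.removed_as_duplicate,
        removed_as_deleted=result.removed_as_deleted + n_removed,
        n_input=result.n_input,
    )
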