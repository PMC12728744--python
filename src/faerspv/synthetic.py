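"""Synthetic FAERS-style extract generator with known ground truth.

Emits the same multi-table ``$``-delimited dialect the IO layer reads
(DEMO, DRUG, REAC, THER, INDI, OUTC, plus a deleted-case list, a PT→SOC
vocabulary and a ground-truth JSON), with every pathology the pipeline
must handle built in: duplicate report versions with later FDA dates and
tie-dates, deleted cases, missing and month-precision dates, mixed age
units, unknown sexes, and configurable injected drug–event signals.

The injection model is the part that matters for validation: PTs are
drawn per report from a categorical lexicon, and an injected signal
multiplies the target PT's *categorical weight* in matching reports.
Because the other weights are untouched, the within-record odds of the
PT are multiplied exactly, so the population record-level reporting odds
ratio equals the configured multiplier by construction — signal recovery
has a closed-form known target.

Random streams are drawn per concern from independently spawned child
generators of the master seed, so adding a field to one table does not
perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .io import VocabularyMap

__all__ = [
    "InjectedSignal",
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticExtract",
    "generate",
    "make_duplicates",
    "preset",
    "PRESETS",
]

TARGET = "TARGET"  # sentinel drug name in InjectedSignal.drug


class InjectedSignal(BaseModel):
    """One drug–event pair with elevated reporting odds.

    ``drug`` is either the sentinel ``"TARGET"`` or the name of one of the
    background drugs; ``sex`` restricts the injection to reports of one
    sex (for sex-specific signal experiments).
    """

    drug: str = TARGET
    pt: str
    odds_multiplier: float = Field(gt=0)
    sex: Optional[str] = None  # "F" or "M"

    @field_validator("sex")
    @classmethod
    def _sex_ok(cls, v):
        if v is not None and v not in ("F", "M"):
            raise ValueError("sex restriction must be 'F' or 'M'")
        return v


class GeneratorConfig(BaseModel):
    """Full specification of a synthetic extract.

    Same seed and config give byte-identical output files.
    """

    seed: int = 0
    n_reports: int = Field(default=1000, gt=0)
    # lexicons
    n_other_drugs: int = Field(default=10, gt=0)
    target_drugname: str = "DONEPEZIL"
    target_ingredient: str = "DONEPEZIL HYDROCHLORIDE"
    n_pts: int = Field(default=50, gt=1)
    n_socs: int = Field(default=8, gt=0)
    pt_weight_alpha: float = 0.7  # Zipf exponent for PT base weights (0 = uniform)
    mean_pts_per_report: float = Field(default=2.9, ge=1)
    # cohort structure
    p_target_report: float = Field(default=0.1, ge=0, le=1)
    p_target_nonsuspect: float = 0.01  # target appears with role SS/C in non-target reports
    p_concomitant: float = 0.3
    injected_signals: List[InjectedSignal] = Field(default_factory=list)
    # duplicates / deletions
    duplicate_rate: float = Field(default=0.0, ge=0, lt=1)
    duplicate_tie_fraction: float = Field(default=0.3, ge=0, le=1)
    max_extra_versions: int = Field(default=3, ge=1)
    deletion_rate: float = Field(default=0.0, ge=0, lt=1)
    # demographics
    sex_probs: Dict[str, float] = Field(
        default_factory=lambda: {"F": 0.513, "M": 0.356, "UNK": 0.131}
    )
    age_child_fraction: float = 0.01  # uniform 1-17 y component
    age_mean: float = 77.0
    age_sd: float = 9.5
    age_missing_rate: float = 0.247
    age_unit_probs: Dict[str, float] = Field(
        default_factory=lambda: {"YR": 0.93, "DEC": 0.05, "MON": 0.02}
    )
    country_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "US": 0.274, "GB": 0.264, "JP": 0.141, "IT": 0.053, "DE": 0.036,
            "FR": 0.08, "CA": 0.06, "ES": 0.05, "AU": 0.042,
        }
    )
    country_missing_rate: float = 0.052
    reporter_probs: Dict[str, float] = Field(
        default_factory=lambda: {"PH": 0.317, "CN": 0.246, "MD": 0.171, "HP": 0.119}
    )
    indication_probs: Dict[str, float] = Field(
        default_factory=lambda: {
            "Dementia Alzheimer's type": 0.338,
            "Product used for unknown indication": 0.232,
            "Dementia": 0.168,
            "Cognitive disorder": 0.033,
            "Memory impairment": 0.147,
        }
    )
    indication_missing_rate: float = 0.082
    outcome_probs: Dict[str, float] = Field(
        default_factory=lambda: {"DE": 0.084, "HO": 0.387, "DS": 0.038, "LT": 0.066, "OT": 0.275}
    )
    # dates and onset
    year_start: int = 2004
    year_end: int = 2024
    onset_median_days: float = 49.0
    onset_sigma: float = 1.4
    pre_treatment_rate: float = 0.02
    event_dt_missing_rate: float = 0.40
    event_dt_partial_rate: float = 0.05
    start_dt_missing_rate: float = 0.30
    start_dt_partial_rate: float = 0.08

    def pt_lexicon(self) -> List[str]:
        return [f"EVENT_{i:03d}" for i in range(1, self.n_pts + 1)]

    def soc_lexicon(self) -> List[str]:
        return [f"SOC_{chr(ord('A') + i)}" for i in range(self.n_socs)]

    def vocabulary(self) -> VocabularyMap:
        socs = self.soc_lexicon()
        return VocabularyMap(
            {pt: socs[i % len(socs)] for i, pt in enumerate(self.pt_lexicon())}
        )

    def other_drug_lexicon(self) -> List[str]:
        return [f"DRUG_{i:02d}" for i in range(1, self.n_other_drugs + 1)]


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually did, for closed-loop validation."""

    injected: List[dict]            # drug, pt, odds_multiplier, sex, expected_a
    duplicate_primaryids: List[int]  # non-canonical versions
    canonical_primaryids: Dict[int, int]  # caseid -> dedup-winning primaryid
    deleted_caseids: List[int]
    target_primaryids: List[int]    # version-1 primaryids of target reports
    onset_days: Dict[int, int]      # primaryid -> true onset (target reports, pre-censoring)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["canonical_primaryids"] = {str(k): v for k, v in d["canonical_primaryids"].items()}
        d["onset_days"] = {str(k): v for k, v in d["onset_days"].items()}
        return json.dumps(d, indent=1, sort_keys=True)


@dataclasses.dataclass
class SyntheticExtract:
    """In-memory quarter bundle plus ground truth.

    Table frames hold file-ready values (dates as YYYYMMDD / YYYYMM digit
    strings, empty string for missing) except ``fda_dt`` which stays an
    integer; ``write`` emits the ``$``-delimited files.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    outc: pd.DataFrame
    vocab: VocabularyMap
    truth: GroundTruth
    config: GeneratorConfig

    def write(self, outdir: str) -> Dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, df in (
            ("DEMO", self.demo), ("DRUG", self.drug), ("REAC", self.reac),
            ("THER", self.ther), ("INDI", self.indi), ("OUTC", self.outc),
        ):
            p = os.path.join(outdir, f"{name}.txt")
            df.to_csv(p, sep="$", index=False)
            paths[name] = p
        vp = os.path.join(outdir, "vocabulary.tsv")
        self.vocab.to_file(vp)
        paths["VOCAB"] = vp
        dp = os.path.join(outdir, "deleted_cases.txt")
        with open(dp, "w", encoding="utf-8") as fh:
            for c in sorted(self.truth.deleted_caseids):
                fh.write(f"{c}\n")
        paths["DELETED"] = dp
        gp = os.path.join(outdir, "ground_truth.json")
        with open(gp, "w", encoding="utf-8") as fh:
            fh.write(self.truth.to_json())
        paths["TRUTH"] = gp
        return paths


def _dates_to_int(days: np.ndarray, base: np.datetime64) -> np.ndarray:
    """Vectorised YYYYMMDD integers from day offsets."""
    dt = pd.DatetimeIndex(base + days.astype("timedelta64[D]"))
    return (dt.year * 10000 + dt.month * 100 + dt.day).to_numpy()


def _censor_dates(ints: np.ndarray, rng: np.random.Generator,
                  missing_rate: float, partial_rate: float) -> np.ndarray:
    """Turn full-date integers into strings with missing/month-precision
    injection."""
    u = rng.random(ints.size)
    out = ints.astype(str).astype(object)
    out[u < missing_rate] = ""
    partial = (u >= missing_rate) & (u < missing_rate + partial_rate)
    out[partial] = (ints[partial] // 100).astype(str)
    return out


def generate(config: GeneratorConfig) -> SyntheticExtract:
    """Generate a full synthetic extract (all six tables + ground truth)."""
    cfg = config
    pts = cfg.pt_lexicon()
    pt_index = {p: i for i, p in enumerate(pts)}
    other_drugs = cfg.other_drug_lexicon()
    for s in cfg.injected_signals:
        if s.pt not in pt_index:
            raise ValueError(f"injected signal references unknown PT {s.pt!r}")
        if s.drug != TARGET and s.drug not in other_drugs:
            raise ValueError(f"injected signal references unknown drug {s.drug!r}")

    ss = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("assign", "demo", "reac", "dates", "ther", "indi", "outc", "dup", "del"),
            ss.spawn(9),
        )
    }

    n = cfg.n_reports
    caseids = np.arange(1_000_000, 1_000_000 + n, dtype=np.int64)
    pids = caseids * 100 + 1

    # --- cohort assignment ------------------------------------------------
    rng = streams["assign"]
    is_target = rng.random(n) < cfg.p_target_report
    drug_idx = rng.integers(0, len(other_drugs), size=n)
    suspect = np.where(is_target, cfg.target_drugname, np.array(other_drugs)[drug_idx])

    # --- demographics -----------------------------------------------------
    rng = streams["demo"]
    sex_levels = list(cfg.sex_probs)
    sex = rng.choice(sex_levels, size=n, p=_norm(list(cfg.sex_probs.values())))
    child = rng.random(n) < cfg.age_child_fraction
    age_years = np.where(
        child,
        rng.uniform(1, 17, size=n),
        np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n), 18, 105),
    )
    unit_levels = list(cfg.age_unit_probs)
    units = rng.choice(unit_levels, size=n, p=_norm(list(cfg.age_unit_probs.values())))
    age_vals = np.where(
        units == "DEC", np.round(age_years / 10, 1),
        np.where(units == "MON", np.round(age_years * 12), np.round(age_years)),
    )
    age_missing = rng.random(n) < cfg.age_missing_rate
    country_levels = list(cfg.country_probs)
    country = rng.choice(country_levels, size=n, p=_norm(list(cfg.country_probs.values())))
    country_missing = rng.random(n) < cfg.country_missing_rate
    rep_levels = list(cfg.reporter_probs) + [""]
    rep_p = list(cfg.reporter_probs.values())
    rep_p.append(max(0.0, 1 - sum(rep_p)))
    occp = rng.choice(rep_levels, size=n, p=_norm(rep_p))

    # --- reactions: categorical PT draws with signal-adjusted weights ------
    rng = streams["reac"]
    k = 1 + rng.poisson(max(cfg.mean_pts_per_report - 1, 0), size=n)
    base_w = (np.arange(1, cfg.n_pts + 1, dtype=float)) ** (-cfg.pt_weight_alpha)
    base_w /= base_w.sum()

    sig_mask = np.zeros(n, dtype=np.int64)  # bitmask of applicable signals
    for j, s in enumerate(cfg.injected_signals):
        applies = suspect == (cfg.target_drugname if s.drug == TARGET else s.drug)
        if s.sex is not None:
            applies &= sex == s.sex
        sig_mask |= applies.astype(np.int64) << j

    report_of_draw = np.repeat(np.arange(n), k)
    draw_pts = np.empty(report_of_draw.size, dtype=np.int64)
    for mask_value in np.unique(sig_mask):
        w = base_w.copy()
        for j, s in enumerate(cfg.injected_signals):
            if mask_value >> j & 1:
                w[pt_index[s.pt]] *= s.odds_multiplier
        w = w / w.sum()
        sel = sig_mask[report_of_draw] == mask_value
        draw_pts[sel] = rng.choice(cfg.n_pts, size=int(sel.sum()), p=w)
    reac = pd.DataFrame(
        {
            "primaryid": pids[report_of_draw],
            "caseid": caseids[report_of_draw],
            "pt": np.array(pts, dtype=object)[draw_pts],
        }
    )

    # expected a per signal: distinct-(report, PT) counting over realised k
    injected_truth = []
    for j, s in enumerate(cfg.injected_signals):
        applies = (sig_mask >> j & 1).astype(bool)
        p_draw = base_w[pt_index[s.pt]] * s.odds_multiplier
        # renormalise within the group that carries this signal alone
        z = 1 - base_w[pt_index[s.pt]] + p_draw
        p_draw = p_draw / z
        expected_a = float(np.sum(1 - (1 - p_draw) ** k[applies]))
        injected_truth.append(
            {"drug": s.drug, "pt": s.pt, "odds_multiplier": s.odds_multiplier,
             "sex": s.sex, "expected_a": expected_a}
        )

    # --- dates and onset ----------------------------------------------------
    rng = streams["dates"]
    base = np.datetime64(f"{cfg.year_start}-01-01")
    horizon = (np.datetime64(f"{cfg.year_end}-12-31") - base).astype(int)
    event_day = rng.integers(0, horizon + 1, size=n)
    onset = np.round(
        rng.lognormal(np.log(cfg.onset_median_days), cfg.onset_sigma, size=n)
    ).astype(np.int64)
    onset = np.maximum(onset, 0)
    pre_treat = rng.random(n) < cfg.pre_treatment_rate
    start_day = np.where(pre_treat, event_day + rng.integers(1, 120, size=n),
                         event_day - onset)
    fda_day = event_day + rng.integers(0, 91, size=n)
    event_int = _dates_to_int(event_day, base)
    start_int = _dates_to_int(start_day, base)
    fda_int = _dates_to_int(fda_day, base)
    event_str = _censor_dates(event_int, rng, cfg.event_dt_missing_rate,
                              cfg.event_dt_partial_rate)

    demo = pd.DataFrame(
        {
            "primaryid": pids,
            "caseid": caseids,
            "fda_dt": fda_int,
            "event_dt": event_str,
            "sex": np.where(sex == "UNK", "", sex).astype(object),
            "age": np.where(age_missing, "", _num_str(age_vals)).astype(object),
            "age_cod": np.where(age_missing, "", units).astype(object),
            "occp_cod": occp.astype(object),
            "occr_country": np.where(country_missing, "", country).astype(object),
        }
    )

    # --- drug table ---------------------------------------------------------
    rng = streams["assign"]
    drug_rows = [
        pd.DataFrame(
            {
                "primaryid": pids, "caseid": caseids, "drug_seq": 1,
                "role_cod": "PS", "drugname": suspect,
                "prod_ai": np.where(
                    is_target, cfg.target_ingredient,
                    np.char.add(suspect.astype(str), " INGREDIENT"),
                ),
            }
        )
    ]
    conc = rng.random(n) < cfg.p_concomitant
    conc_drug = np.array(other_drugs)[rng.integers(0, len(other_drugs), size=n)]
    drug_rows.append(
        pd.DataFrame(
            {
                "primaryid": pids[conc], "caseid": caseids[conc], "drug_seq": 2,
                "role_cod": "C", "drugname": conc_drug[conc],
                "prod_ai": np.char.add(conc_drug[conc].astype(str), " INGREDIENT"),
            }
        )
    )
    nonsusp = (~is_target) & (rng.random(n) < cfg.p_target_nonsuspect)
    drug_rows.append(
        pd.DataFrame(
            {
                "primaryid": pids[nonsusp], "caseid": caseids[nonsusp], "drug_seq": 3,
                "role_cod": "SS", "drugname": cfg.target_drugname,
                "prod_ai": cfg.target_ingredient,
            }
        )
    )
    drug = pd.concat(drug_rows, ignore_index=True).sort_values(
        ["primaryid", "drug_seq"], kind="mergesort"
    ).reset_index(drop=True)

    # --- therapy table (suspect drug only) -----------------------------------
    rng = streams["ther"]
    start_str = _censor_dates(start_int, rng, cfg.start_dt_missing_rate,
                              cfg.start_dt_partial_rate)
    dur = rng.integers(30, 721, size=n)
    end_int = _dates_to_int(start_day + dur, base)
    ther = pd.DataFrame(
        {
            "primaryid": pids, "caseid": caseids, "dsg_drug_seq": 1,
            "start_dt": start_str, "end_dt": end_int.astype(str),
        }
    )

    # --- indications ----------------------------------------------------------
    rng = streams["indi"]
    indi_levels = list(cfg.indication_probs)
    ipt = rng.choice(indi_levels, size=n, p=_norm(list(cfg.indication_probs.values())))
    keep = rng.random(n) >= cfg.indication_missing_rate
    indi = pd.DataFrame(
        {
            "primaryid": pids[keep], "caseid": caseids[keep],
            "indi_drug_seq": 1, "indi_pt": ipt[keep],
        }
    )

    # --- outcomes ---------------------------------------------------------------
    rng = streams["outc"]
    outc_parts = []
    for code, p in cfg.outcome_probs.items():
        hit = rng.random(n) < p
        outc_parts.append(
            pd.DataFrame({"primaryid": pids[hit], "caseid": caseids[hit], "outc_cod": code})
        )
    outc = pd.concat(outc_parts, ignore_index=True).sort_values(
        ["primaryid", "outc_cod"], kind="mergesort"
    ).reset_index(drop=True)

    # --- duplicates ---------------------------------------------------------------
    demo, dup_pids, canonical, version_map = make_duplicates(
        demo, cfg.duplicate_rate, streams["dup"],
        tie_fraction=cfg.duplicate_tie_fraction,
        max_extra_versions=cfg.max_extra_versions,
    )
    if version_map:
        drug = _replicate_versions(drug, version_map)
        reac = _replicate_versions(reac, version_map)
        ther = _replicate_versions(ther, version_map)
        indi = _replicate_versions(indi, version_map)
        outc = _replicate_versions(outc, version_map)

    # --- deletions -------------------------------------------------------------------
    rng = streams["del"]
    deleted = caseids[rng.random(n) < cfg.deletion_rate]

    truth = GroundTruth(
        injected=injected_truth,
        duplicate_primaryids=[int(p) for p in dup_pids],
        canonical_primaryids=canonical,
        deleted_caseids=[int(c) for c in deleted],
        target_primaryids=[int(p) for p in pids[is_target]],
        onset_days={
            int(p): int(o)
            for p, o, pt_ in zip(pids[is_target], onset[is_target], pre_treat[is_target])
            if not pt_
        },
        )
    return SyntheticExtract(
        demo=demo, drug=drug, reac=reac, ther=ther, indi=indi, outc=outc,
        vocab=cfg.vocabulary(), truth=truth, config=cfg,
    )


def _norm(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise ValueError("probabilities must be nonnegative")
    return arr / arr.sum()


def _num_str(vals: np.ndarray) -> np.ndarray:
    out = np.empty(vals.size, dtype=object)
    for i, v in enumerate(vals):
        out[i] = str(int(v)) if float(v) == int(v) else str(v)
    return out


def make_duplicates(
    demo: pd.DataFrame,
    rate: float,
    rng: np.random.Generator,
    tie_fraction: float = 0.3,
    max_extra_versions: int = 3,
) -> Tuple[pd.DataFrame, List[int], Dict[int, int], Dict[int, List[int]]]:
    """Re-emit a fraction of cases as additional report versions.

    Each selected case gains 1..``max_extra_versions`` extra DEMO rows
    with incremented primaryid and (cumulatively) later ``fda_dt``; a
    ``tie_fraction`` of the increments reuse the previous version's
    ``fda_dt`` so the primaryid tie-break is exercised.  Returns the
    augmented DEMO, the list of non-canonical (superseded) primaryids,
    the caseid → canonical-primaryid map, and the caseid → new-version
    primaryid lists (used to replicate the other tables).
    """
    if not 0 <= rate < 1:
        raise ValueError("duplicate rate must be in [0, 1)")
    n = len(demo)
    canonical = dict(zip(demo["caseid"].astype(int), demo["primaryid"].astype(int)))
    if rate == 0 or n == 0:
        return demo, [], canonical, {}
    pick_idx = np.flatnonzero(rng.random(n) < rate)
    if pick_idx.size == 0:
        return demo, [], canonical, {}
    n_extra = rng.integers(1, max_extra_versions + 1, size=pick_idx.size)
    total = int(n_extra.sum())
    rep = np.repeat(pick_idx, n_extra)
    version_no = np.concatenate([np.arange(1, e + 1) for e in n_extra])

    # cumulative day advances within each case; a tie keeps the previous
    # version's fda_dt so the primaryid tie-break gets exercised
    adv = rng.integers(1, 181, size=total)
    adv[rng.random(total) < tie_fraction] = 0
    cs = np.cumsum(adv)
    case_first = np.concatenate([[0], np.cumsum(n_extra)[:-1]])
    cum_adv = cs - np.repeat(np.where(case_first > 0, cs[case_first - 1], 0), n_extra)

    base_pid = demo["primaryid"].to_numpy()[rep]
    base_fda = pd.to_datetime(
        demo["fda_dt"].to_numpy()[rep].astype(str), format="%Y%m%d"
    )
    new_fda_dt = base_fda + pd.to_timedelta(cum_adv, unit="D")
    new_rows = demo.iloc[rep].copy()
    new_rows["primaryid"] = base_pid + version_no
    new_rows["fda_dt"] = (
        new_fda_dt.year * 10000 + new_fda_dt.month * 100 + new_fda_dt.day
    ).to_numpy()

    caseids = demo["caseid"].to_numpy()
    all_pids = demo["primaryid"].to_numpy()
    dup_pids: List[int] = []
    version_map: Dict[int, List[int]] = {}
    for i, e in zip(pick_idx, n_extra):
        caseid = int(caseids[i])
        pids = [int(all_pids[i]) + v for v in range(1, int(e) + 1)]
        version_map[caseid] = pids
        canonical[caseid] = pids[-1]
        dup_pids.extend([int(all_pids[i])] + pids[:-1])
    dup_pids = sorted(set(dup_pids))
    out = pd.concat([demo, new_rows], ignore_index=True)
    out = out.sort_values(["caseid", "primaryid"], kind="mergesort").reset_index(drop=True)
    return out, dup_pids, canonical, version_map


def _replicate_versions(table: pd.DataFrame, version_map: Dict[int, List[int]]) -> pd.DataFrame:
    """Duplicate a case's rows under each new version primaryid (FAERS
    re-submits the full report per version)."""
    ver = pd.DataFrame(
        [(cid, pid) for cid, pids in version_map.items() for pid in pids],
        columns=["caseid", "_new_pid"],
    )
    dup = table[table["caseid"].isin(version_map)].merge(ver, on="caseid")
    dup["primaryid"] = dup["_new_pid"]
    dup = dup[table.columns]
    out = pd.concat([table, dup], ignore_index=True)
    return out.sort_values(["caseid", "primaryid"], kind="mergesort").reset_index(drop=True)


def preset(name: str, seed: int = 0) -> GeneratorConfig:
    """Frozen, documented generator configurations.

    * ``minimal`` — 100 reports, 3 background drugs, 5 PTs, no injection,
      no duplicates: the smallest end-to-end smoke input.
    * ``paper_like`` — a donepezil-study-shaped extract: ≈9,000 target
      reports out of 30,000, sex split 51.3% F / 35.6% M, elderly age
      mixture, ≈2.9 PTs per report, log-normal onset with median 49 days,
      duplicates and deletions on, three injected signals of graded
      strength (odds ×32, ×11, ×2.5).
    * ``sex_specific_signal`` — one PT with reporting odds ×20 in female
      target reports only.
    * ``null`` — moderate size, no injected signals, for calibration of
      the four-criteria conjunction.
    """
    if name == "minimal":
        return GeneratorConfig(
            seed=seed, n_reports=100, n_other_drugs=3, n_pts=5, n_socs=2,
            mean_pts_per_report=2.0, p_target_report=0.3,
            duplicate_rate=0.0, deletion_rate=0.0,
            event_dt_missing_rate=0.1, start_dt_missing_rate=0.1,
        )
    if name == "paper_like":
        # target share 5% keeps EBGM close to ROR (a dominant target drug
        # would dilute observed/expected); injected PTs sit deep in the
        # Zipf tail so the three signals' inflated weights add only ~3%
        # mass and barely mask one another
        return GeneratorConfig(
            seed=seed, n_reports=180_000, n_other_drugs=20, n_pts=500, n_socs=15,
            mean_pts_per_report=2.9, p_target_report=0.05,
            duplicate_rate=0.05, deletion_rate=0.005,
            injected_signals=[
                InjectedSignal(pt="EVENT_450", odds_multiplier=32.0),
                InjectedSignal(pt="EVENT_470", odds_multiplier=11.0),
                InjectedSignal(pt="EVENT_300", odds_multiplier=2.5),
            ],
        )
    if name == "sex_specific_signal":
        return GeneratorConfig(
            seed=seed, n_reports=12_000, n_other_drugs=10, n_pts=60, n_socs=8,
            mean_pts_per_report=3.0, p_target_report=0.2,
            sex_probs={"F": 0.48, "M": 0.48, "UNK": 0.04},
            injected_signals=[
                InjectedSignal(pt="EVENT_030", odds_multiplier=20.0, sex="F"),
            ],
        )
    if name == "null":
        return GeneratorConfig(
            seed=seed, n_reports=4_000, n_other_drugs=10, n_pts=60, n_socs=8,
            mean_pts_per_report=3.0, p_target_report=0.15,
        )
    raise ValueError(
        f"unknown preset {name!r}; available: minimal, paper_like, sex_specific_signal, null"
    )


PRESETS = ("minimal", "paper_like", "sex_specific_signal", "null")
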