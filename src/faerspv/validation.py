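"""Closed-loop validation experiments against generator ground truth.

These are the package's own calibration studies, run both in the test
suite and by the reproduction script:

* **ROR recovery** — inject a known reporting-odds multiplier and check
  that the estimated ROR's 95% CI covers it at the nominal rate and that
  log-ROR is unbiased;
* **null calibration** — with nothing injected, measure how often the
  conjunction of all four signal criteria fires among PTs with a ≥ 3
  (the conjunction is conservative; the observed rate is reported, not
  assumed);
* **sex-specific recovery** — a female-only injected signal must be
  flagged in the female stratum and not in the male stratum.

Every experiment derives its per-replicate generator seeds from one
master seed, so a single integer reproduces the whole study.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .cohort import ReportCase
from .describe import stratified_signals
from .io import normalize_pt
from .pipeline import analyze_extract
from .records import Sex
from .stats import build_contingency, compute_ror, signal_table
from .synthetic import GeneratorConfig, InjectedSignal, generate, preset

__all__ = [
    "recovery_config",
    "ror_recovery_experiment",
    "null_calibration_experiment",
    "sex_specific_experiment",
]

RECOVERY_MULTIPLIER = 11.0
RECOVERY_PT = "EVENT_100"


def _child_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def recovery_config(seed: int) -> GeneratorConfig:
    """Frozen conditions for the ROR-recovery study: 20,000 reports, 10%
    target share, ~3 PTs per report from a Zipf(1.3) lexicon of 300, one
    injected signal with reporting odds ×11 whose baseline weight puts
    the expected target-with-event count near 50 records."""
    return GeneratorConfig(
        seed=seed, n_reports=20_000, n_other_drugs=10, n_pts=300, n_socs=10,
        pt_weight_alpha=1.3, mean_pts_per_report=3.0, p_target_report=0.1,
        injected_signals=[
            InjectedSignal(pt=RECOVERY_PT, odds_multiplier=RECOVERY_MULTIPLIER)
        ],
    )


def ror_recovery_experiment(master_seed: int, n_replicates: int = 100) -> Dict[str, float]:
    """Replicate the recovery study and summarise coverage and bias.

    Returns the number of replicates whose 95% CI covers the true
    multiplier, the mean log-ROR with its Monte-Carlo standard error,
    and the mean observed/expected event counts.
    """
    covered = 0
    logs = []
    a_obs, a_exp = [], []
    for seed in _child_seeds(master_seed, n_replicates):
        extract = generate(recovery_config(int(seed)))
        events, _, _ = analyze_extract(extract)
        t = build_contingency(events, RECOVERY_PT, "PT")
        ror, lo, hi = compute_ror(t)
        if lo <= RECOVERY_MULTIPLIER <= hi:
            covered += 1
        logs.append(np.log(ror))
        a_obs.append(t.a)
        a_exp.append(extract.truth.injected[0]["expected_a"])
    logs = np.asarray(logs)
    return {
        "n_replicates": n_replicates,
        "true_odds_multiplier": RECOVERY_MULTIPLIER,
        "ci_covered": int(covered),
        "coverage_pct": 100.0 * covered / n_replicates,
        "mean_log_ror": float(logs.mean()),
        "true_log_odds": float(np.log(RECOVERY_MULTIPLIER)),
        "mc_se_log_ror": float(logs.std(ddof=1) / np.sqrt(n_replicates)),
        "mean_a": float(np.mean(a_obs)),
        "mean_expected_a": float(np.mean(a_exp)),
    }


def null_calibration_experiment(master_seed: int, n_replicates: int = 500) -> Dict[str, float]:
    """No-injection runs: fraction of PTs with a ≥ 3 flagged by all four
    criteria simultaneously (the empirical false-signal rate of the
    conjunction)."""
    flagged = 0
    eligible = 0
    for seed in _child_seeds(master_seed, n_replicates):
        extract = generate(preset("null", seed=int(seed)))
        events, _, _ = analyze_extract(extract)
        table = signal_table(events, level="PT")
        table = table[table["a"] >= 3]
        eligible += int(len(table))
        flagged += int(table["all_four"].sum())
    return {
        "n_replicates": n_replicates,
        "n_eligible_pts": eligible,
        "n_flagged_all_four": flagged,
        "all_four_rate_pct": 100.0 * flagged / max(eligible, 1),
    }


def sex_specific_experiment(master_seed: int, n_replicates: int = 20) -> Dict[str, float]:
    """Female-only injected signal: count replicates where the PT meets
    all four criteria in the female stratum and not in the male one."""
    detected = 0
    for seed in _child_seeds(master_seed, n_replicates):
        extract = generate(preset("sex_specific_signal", seed=int(seed)))
        events, _, targets = analyze_extract(extract)
        sig_pt = normalize_pt(extract.config.injected_signals[0].pt)
        sexes = dict(zip(extract.demo.primaryid.astype(int), extract.demo.sex))
        cases = [
            ReportCase(
                primaryid=int(p), caseid=0, is_target=(p in targets),
                sex=Sex(sx) if sx in ("F", "M") else Sex.UNK,
            )
            for p, sx in sexes.items()
        ]
        flags = {}
        for stratum in ("female", "male"):
            table = stratified_signals(events, cases, stratum, top_k=None)
            row = table[table["pt"] == sig_pt]
            flags[stratum] = bool(row["all_four"].iloc[0]) if len(row) else False
        if flags["female"] and not flags["male"]:
            detected += 1
    return {
        "n_replicates": n_replicates,
        "n_detected_female_only": detected,
    }
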