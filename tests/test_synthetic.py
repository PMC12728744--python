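"""Generator: reproducibility, duplicates, injection ground truth, presets."""

import hashlib
import json

import numpy as np
import pandas as pd
import pytest

import faerspv as f
from faerspv.io import normalize_pt
from faerspv.synthetic import make_duplicates


def _hash_dir(extract, tmp_path, name):
    d = tmp_path / name
    paths = extract.write(str(d))
    h = hashlib.sha256()
    for k in sorted(paths):
        h.update(open(paths[k], "rb").read())
    return h.hexdigest()


def test_same_seed_and_config_byte_identical(tmp_path):
    cfg = f.preset("minimal", seed=9).model_copy(
        update={"duplicate_rate": 0.1, "deletion_rate": 0.05}
    )
    h1 = _hash_dir(f.generate(cfg), tmp_path, "a")
    h2 = _hash_dir(f.generate(cfg), tmp_path, "b")
    assert h1 == h2
    h3 = _hash_dir(f.generate(cfg.model_copy(update={"seed": 10})), tmp_path, "c")
    assert h1 != h3


def test_no_duplicates_no_deletions_dedup_is_identity():
    cfg = f.preset("minimal", seed=1)
    assert cfg.duplicate_rate == 0 and cfg.deletion_rate == 0
    ex = f.generate(cfg)
    res = f.deduplicate(ex.demo[["primaryid", "caseid", "fda_dt"]])
    assert len(res.retained_primaryids) == len(ex.demo)
    assert res.removed_as_duplicate == 0


def test_duplicate_versions_resolved_to_canonical():
    cfg = f.preset("minimal", seed=3).model_copy(
        update={"duplicate_rate": 0.3, "n_reports": 300}
    )
    ex = f.generate(cfg)
    res = f.deduplicate(ex.demo[["primaryid", "caseid", "fda_dt"]])
    assert res.retained_primaryids == set(ex.truth.canonical_primaryids.values())
    assert res.removed_as_duplicate == len(ex.truth.duplicate_primaryids)
    # superseded versions never retained
    assert not (res.retained_primaryids & set(ex.truth.duplicate_primaryids))


def test_make_duplicates_rate_zero_identity():
    demo = pd.DataFrame({"primaryid": [101], "caseid": [1], "fda_dt": [20200101]})
    out, dups, canonical, vmap = make_duplicates(demo, 0.0, np.random.default_rng(0))
    assert out is demo and dups == [] and vmap == {} and canonical == {1: 101}


def test_make_duplicates_later_version_wins():
    demo = pd.DataFrame({"primaryid": [101], "caseid": [1], "fda_dt": [20200101]})
    rng = np.random.default_rng(1)
    out, dups, canonical, vmap = make_duplicates(
        demo, 0.999, rng, tie_fraction=0.0, max_extra_versions=2
    )
    assert len(out) > 1
    res = f.deduplicate(out)
    assert res.retained_primaryids == {canonical[1]}
    # later emissions have strictly increasing fda_dt
    assert out.sort_values("primaryid").fda_dt.is_monotonic_increasing


def test_make_duplicates_tie_break_by_primaryid():
    demo = pd.DataFrame({"primaryid": [101], "caseid": [1], "fda_dt": [20200101]})
    rng = np.random.default_rng(2)
    out, _, canonical, _ = make_duplicates(
        demo, 0.999, rng, tie_fraction=1.0, max_extra_versions=1
    )
    # tie on fda_dt: all versions share the date, highest primaryid retained
    assert out.fda_dt.nunique() == 1
    assert f.deduplicate(out).retained_primaryids == {out.primaryid.max()} == {canonical[1]}


def test_other_tables_replicated_for_new_versions():
    cfg = f.preset("minimal", seed=5).model_copy(
        update={"duplicate_rate": 0.5, "n_reports": 50}
    )
    ex = f.generate(cfg)
    # every retained primaryid has REAC rows (analysis never loses content)
    res = f.deduplicate(ex.demo[["primaryid", "caseid", "fda_dt"]])
    assert res.retained_primaryids <= set(ex.reac.primaryid)


def test_injected_signal_recovers_population_ror():
    """The categorical-weight injection makes the population record-level
    ROR equal the odds multiplier; the estimator is unbiased on the log
    scale (mean over seeds within 4 standard errors)."""
    logs, ses = [], []
    for seed in range(5):
        cfg = f.GeneratorConfig(
            seed=seed, n_reports=20_000, n_pts=100, pt_weight_alpha=0.5,
            p_target_report=0.2, mean_pts_per_report=3.0,
            injected_signals=[f.InjectedSignal(pt="EVENT_050", odds_multiplier=11.0)],
        )
        ex = f.generate(cfg)
        events, dd, targets = f.analyze_extract(ex)
        t = f.build_contingency(events, "EVENT_050", "PT")
        ror, lo, hi = f.compute_ror(t)
        logs.append(np.log(ror))
        ses.append(np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d))
        assert t.a == pytest.approx(ex.truth.injected[0]["expected_a"], rel=0.5)
    se_mean = np.sqrt(np.mean(np.square(ses)) / len(ses))
    assert abs(np.mean(logs) - np.log(11.0)) < 4 * se_mean


def test_unknown_signal_pt_fatal():
    cfg = f.GeneratorConfig(
        n_pts=5, injected_signals=[f.InjectedSignal(pt="EVENT_099", odds_multiplier=2.0)]
    )
    with pytest.raises(ValueError, match="unknown PT"):
        f.generate(cfg)
    cfg2 = f.GeneratorConfig(
        n_pts=5,
        injected_signals=[f.InjectedSignal(drug="NOSUCH", pt="EVENT_001", odds_multiplier=2.0)],
    )
    with pytest.raises(ValueError, match="unknown drug"):
        f.generate(cfg2)


def test_preset_minimal_shape():
    cfg = f.preset("minimal")
    assert cfg.n_reports == 100 and cfg.n_other_drugs == 3 and cfg.n_pts == 5
    assert cfg.injected_signals == []


def test_preset_sex_specific_construction():
    cfg = f.preset("sex_specific_signal")
    [sig] = cfg.injected_signals
    assert sig.sex == "F" and sig.odds_multiplier == 20.0


def test_preset_unknown_name_lists_presets():
    with pytest.raises(ValueError, match="minimal"):
        f.preset("bogus")


def test_ground_truth_json_round_trips(minimal_extract):
    d = json.loads(minimal_extract.truth.to_json())
    assert set(d) == {
        "injected", "duplicate_primaryids", "canonical_primaryids",
        "deleted_caseids", "target_primaryids", "onset_days",
    }
    assert sorted(int(p) for p in d["target_primaryids"]) == sorted(
        minimal_extract.truth.target_primaryids
    )


def test_vocabulary_covers_all_emitted_pts(minimal_extract):
    ex = minimal_extract
    assert all(pt in ex.vocab for pt in ex.reac.pt.unique())


def test_files_parse_cleanly(written_bundle):
    extract, paths, _ = written_bundle
    demo, rep = f.read_table(paths["DEMO"], "DEMO")
    assert rep.records_skipped == 0
    assert len(demo) == len(extract.demo)
    # in-memory and file routes agree on the event table
    vocab = f.VocabularyMap.from_file(paths["VOCAB"])
    dd = f.deduplicate(demo)
    dd = f.apply_deletions(dd, f.read_deletion_list(paths["DELETED"]))
    drugs, _ = f.read_table(paths["DRUG"], "DRUG")
    reac, _ = f.read_table(paths["REAC"], "REAC")
    targets = f.select_target_reports(drugs, dd.retained_primaryids, ["donepezil"])
    events_file = f.build_event_table(reac, dd.retained_primaryids, targets, vocab)
    events_mem, _, targets_mem = f.analyze_extract(extract)
    assert targets == targets_mem
    pd.testing.assert_frame_equal(
        events_file.reset_index(drop=True), events_mem.reset_index(drop=True)
    )
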