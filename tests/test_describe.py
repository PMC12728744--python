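"""Descriptive characterisation and sex-stratified signal batteries."""

import numpy as np
import pandas as pd
import pytest

import faerspv as f
from faerspv.cohort import ReportCase
from faerspv.describe import stratified_signals
from faerspv.records import Sex


def case(pid, sex="F", age=None, country=None, year=None, outcomes=(), indi=(),
         reporter=None, target=True):
    return ReportCase(
        primaryid=pid, caseid=pid, is_target=target, sex=Sex(sex),
        age_years=age, country=country, report_year=year,
        outcomes=set(outcomes), indications=set(indi),
        reporter_occupation=reporter,
    )


class TestDescribeCohort:
    def test_sex_percentages(self):
        s = f.describe_cohort([case(1, "F"), case(2, "F"), case(3, "M"), case(4, "M")])
        assert s.sex["F"] == (2, 50.0) and s.sex["M"] == (2, 50.0)

    def test_age_bins(self):
        s = f.describe_cohort([case(i, age=a) for i, a in enumerate([70, 80, 90])])
        assert s.age_bins["65-84"][0] == 2 and s.age_bins[">=85"][0] == 1

    def test_blocks_sum_to_cohort_size(self):
        cases = [
            case(1, "F", 70, "US", 2019, outcomes={"HO"}, reporter="pharmacist"),
            case(2, "M", 90, "GB", 2020, outcomes={"DE", "HO"}),
            case(3, "UNK", None, None, 2020),
        ]
        s = f.describe_cohort(cases)
        assert sum(c for c, _ in s.sex.values()) == s.n
        assert sum(c for c, _ in s.age_bins.values()) == s.n
        assert sum(c for c, _ in s.reporters.values()) == s.n
        # percentages recompute from counts
        for c, p in s.sex.values():
            assert p == pytest.approx(100 * c / s.n)

    def test_topk_tie_broken_by_name(self):
        cases = [case(1, country="ZZ"), case(2, country="AA")]
        s = f.describe_cohort(cases, top_k=1)
        assert s.top_countries[0][0] == "AA"

    def test_percentages_scale_invariant(self):
        cases = [case(i, ["F", "M", "UNK"][i % 3], age=60 + i) for i in range(9)]
        doubled = cases + [case(100 + c.primaryid, c.sex.value, c.age_years) for c in cases]
        s1, s2 = f.describe_cohort(cases), f.describe_cohort(doubled)
        for k in s1.sex:
            assert s1.sex[k][1] == pytest.approx(s2.sex[k][1])
        for k in s1.age_bins:
            assert s1.age_bins[k][1] == pytest.approx(s2.age_bins[k][1])

    def test_generator_female_share_matches_configured_probability(self):
        """P(F)=0.513 at n=8,943 lands inside binomial 99% bounds."""
        ex = f.generate(
            f.preset("null", seed=3).model_copy(update={"n_reports": 8943})
        )
        share = (ex.demo.sex == "F").mean()
        se = np.sqrt(0.513 * 0.487 / 8943)
        assert abs(share - 0.513) < 2.576 * se


class TestYearlyTrend:
    def test_single_case(self):
        t = f.yearly_trend([case(1, year=2019)])
        assert t.loc[0, "year"] == 2019 and t.loc[0, "total"] == 1

    def test_scaled_total(self):
        cases = [case(i, year=2019) for i in range(848)]
        t = f.yearly_trend(cases, scale_factor=0.25)
        assert t.loc[0, "total_scaled"] == pytest.approx(212.0)

    def test_country_groups_and_empty_group(self):
        cases = [case(1, country="US", year=2020), case(2, country="JP", year=2020)]
        t = f.yearly_trend(cases, {"USA": {"US"}, "NONE": {"XX"}})
        assert t.loc[0, "USA"] == 1 and t.loc[0, "NONE"] == 0

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            f.yearly_trend([case(1, year=2019)], scale_factor=0)


class TestStratified:
    def _events_and_cases(self):
        ex = f.generate(f.preset("sex_specific_signal", seed=4))
        events, dd, targets = f.analyze_extract(ex)
        sex_of = dict(zip(ex.demo.primaryid.astype(int), ex.demo.sex))
        cases = [
            case(int(p), sx if sx in ("F", "M") else "UNK", target=(p in targets))
            for p, sx in sex_of.items()
        ]
        return events, cases

    def test_stratum_margins_sum_to_pooled(self):
        """a_female + a_male + a_unknown = pooled a for every PT."""
        events, cases = self._events_and_cases()
        pooled = f.signal_table(events, level="PT").set_index("pt")["a"]
        parts = []
        for s in ("female", "male"):
            t = stratified_signals(events, cases, s, top_k=None)
            parts.append(t.set_index("pt")["a"])
        sex_of = {c.primaryid: c.sex.value for c in cases}
        unk = events[
            events.is_target & (events.primaryid.map(sex_of) == "UNK")
        ].groupby("pt").size()
        total = (
            parts[0].reindex(pooled.index, fill_value=0)
            + parts[1].reindex(pooled.index, fill_value=0)
            + unk.reindex(pooled.index, fill_value=0)
        )
        pd.testing.assert_series_equal(total, pooled, check_names=False, check_dtype=False)

    def test_female_only_pt_absent_from_male_stratum(self, vocab):
        from faerspv.records import ReacRecord

        reac = [ReacRecord(1, 1, "Nausea"), ReacRecord(2, 2, "Fall")]
        events = f.build_event_table(reac, {1, 2}, {1, 2}, vocab)
        cases = [case(1, "F"), case(2, "M")]
        fem = stratified_signals(events, cases, "female", top_k=None)
        assert set(fem.pt) == {"nausea"}

    def test_sorted_by_frequency_and_topk(self):
        events, cases = self._events_and_cases()
        t = stratified_signals(events, cases, "female", top_k=10)
        assert len(t) == 10
        assert (t.a.to_numpy() == np.sort(t.a.to_numpy())[::-1]).all()
        assert (t.stratum == "female").all()

    def test_between_sex_contrast_runs(self):
        events, cases = self._events_and_cases()
        t = stratified_signals(events, cases, "female", top_k=None, contrast="between_sex")
        # a + c counts only target records of known sex
        sex_of = {c.primaryid: c.sex.value for c in cases}
        known = events[events.is_target & events.primaryid.map(sex_of).isin(["F", "M"])]
        assert t.a.sum() + t.c.sum() == len(known)

    def test_no_sex_injection_ror_ratio_centred_on_one(self):
        """With a sex-balanced generator and no sex-specific injection the
        per-PT female/male ROR ratio is centred on 1 (median of per-seed
        medians within [0.8, 1.25])."""
        medians = []
        for seed in range(8):
            cfg = f.preset("null", seed=seed).model_copy(
                update={"sex_probs": {"F": 0.49, "M": 0.49, "UNK": 0.02},
                        "n_reports": 8000, "p_target_report": 0.3}
            )
            ex = f.generate(cfg)
            events, dd, targets = f.analyze_extract(ex)
            sex_of = dict(zip(ex.demo.primaryid.astype(int), ex.demo.sex))
            cases = [
                case(int(p), sx if sx in ("F", "M") else "UNK", target=(p in targets))
                for p, sx in sex_of.items()
            ]
            fem = stratified_signals(events, cases, "female", top_k=None).set_index("pt")
            mal = stratified_signals(events, cases, "male", top_k=None).set_index("pt")
            common = fem.index[(fem.a >= 30)].intersection(mal.index[mal.a >= 30])
            ratio = (fem.loc[common, "ror"] / mal.loc[common, "ror"]).dropna()
            if len(ratio):
                medians.append(float(ratio.median()))
        assert 0.8 <= float(np.median(medians)) <= 1.25

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ValueError):
            stratified_signals(pd.DataFrame(), [], "other")
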