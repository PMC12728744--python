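"""Disproportionality statistics: worked values, laws, oracles, flags."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import faerspv as f
from faerspv.stats import _metrics_arrays, signal_table
from conftest import independence_tables, random_tables

T = f.ContingencyTable(10, 90, 100, 9900)


class TestWorkedValues:
    def test_ror(self):
        ror, lo, hi = f.compute_ror(T)
        assert ror == pytest.approx(11.0)          # ad/bc = 99000/9000
        assert lo < 11.0 < hi

    def test_prr_and_chi2(self):
        prr, chi2 = f.compute_prr(T)
        assert prr == pytest.approx(10.0)          # 10*10000/(100*100)
        # printed-formula value, cross-checked against scipy's Pearson chi2
        assert chi2 == pytest.approx(74.4471744, abs=1e-6)
        assert chi2 == pytest.approx(
            chi2_contingency([[10, 90], [100, 9900]], correction=False).statistic
        )

    def test_ic_and_ebgm(self):
        ic, ic025 = f.compute_ic(T)
        ebgm, ebgm05 = f.compute_ebgm(T)
        assert ebgm == pytest.approx(10 * 10100 / (110 * 100))  # 9.1818...
        assert ic == pytest.approx(np.log2(9.18181818), abs=1e-6)
        assert ic == pytest.approx(3.1988, abs=1e-4)
        assert 2.0 ** ic025 == pytest.approx(ebgm05)

    def test_independence_table(self):
        t = f.ContingencyTable(10, 90, 100, 900)
        ror, lo, hi = f.compute_ror(t)
        assert ror == pytest.approx(1.0) and lo < 1.0 < hi
        assert f.compute_prr(t) == (pytest.approx(1.0), pytest.approx(0.0))
        assert f.compute_ic(t)[0] == pytest.approx(0.0)
        assert f.compute_ebgm(t)[0] == pytest.approx(1.0)


class TestDegenerate:
    def test_zero_cell_makes_ror_undefined(self):
        t = f.ContingencyTable(5, 0, 3, 10)
        ror, lo, hi = f.compute_ror(t)
        assert np.isnan(ror) and np.isnan(lo) and np.isnan(hi)

    def test_c_zero_makes_prr_undefined(self):
        prr, _ = f.compute_prr(f.ContingencyTable(5, 5, 0, 10))
        assert np.isnan(prr)

    def test_a_zero_gives_minus_inf_ic_and_no_signal(self):
        m = f.compute_metrics(f.ContingencyTable(0, 10, 5, 100))
        assert m.ic == -np.inf and m.ic025 == -np.inf
        assert not (m.ror_sig or m.prr_sig or m.bcpnn_sig or m.mgps_sig or m.all_four)

    def test_haldane_correction_defines_zero_cell_tables(self):
        t = f.ContingencyTable(5, 0, 3, 10)
        ror, lo, hi = f.compute_ror(t, zero_cell_policy="haldane")
        assert np.isfinite(ror) and lo < ror < hi

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            f.ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            f.ContingencyTable(0, 0, 0, 0)


class TestFlags:
    def test_small_a_blocks_ror_signal(self):
        # huge ROR but a=2 -> below the a>=3 case threshold
        m = f.compute_metrics(f.ContingencyTable(2, 10, 1, 10_000))
        assert not m.ror_sig and not m.all_four

    def test_independence_flags_all_false(self):
        m = f.compute_metrics(f.ContingencyTable(100, 900, 1000, 9000))
        assert not any([m.ror_sig, m.prr_sig, m.bcpnn_sig, m.mgps_sig, m.all_four])

    def test_strong_signal_meets_all_four(self):
        # bradycardia-like scale: a=739 against a weak background
        m = f.compute_metrics(f.ContingencyTable(739, 10_494, 3_000, 4_000_000))
        assert m.ror_sig and m.prr_sig and m.bcpnn_sig and m.mgps_sig and m.all_four

    def test_classify_signal_recomputes(self):
        m = f.compute_metrics(f.ContingencyTable(50, 100, 10, 10_000))
        m.all_four = False
        assert f.classify_signal(m).all_four


class TestLaws:
    """Algebraic invariants on randomly generated tables."""

    def test_independence_law(self):
        rng = np.random.default_rng(101)
        cells = independence_tables(rng, 1000)
        m = _metrics_arrays(*cells.T)
        for key, target in (("ror", 1), ("prr", 1), ("ebgm", 1), ("ic", 0), ("chi2", 0)):
            np.testing.assert_allclose(m[key], target, atol=1e-9)

    def test_identity_ebgm_is_two_to_the_ic(self):
        rng = np.random.default_rng(7)
        cells = random_tables(rng, 5000)
        m = _metrics_arrays(*cells.T)
        np.testing.assert_allclose(2.0 ** m["ic"], m["ebgm"], rtol=1e-12)
        np.testing.assert_allclose(2.0 ** m["ic025"], m["ebgm05"], rtol=1e-12)

    def test_ordering_law(self):
        """sign(ror - prr) = sign(ror - 1) on nondegenerate tables."""
        rng = np.random.default_rng(13)
        cells = random_tables(rng, 10_000)
        m = _metrics_arrays(*cells.T)
        s1 = np.sign(m["ror"] - m["prr"])
        s2 = np.sign(m["ror"] - 1)
        close = np.isclose(m["ror"], 1, atol=1e-12)
        assert (s1[~close] == s2[~close]).all()

    def test_chi2_matches_scipy_oracle(self):
        rng = np.random.default_rng(17)
        cells = random_tables(rng, 2000)
        m = _metrics_arrays(*cells.T)
        oracle = np.array(
            [
                chi2_contingency([[a, b], [c, d]], correction=False).statistic
                for a, b, c, d in cells
            ]
        )
        np.testing.assert_allclose(m["chi2"], oracle, atol=1e-9, rtol=1e-9)

    def test_monotonicity_in_a(self):
        b, c, d = 500, 80, 20_000
        a = np.arange(1, 200)
        m = _metrics_arrays(a, b, c, d)
        for key in ("ror", "prr", "ic", "ebgm"):
            assert (np.diff(m[key]) > 0).all(), key

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(23)
        cells = random_tables(rng, 5000)
        m = _metrics_arrays(*cells.T)
        assert (m["ror_low"] <= m["ror"] + 1e-12).all()
        assert (m["ror"] <= m["ror_high"] + 1e-12).all()
        assert (m["ebgm05"] <= m["ebgm"] + 1e-12).all()


class TestBatch:
    def test_batch_equals_scalar(self, minimal_extract):
        """Batch evaluation over all PTs equals per-table scalar evaluation."""
        events, _, _ = f.analyze_extract(minimal_extract)
        batch = signal_table(events, level="PT")
        for _, row in batch.iterrows():
            t = f.build_contingency(events, row.pt, "PT")
            assert (t.a, t.b, t.c, t.d) == (row.a, row.b, row.c, row.d)
            m = f.compute_metrics(t)
            assert m.ror == pytest.approx(row.ror, nan_ok=True)
            assert m.chi2 == pytest.approx(row.chi2, nan_ok=True)
            assert m.ic == pytest.approx(row.ic, nan_ok=True)
            assert m.ebgm05 == pytest.approx(row.ebgm05, nan_ok=True)
            assert m.all_four == row.all_four

    def test_soc_level_counts_records(self, minimal_extract):
        events, _, _ = f.analyze_extract(minimal_extract)
        soc = signal_table(events, level="SOC")
        assert soc.a.sum() + soc.c.sum() == len(events)
        t = f.build_contingency(events, soc.soc.iloc[0], "SOC")
        assert t.a == soc.a.iloc[0]


def test_all_target_degenerate_margin_flagged_not_crashing(vocab):
    """c = d = 0 (every record from the target drug) leaves the statistics
    undefined, never raises."""
    from faerspv.records import ReacRecord

    reac = [ReacRecord(1, 1, "Nausea"), ReacRecord(2, 2, "Fall")]
    events = f.build_event_table(reac, {1, 2}, {1, 2}, vocab)
    table = signal_table(events, level="PT")
    assert np.isnan(table.ror).all()
    assert not table.all_four.any()
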