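"""The four disproportionality estimators and the combined signal rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvsignal as pv
from pvsignal.contingency import pearson_chi2

T_BASE = pv.ContingencyTable(a=10, b=90, c=100, d=9900)
T_PROP = pv.ContingencyTable(a=10, b=90, c=20, d=180)  # a/b == c/d

cells = st.integers(1, 2000)
tables = st.builds(pv.ContingencyTable, a=cells, b=cells, c=cells, d=cells)


class TestROR:
    def test_closed_form_point(self):
        est = pv.ror_estimate(T_BASE)
        assert est.point == pytest.approx(11.0)
        assert est.lower < 11.0 < est.upper

    def test_proportional_table_is_null(self):
        assert pv.ror_estimate(T_PROP).point == pytest.approx(1.0)

    def test_zero_cell_is_undefined(self):
        est = pv.ror_estimate(pv.ContingencyTable(a=0, b=10, c=10, d=10))
        assert not est.defined


class TestPRR:
    def test_closed_form_point_and_chi2(self):
        est, chi2 = pv.prr_estimate(T_BASE)
        assert est.point == pytest.approx(10.0)
        # expected cells 1.0891 / 98.9109 / 108.911 / 9891.09 give chi2 ~ 74.4
        assert chi2 == pytest.approx(74.4, abs=0.05)

    def test_proportional_table_has_zero_chi2(self):
        est, chi2 = pv.prr_estimate(T_PROP)
        assert est.point == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_c_is_undefined(self):
        est, _ = pv.prr_estimate(pv.ContingencyTable(a=5, b=5, c=0, d=10))
        assert not est.defined


class TestICAndEBGM:
    def test_ebgm_closed_form(self):
        assert pv.ebgm_estimate(T_BASE).point == pytest.approx(10 * 10100 / (110 * 100))

    def test_ic_is_log2_of_observed_over_expected(self):
        assert pv.ic_estimate(T_BASE).point == pytest.approx(math.log2(9.1818), abs=1e-3)

    def test_proportional_table_gives_ic_zero_ebgm_one(self):
        assert pv.ic_estimate(T_PROP).point == pytest.approx(0.0, abs=1e-12)
        assert pv.ebgm_estimate(T_PROP).point == pytest.approx(1.0)

    def test_a_zero_undefined(self):
        t = pv.ContingencyTable(a=0, b=10, c=10, d=10)
        assert not pv.ic_estimate(t).defined
        assert not pv.ebgm_estimate(t).defined

    def test_bayes_interval_shrinks_small_counts(self):
        # with a tiny a-cell the posterior bound sits far below the
        # delta-method bound (the tabulated behaviour for rare terms)
        t = pv.ContingencyTable(a=3, b=500, c=30, d=2_000_000)
        se = pv.ic_estimate(t, method="se")
        bayes = pv.ic_estimate(t, method="bcpnn-bayes")
        assert bayes.lower < se.lower
        assert bayes.lower < 2.0  # strong shrinkage despite a huge point IC
        assert se.point > 6

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            pv.ic_estimate(T_BASE, method="magic")

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(tables)
    def test_ic_equals_log2_ebgm_identically(self, t):
        assert pv.ic_estimate(t).point == pytest.approx(
            math.log2(pv.ebgm_estimate(t).point), abs=1e-12)


class TestEvaluateSignal:
    def test_strong_table_passes_all_criteria(self):
        r = pv.evaluate_signal(pv.ContingencyTable(a=20, b=80, c=200, d=19700))
        assert r.ror.point == pytest.approx(24.625)
        assert r.prr.point == pytest.approx(19.9)
        assert r.ebgm.point == pytest.approx(20 * 20000 / (220 * 100))
        assert r.count_pass and r.ror_pass and r.prr_pass and r.ic_pass and r.ebgm_pass
        assert r.significant

    def test_below_minimum_count_never_significant(self):
        r = pv.evaluate_signal(pv.ContingencyTable(a=2, b=8, c=2, d=19988))
        assert not r.count_pass
        assert not r.significant

    def test_null_table_fails_ratio_criteria(self):
        r = pv.evaluate_signal(pv.ContingencyTable(a=5, b=95, c=50, d=950))
        assert r.count_pass
        assert not (r.ror_pass or r.prr_pass or r.ic_pass or r.ebgm_pass)
        assert not r.significant

    def test_thresholds_are_configurable(self):
        t = pv.ContingencyTable(a=5, b=95, c=50, d=9950)
        assert pv.evaluate_signal(t, pv.Thresholds(min_a=3)).count_pass
        assert not pv.evaluate_signal(t, pv.Thresholds(min_a=10)).count_pass


class TestProperties:
    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(tables)
    def test_sign_coherence_across_estimators(self, t):
        ror = pv.ror_estimate(t).point
        prr, _ = pv.prr_estimate(t)
        ic = pv.ic_estimate(t).point
        ebgm = pv.ebgm_estimate(t).point
        signs = {math.copysign(1, x) for x in
                 (math.log(ror), math.log(prr.point), ic, math.log(ebgm))
                 if abs(x) > 1e-12}
        assert len(signs) <= 1

    def test_monotonicity_in_a(self):
        pts = []
        for a in (5, 10, 20, 40):
            t = pv.ContingencyTable(a=a, b=100, c=50, d=5000)
            prr, _ = pv.prr_estimate(t)
            pts.append((pv.ror_estimate(t).point, prr.point,
                        pv.ic_estimate(t).point, pv.ebgm_estimate(t).point))
        for col in range(4):
            vals = [p[col] for p in pts]
            assert vals == sorted(vals)
            assert len(set(vals)) == len(vals)

    def test_null_calibration_median_near_one(self):
        """Under independence each estimator's median across replicates ~ 1."""
        rng = np.random.default_rng(123)
        n_t, n_o, p = 400, 8000, 0.05
        points = []
        for _ in range(300):
            a = rng.binomial(n_t, p)
            c = rng.binomial(n_o, p)
            if a == 0 or c == 0 or a == n_t or c == n_o:
                continue
            t = pv.ContingencyTable(a=a, b=n_t - a, c=c, d=n_o - c)
            points.append((pv.ror_estimate(t).point, pv.ebgm_estimate(t).point,
                           pv.ic_estimate(t).point))
        med = np.median(np.array(points), axis=0)
        assert med[0] == pytest.approx(1.0, abs=0.15)
        assert med[1] == pytest.approx(1.0, abs=0.15)
        assert med[2] == pytest.approx(0.0, abs=0.2)


def test_oracle_equivalence_on_random_tables():
    """ROR point/CI and chi2 agree with statsmodels/scipy on 1,000 tables."""
    from scipy.stats import chi2_contingency
    from statsmodels.stats.contingency_tables import Table2x2

    rng = np.random.default_rng(7)
    for _ in range(1000):
        a, b, c, d = (int(x) for x in rng.integers(1, 300, size=4))
        t = pv.ContingencyTable(a=a, b=b, c=c, d=d)
        sm = Table2x2(np.array([[a, b], [c, d]]))
        est = pv.ror_estimate(t)
        assert est.point == pytest.approx(sm.oddsratio, rel=1e-12)
        lo, hi = sm.oddsratio_confint(0.05)
        assert est.lower == pytest.approx(lo, rel=1e-9)
        assert est.upper == pytest.approx(hi, rel=1e-9)
        assert pearson_chi2(t) == pytest.approx(
            chi2_contingency([[a, b], [c, d]], correction=False)[0], rel=1e-12)


def test_external_aggregate_counts_route():
    """Margins-only inputs (a, a+b, a+c, N) reconstruct the same estimates."""
    t = pv.ContingencyTable(a=10, b=90, c=100, d=9900)
    t2 = pv.ContingencyTable.from_margins(a=10, target_total=100, term_total=110, n=10100)
    assert pv.ror_estimate(t) == pv.ror_estimate(t2)
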