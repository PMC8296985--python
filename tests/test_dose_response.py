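"""4PL fitting, closed-form AUC and DSS scoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from covscreen.dose_response import (
    DSSResult,
    LogisticFit,
    auc_closed_form,
    dss,
    fit_logistic4,
    logistic4,
    selectivity_ratio,
)

CMIN, CMAX = np.log10(0.6e-6), np.log10(40e-6)  # typical screening window


def quad_auc(fit, lo, hi):
    """Adaptive-quadrature oracle for the logistic integral."""
    val, _ = quad(lambda x: logistic4(x, fit.bottom, fit.top, fit.hill, fit.log10_mid),
                  lo, hi, limit=200)
    return val


class TestFitLogistic4:
    def test_noiseless_self_consistency(self):
        conc = np.geomspace(1e-7, 1e-3, 12)
        y = logistic4(np.log10(conc), 0.0, 100.0, 1.0, -5.0)
        fit = fit_logistic4(conc, y)
        assert abs(fit.bottom - 0.0) < 1e-6
        assert abs(fit.top - 100.0) < 1e-6
        assert abs(fit.hill - 1.0) < 1e-6
        assert abs(fit.log10_mid - (-5.0)) < 1e-6

    def test_log_midpoint_maps_to_micromolar_ic50(self):
        # a midpoint of -4.92 log10 molar is a 12 uM IC50 at table precision
        fit = LogisticFit(0.0, 100.0, 1.0, -4.92)
        assert np.isclose(fit.ic50, 12e-6, rtol=5e-3)

    def test_agrees_with_coarse_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        conc = np.geomspace(1e-7, 1e-3, 16)
        x = np.log10(conc)
        y = logistic4(x, 0.0, 100.0, 1.0, -5.0) + rng.normal(0, 2.0, x.size)

        bottoms = np.linspace(-10, 30, 5)
        tops = np.linspace(60, 120, 5)
        hills = np.linspace(0.5, 2.5, 5)
        mids = np.linspace(-6, -4, 5)
        best, best_rss = None, np.inf
        for b in bottoms:
            for t in tops:
                for h in hills:
                    for m in mids:
                        rss = np.sum((logistic4(x, b, t, h, m) - y) ** 2)
                        if rss < best_rss:
                            best, best_rss = (b, t, h, m), rss
        fit = fit_logistic4(conc, y)
        assert fit.rss <= best_rss + 1e-9
        steps = (10.0, 15.0, 0.5, 0.5)
        for got, grid, step in zip((fit.bottom, fit.top, fit.hill, fit.log10_mid), best, steps):
            assert abs(got - grid) <= step

    def test_underdetermined_input_is_inconclusive_not_fatal(self):
        fit = fit_logistic4([1e-6, 1e-5, 1e-4], [10.0, 50.0, 90.0])
        assert fit.inconclusive and not fit.converged

    def test_descending_curve_gets_negative_hill(self):
        conc = np.geomspace(1e-7, 1e-3, 12)
        y = logistic4(np.log10(conc), 0.05, 0.25, -1.2, -5.3)
        fit = fit_logistic4(conc, y, bounds="auto")
        assert fit.hill < 0
        assert fit.top >= fit.bottom
        assert abs(fit.log10_mid - (-5.3)) < 1e-6


class TestAucClosedForm:
    def test_zero_curve(self):
        assert auc_closed_form(LogisticFit(0, 0, 1, -5), -6, -4) == 0.0

    def test_constant_100_over_two_decades(self):
        assert abs(auc_closed_form(LogisticFit(100, 100, 1, -5), -6, -4) - 200.0) < 1e-12

    @given(
        bottom=st.floats(-10, 50),
        top=st.floats(0, 120),
        hill=st.floats(0.2, 10),
        mid=st.floats(-8, -3),
        lo=st.floats(-7, -5.5),
        hi=st.floats(-5.4, -3),
    )
    def test_matches_adaptive_quadrature(self, bottom, top, hill, mid, lo, hi):
        fit = LogisticFit(bottom, top, hill, mid)
        exact = auc_closed_form(fit, lo, hi)
        approx = quad_auc(fit, lo, hi)
        assert abs(exact - approx) <= 1e-6 * max(1.0, abs(approx))

    def test_stable_for_steep_slopes(self):
        fit = LogisticFit(0, 100, 10, -5)
        val = auc_closed_form(fit, -12, -2)
        assert np.isfinite(val)
        assert abs(val - quad_auc(fit, -12, -2)) < 1e-6 * val


class TestDss:
    def test_full_inhibition_analytic_scores(self):
        fit = LogisticFit(100.0, 100.0, 1.0, -5.0)  # response == 100 everywhere
        res = dss(fit, CMIN, CMAX, t=10.0)
        assert abs(res.dss1 - 100.0) < 1e-9
        assert abs(res.dss2 - 50.0) < 1e-9
        assert abs(res.dss3 - 50.0) < 1e-9

    def test_zero_response_scores_zero(self):
        res = dss(LogisticFit(0.0, 0.0, 1.0, -5.0), CMIN, CMAX)
        assert res.dss1 == res.dss2 == res.dss3 == 0.0

    def test_matches_numerical_integration_oracle(self):
        fit = LogisticFit(0.0, 80.0, 1.0, (CMIN + CMAX) / 2.0)
        res = dss(fit, CMIN, CMAX, t=10.0)
        # oracle: numerical threshold crossing + quadrature + printed formulas
        from scipy.optimize import brentq
        x1 = brentq(lambda x: fit(x) - 10.0, CMIN, CMAX, xtol=1e-14)
        auc = quad_auc(fit, x1, CMAX)
        d1 = (auc - 10.0 * (CMAX - x1)) / (90.0 * (CMAX - CMIN))
        d2 = d1 / np.log10(80.0)
        d3 = d2 * (CMAX - x1) / (CMAX - CMIN)
        assert abs(res.dss3 - 100.0 * d3) < 1e-6

    def test_curve_below_threshold_scores_zero(self):
        fit = LogisticFit(0.0, 8.0, 1.0, (CMIN + CMAX) / 2.0)
        res = dss(fit, CMIN, CMAX, t=10.0)
        assert res.dss1 == 0.0

    def test_monotone_in_top_asymptote(self):
        mid = (CMIN + CMAX) / 2.0
        scores = [dss(LogisticFit(0.0, top, 1.0, mid), CMIN, CMAX).dss1
                  for top in (40.0, 60.0, 80.0, 100.0, 120.0)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_narrow_window_penalized_by_dss3(self):
        # curve only crossing threshold near the top dose: DSS3 << DSS1
        fit = LogisticFit(0.0, 100.0, 4.0, CMAX - 0.1)
        res = dss(fit, CMIN, CMAX)
        assert 0 < res.dss3 < 0.5 * res.dss1

    def test_scale_equivariance_under_log_shift(self):
        fit = LogisticFit(5.0, 90.0, 1.5, -5.2)
        shift = 1.7
        shifted = LogisticFit(5.0, 90.0, 1.5, -5.2 + shift)
        a = dss(fit, CMIN, CMAX)
        b = dss(shifted, CMIN + shift, CMAX + shift)
        for attr in ("dss1", "dss2", "dss3"):
            assert abs(getattr(a, attr) - getattr(b, attr)) < 1e-9

    def test_ordering_invariant(self):
        # 0 <= dss3 <= dss2 <= dss1 <= 100 for a <= 100 within the window
        for mid in np.linspace(CMIN, CMAX, 7):
            res = dss(LogisticFit(0.0, 95.0, 1.3, mid), CMIN, CMAX)
            assert 0.0 <= res.dss3 <= res.dss2 + 1e-12
            assert res.dss2 <= res.dss1 + 1e-12
            assert res.dss1 <= 100.0 + 1e-12

    def test_inconclusive_fit_scores_zero_with_warning(self):
        bad = LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                          inconclusive=True, reason="no fit")
        res = dss(bad, CMIN, CMAX)
        assert res.dss3 == 0.0 and "inconclusive" in res.warning


class TestSelectivityRatio:
    def _res(self, dss3):
        return DSSResult(dss3, dss3, dss3, 0, 10, 100, CMIN, CMAX, CMIN, CMAX)

    def test_equal_scores_give_unity(self):
        assert selectivity_ratio(self._res(25.0), self._res(25.0)) == 1.0

    def test_direct_ratio(self):
        assert selectivity_ratio(self._res(30.0), self._res(10.0)) == 3.0

    def test_zero_denominator_flags_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(selectivity_ratio(self._res(30.0), self._res(0.0)))

    def test_end_to_end_ratio_matches_oracle(self):
        fit_a = LogisticFit(0.0, 100.0, 1.0, (CMIN + CMAX) / 2)
        fit_b = LogisticFit(0.0, 70.0, 1.0, CMAX - 0.3)
        ratio = selectivity_ratio(dss(fit_a, CMIN, CMAX), dss(fit_b, CMIN, CMAX))
        oracle = dss(fit_a, CMIN, CMAX).dss3 / dss(fit_b, CMIN, CMAX).dss3
        assert np.isclose(ratio, oracle, rtol=1e-12)
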