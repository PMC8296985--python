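"""BRET ratios, donor-saturation fits, A/D-ratio selection and inhibition."""

import numpy as np
import pandas as pd
import pytest

from covscreen.bret import (
    BretWell,
    bret_inhibition,
    bret_ratio,
    fit_saturation,
    relative_expression,
    select_assay_ad_ratio,
    titration_points,
)
from covscreen.dose_response import dss, fit_logistic4
from covscreen.synthetic import SimulationConfig, gen_bret_titration, kras_ad_titration


class TestBretRatio:
    DONOR_ONLY = BretWell(em515=100.0, em410=1000.0, condition="donor_only")

    def test_background_identity(self):
        sample = BretWell(em515=100.0, em410=1000.0)
        assert bret_ratio(sample, self.DONOR_ONLY) == 0.0

    def test_direct_evaluation(self):
        sample = BretWell(em515=300.0, em410=1000.0)
        assert abs(bret_ratio(sample, self.DONOR_ONLY) - 0.20) < 1e-12

    def test_invariant_under_channel_scaling(self):
        sample = BretWell(em515=300.0, em410=1000.0)
        scaled = BretWell(em515=3000.0, em410=10000.0)
        assert np.isclose(bret_ratio(sample, self.DONOR_ONLY),
                          bret_ratio(scaled, self.DONOR_ONLY), rtol=1e-12)

    def test_decreasing_in_donor_only_background(self):
        sample = BretWell(em515=300.0, em410=1000.0)
        backgrounds = [BretWell(em515=b, em410=1000.0) for b in (50.0, 100.0, 200.0)]
        ratios = [bret_ratio(sample, bg) for bg in backgrounds]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            bret_ratio(BretWell(em515=1.0, em410=0.0), self.DONOR_ONLY)


class TestRelativeExpression:
    @pytest.mark.parametrize("rfu, rlu, expected", [(2000.0, 2000.0, 1.0),
                                                    (0.0, 2000.0, 0.0),
                                                    (5000.0, 2000.0, 2.5)])
    def test_direct(self, rfu, rlu, expected):
        assert relative_expression(rfu, rlu) == expected

    def test_zero_rlu_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_expression(100.0, 0.0)


class TestFitSaturation:
    def test_noiseless_recovery(self):
        x = np.geomspace(0.05, 4.0, 12)
        y = 0.35 * x / (1.0 + x)
        fit = fit_saturation(x, y)
        assert abs(fit.bret_max - 0.35) < 1e-6
        assert abs(fit.bret_50 - 1.0) < 1e-6

    def test_midpoint_property(self):
        x = np.geomspace(0.05, 4.0, 12)
        fit = fit_saturation(x, 0.35 * x / (1.0 + x))
        y_at_b50 = fit.bret_max * fit.bret_50 / (fit.bret_50 + fit.bret_50)
        assert np.isclose(y_at_b50, fit.bret_max / 2.0, rtol=1e-12)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(17)
        x = np.geomspace(0.05, 4.0, 12)
        y = 0.35 * x / (1.0 + x) * (1.0 + 0.02 * rng.standard_normal(12))
        bmaxs = np.linspace(0.2, 0.5, 151)
        b50s = np.linspace(0.4, 2.0, 161)
        B, H = np.meshgrid(bmaxs, b50s, indexing="ij")
        rss = ((B[..., None] * x / (H[..., None] + x) - y) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        fit = fit_saturation(x, y)
        assert abs(fit.bret_max - bmaxs[i]) <= bmaxs[1] - bmaxs[0]
        assert abs(fit.bret_50 - b50s[j]) <= b50s[1] - b50s[0]

    def test_no_curvature_flags_unresolved(self):
        x = np.linspace(0.01, 0.1, 8)  # far below any saturation
        y = 0.05 * x  # linear
        fit = fit_saturation(x, y)
        assert not fit.resolved
        assert np.isclose(fit.slope, 0.05, rtol=1e-6)

    def test_recovery_from_generated_titration(self):
        cfg = SimulationConfig(seed=21, cv=0.02, additive_frac=0.0, replicates=1)
        wells = gen_bret_titration(0.35, 1.0, cfg)
        pts = titration_points(wells)
        fit = fit_saturation(pts["rel_expression"], pts["ratio"])
        assert abs(fit.bret_max - 0.35) / 0.35 < 0.05
        assert abs(fit.bret_50 - 1.0) < 0.10


class TestSelectAssayAdRatio:
    def _fit(self, b50=1.0, bmax=0.35):
        x = np.geomspace(0.05, 4.0, 12) * b50
        return fit_saturation(x, bmax * x / (b50 + x))

    def test_picks_half_bret50_expression(self):
        fit = self._fit(b50=1.0)
        df = pd.DataFrame({
            "ad_ratio": [1, 1, 2, 2, 4, 4],
            "rel_expression": [0.1, 0.1, 0.5, 0.5, 1.0, 1.0],
        })
        assert select_assay_ad_ratio(df, fit) == 2

    def test_tie_breaks_to_lower_ratio(self):
        fit = self._fit(b50=1.0)
        df = pd.DataFrame({
            "ad_ratio": [1, 2, 4],
            "rel_expression": [0.4, 0.6, 2.0],  # 0.4 and 0.6 equidistant from 0.5
        })
        assert select_assay_ad_ratio(df, fit) == 1

    def test_saturated_titration_warns_and_returns_lowest(self):
        fit = self._fit(b50=0.1)
        df = pd.DataFrame({
            "ad_ratio": [2, 4, 8],
            "rel_expression": [0.5, 1.0, 2.0],  # all > 3 * BRET50
        })
        with pytest.warns(UserWarning, match="saturation"):
            assert select_assay_ad_ratio(df, fit) == 2

    def test_kras_fixture_selects_4_to_1(self):
        df = kras_ad_titration()
        fit = fit_saturation(df["rel_expression"], df["ratio"])
        assert select_assay_ad_ratio(df, fit) == 4


class TestBretInhibition:
    def test_anchors_and_midpoint(self):
        treated = {"vehicle-like": 0.30, "half": 0.15, "max": 0.06}
        df, a = bret_inhibition(treated, vehicle_ratio=0.30, asymptote_ratio=0.06)
        vals = df.set_index("treatment")["value"]
        assert vals["vehicle-like"] == 0.0
        assert vals["half"] == 50.0
        assert np.isclose(vals["max"], a)
        assert np.isclose(a, 80.0)

    def test_nonpositive_vehicle_rejected(self):
        with pytest.raises(ValueError):
            bret_inhibition({"x": 0.1}, vehicle_ratio=0.0)

    def test_bret_dss_equals_dose_response_dss_on_same_values(self):
        # composition identity: converting ratios to % inhibition and scoring
        # must equal scoring the same % inhibition values directly
        conc = np.geomspace(0.1e-6, 80e-6, 10)
        from covscreen.dose_response import logistic4
        inhibition = logistic4(np.log10(conc), 0.0, 85.0, 1.2, -5.5)
        vehicle = 0.30
        ratios = {f"c{i}": vehicle * (1.0 - v / 100.0) for i, v in enumerate(inhibition)}
        df, _ = bret_inhibition(ratios, vehicle_ratio=vehicle)
        assert np.allclose(df["value"], inhibition)

        cmin, cmax = np.log10(conc[0]), np.log10(conc[-1])
        fit_a = fit_logistic4(conc, df["value"].to_numpy())
        fit_b = fit_logistic4(conc, inhibition)
        res_a = dss(fit_a, cmin, cmax)
        res_b = dss(fit_b, cmin, cmax)
        assert np.isclose(res_a.dss3, res_b.dss3, rtol=1e-9)
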