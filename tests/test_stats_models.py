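import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dupmodes.stats_models import (
    WGD_CODES_ARABIDOPSIS,
    WGD_CODES_RICE,
    anova_tukey,
    correlation_power,
    correlation_test,
    encode_wgd_events,
    regress_d,
    spline_trend,
)


class TestCorrelationTest:
    def test_hand_case_r_08_with_two_df(self):
        r, p = correlation_test([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * math.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-9)

    def test_perfectly_linear(self):
        r, p = correlation_test([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_type_one_error_calibrated(self, rng):
        reps, n, rejections = 1500, 50, 0
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        for i in range(reps):
            _, p = correlation_test(x[i], y[i])
            rejections += p < 0.05
        rate = rejections / reps
        assert rate == pytest.approx(0.05, abs=3 * math.sqrt(0.05 * 0.95 / reps))


class TestCorrelationPower:
    def test_null_power_equals_alpha(self):
        assert correlation_power(0.0, 100, alpha=0.05) == pytest.approx(0.05, abs=1e-10)

    def test_large_sample_weak_correlation_exceeds_098(self):
        assert correlation_power(0.126, 2858, alpha=0.05) > 0.98

    def test_matches_monte_carlo_at_moderate_n(self, rng):
        n, reps, r = 30, 20_000, 0.5
        x = rng.standard_normal((reps, n))
        y = r * x + math.sqrt(1 - r * r) * rng.standard_normal((reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        rs = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        tcrit = stats.t.ppf(0.975, n - 2)
        rcrit = tcrit / math.sqrt(tcrit**2 + n - 2)
        mc = float((np.abs(rs) > rcrit).mean())
        assert correlation_power(r, n) == pytest.approx(mc, abs=0.01)


class TestWgdCodes:
    def test_paper_mappings(self):
        assert list(encode_wgd_events(["alpha", "beta", "gamma"], WGD_CODES_ARABIDOPSIS)) == [1, 2, 3]
        assert list(encode_wgd_events(["rho", "sigma"], WGD_CODES_RICE)) == [1, 2]

    def test_unknown_event_raises(self):
        with pytest.raises(KeyError):
            encode_wgd_events(["delta"], WGD_CODES_RICE)


class TestRegression:
    def test_noiseless_data_recovered_exactly(self):
        ks = np.linspace(0, 3, 50)
        df = pd.DataFrame({"d": 0.5 + 0.1 * ks, "ks": ks})
        res = regress_d(df, model="ks")
        assert res.params["a"] == pytest.approx(0.5, abs=1e-10)
        assert res.params["b1"] == pytest.approx(0.1, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_model_reproduces_mean(self, rng):
        d = rng.standard_normal(40) + 2.0
        res = regress_d(pd.DataFrame({"d": d}), model="null")
        assert res.params["a"] == pytest.approx(d.mean(), abs=1e-10)

    def test_aic_invariant_to_constant_shift(self, rng):
        ks = rng.uniform(0, 3, 200)
        w = rng.integers(1, 4, 200).astype(float)
        d = 0.5 + 0.05 * ks + 0.05 * w + 0.2 * rng.standard_normal(200)
        df = pd.DataFrame({"d": d, "ks": ks, "w": w})
        df_shift = df.assign(d=df["d"] + 5.0)
        for model in ("ks", "w", "ks+w"):
            assert regress_d(df, model).aic == pytest.approx(
                regress_d(df_shift, model).aic, abs=1e-8
            )

    def test_adjusted_r2_matches_formula(self, rng):
        n = 80
        ks = rng.uniform(0, 3, n)
        d = 0.5 + 0.1 * ks + 0.3 * rng.standard_normal(n)
        res = regress_d(pd.DataFrame({"d": d, "ks": ks}), model="ks")
        expected = 1 - (1 - res.r2) * (n - 1) / (n - 1 - 1)
        assert res.adj_r2 == pytest.approx(expected, abs=1e-10)

    def test_collinear_design_rejected(self):
        ks = np.ones(20)
        df = pd.DataFrame({"d": np.random.default_rng(0).standard_normal(20), "ks": ks})
        with pytest.raises(ValueError, match="collinear"):
            regress_d(df, model="ks")

    def test_permuted_response_pvalues_are_uniform(self, rng):
        # calibration: under the null, b1 p-values are U(0, 1)
        n, reps = 300, 400
        ks = rng.uniform(0, 3, n)
        ps = []
        for _ in range(reps):
            d = rng.standard_normal(n)
            ps.append(regress_d(pd.DataFrame({"d": d, "ks": ks}), model="ks").pvalues["b1"])
        ks_stat = stats.kstest(ps, "uniform").pvalue
        assert ks_stat > 0.001


class TestAnovaTukey:
    def test_identical_groups(self):
        g = list(np.linspace(0, 1, 10))
        res = anova_tukey({"a": g, "b": g, "c": g})
        assert res.f == pytest.approx(0.0, abs=1e-10)
        assert not res.tukey["significant"].any()

    def test_two_groups_reduce_to_t_test(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 0.4
        res = anova_tukey({"a": a, "b": b})
        t, p = stats.ttest_ind(a, b)
        assert res.f == pytest.approx(t**2, abs=1e-8)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_separated_groups_all_contrasts_significant(self, rng):
        groups = {
            "a": rng.normal(0, 1, 100),
            "b": rng.normal(1, 1, 100),
            "c": rng.normal(2, 1, 100),
        }
        res = anova_tukey(groups)
        assert res.p < 1e-10
        assert res.tukey["significant"].all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0]})


class TestSplineTrend:
    def test_reproduces_straight_line(self):
        x = np.linspace(0, 6, 100)
        y = 2 * x + 1
        fit = spline_trend(x, y, df=10)
        assert np.abs(fit(x) - y).max() < 1e-6

    def test_df_two_equals_ols_line(self, rng):
        x = np.linspace(0, 6, 120)
        y = 0.5 + 0.3 * x + 0.05 * rng.standard_normal(120)
        fit = spline_trend(x, y, df=2, tol=0.05)
        slope, intercept = np.polyfit(x, y, 1)
        assert np.abs(fit(x) - (slope * x + intercept)).max() < 1e-3

    def test_effective_df_within_tolerance(self, rng):
        x = np.sort(rng.uniform(0, 6, 200))
        y = np.sin(x) + 0.2 * rng.standard_normal(200)
        fit = spline_trend(x, y, df=10, tol=0.1)
        assert abs(fit.effective_df - 10) <= 0.1

    def test_beats_straight_line_on_sine(self, rng):
        x = np.sort(rng.uniform(0, 6, 500))
        y = np.sin(x) + 0.1 * rng.standard_normal(500)
        fit = spline_trend(x, y, df=10)
        slope, intercept = np.polyfit(x, y, 1)
        mse_spline = float(np.mean((fit(x) - y) ** 2))
        mse_line = float(np.mean((slope * x + intercept - y) ** 2))
        assert mse_spline < mse_line

    def test_too_few_distinct_x_raises(self):
        x = np.repeat(np.arange(8.0), 3)
        y = np.tile(np.arange(8.0), 3)
        with pytest.raises(ValueError, match="smaller df"):
            spline_trend(x, y, df=10)

    def test_matches_scipy_smoothing_spline_at_same_lambda(self, rng):
        from scipy.interpolate import make_smoothing_spline

        x = np.sort(rng.uniform(0, 6, 80))
        y = np.sin(x) + 0.2 * rng.standard_normal(80)
        fit = spline_trend(x, y, df=8)
        spl = make_smoothing_spline(fit.x, y, lam=fit.lam)
        assert np.abs(spl(fit.x) - fit.fitted).max() < 1e-8

    def test_duplicate_x_are_weight_averaged(self, rng):
        x = np.concatenate([np.linspace(0, 5, 50), np.linspace(0, 5, 50)])
        y = 2 * x + rng.standard_normal(100) * 0.01
        fit = spline_trend(x, y, df=5)
        assert np.abs(fit(np.linspace(0, 5, 20)) - (2 * np.linspace(0, 5, 20))).max() < 0.05
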