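import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from attnbattery.psychometrics import (
    ModelComparison,
    PairedSample,
    RegressionSpec,
    compare_nested,
    fit_ols,
    logit_percent,
    one_way_anova,
    paired_t,
    pearson_r,
    pillai_group_test,
    test_retest as retest_report,
)

from conftest import ols_oracle


class TestPearson:
    def test_perfect_positive(self):
        r, _ = pearson_r([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = pearson_r([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_hand_computed(self):
        r, _ = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t(PairedSample((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)))
        assert t == 0.0 and df == 2 and p == 1.0

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(ValueError):
            paired_t(PairedSample((2.0, 3.0, 4.0, 5.0), (1.0, 2.0, 3.0, 4.0)))

    def test_hand_computed(self):
        # differences {2, 0, 4, 2}: mean 2, sd 1.633, t = 2 / (1.633/2)
        t, df, _ = paired_t(PairedSample((3.0, 1.0, 5.0, 4.0), (1.0, 1.0, 1.0, 2.0)))
        assert df == 3
        assert t == pytest.approx(2.449, abs=1e-3)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            PairedSample((1.0, 2.0), (1.0, 3.0))


class TestAnova:
    def test_identical_groups(self):
        f, df1, df2, p = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == 0.0 and (df1, df2) == (2, 6) and p == 1.0

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f, df1, df2, p_f = one_way_anova([a, b])
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.3, 0.6, 0.1)]
        f, _, _, p = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_calibration_small(self):
        # 200-rep KS sanity check; the 500-rep version runs in acceptance
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(200):
            groups = [rng.normal(0, 1, 5) for _ in range(8)]
            pvals.append(one_way_anova(groups)[3])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2, 3]])


class TestLogit:
    def test_half_maps_to_zero(self):
        assert logit_percent(0.5) == pytest.approx(0.0)
        assert logit_percent(0.5, n_units=150) == pytest.approx(0.0)

    def test_closed_form_point_eight(self):
        assert logit_percent(0.8) == pytest.approx(math.log(4.0))

    def test_boundary_finite_with_eps(self):
        eps = 1.0 / 300.0
        assert logit_percent(1.0, n_units=150) == pytest.approx(
            math.log((1 + eps) / eps)
        )
        assert math.isfinite(logit_percent(0.0, n_units=150))

    def test_boundary_without_eps_rejected(self):
        with pytest.raises(ValueError):
            logit_percent(1.0)

    def test_strictly_increasing_and_odd(self):
        ps = np.linspace(0.05, 0.95, 19)
        vals = [logit_percent(p) for p in ps]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        for p in ps:
            assert logit_percent(p) == pytest.approx(-logit_percent(1 - p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logit_percent(1.2)


def _random_frame(rng, n=30):
    return pd.DataFrame(
        {
            "y": rng.normal(0, 1, n),
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(0, 1, n),
            "x3": rng.normal(0, 1, n),
        }
    )


SPEC = RegressionSpec(outcome="y", block1=("x1", "x2"), block2_additions=("x3",))


class TestFitOLS:
    def test_exact_fit(self):
        data = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [1.0, 2.0, 3.0, 4.0]})
        spec = RegressionSpec(outcome="y", block1=(), block2_additions=("x",))
        fit = fit_ols(spec, data, block=2)
        est = fit.estimates[0]
        assert est.beta == pytest.approx(1.0)
        assert fit.adj_r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            data = _random_frame(rng, n)
            data["y"] = data["x1"] * 0.5 - data["x2"] * 0.2 + rng.normal(0, 1, n)
            fit = fit_ols(SPEC, data, block=2)
            coef, se, rss = ols_oracle(
                data["y"], data[["x1", "x2", "x3"]].to_numpy()
            )
            assert fit.intercept == pytest.approx(coef[0], abs=1e-8)
            for j, est in enumerate(fit.estimates):
                assert est.b == pytest.approx(coef[j + 1], abs=1e-8)
                assert est.se == pytest.approx(se[j + 1], abs=1e-8)
            assert fit.rss == pytest.approx(rss, abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        data = _random_frame(rng, 40)
        fit = fit_ols(SPEC, data, block=2)
        x = sm.add_constant(data[["x1", "x2", "x3"]])
        ref = sm.OLS(data["y"], x).fit()
        for est, name in zip(fit.estimates, ("x1", "x2", "x3")):
            assert est.b == pytest.approx(ref.params[name], abs=1e-10)
            assert est.t == pytest.approx(ref.tvalues[name], abs=1e-8)
            assert est.p == pytest.approx(ref.pvalues[name], abs=1e-10)
        assert fit.adj_r_squared == pytest.approx(ref.rsquared_adj, abs=1e-10)
        assert fit.f_model == pytest.approx(ref.fvalue, abs=1e-8)

    def test_standardized_beta_is_zscored_slope(self):
        rng = np.random.default_rng(5)
        data = _random_frame(rng, 35)
        fit = fit_ols(SPEC, data, block=1)
        z = (data - data.mean()) / data.std(ddof=1)
        zfit = fit_ols(SPEC, z, block=1)
        for est, zest in zip(fit.estimates, zfit.estimates):
            assert est.beta == pytest.approx(zest.b, abs=1e-10)

    def test_null_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(500):
            data = _random_frame(rng, 40)
            vals.append(fit_ols(SPEC, data, block=2).adj_r_squared)
        assert abs(np.mean(vals)) < 0.02

    def test_log_transform_applied(self):
        rng = np.random.default_rng(7)
        n = 30
        data = pd.DataFrame(
            {
                "y": rng.normal(0, 1, n),
                "exp_years": rng.uniform(1.0, 20.0, n),
            }
        )
        spec = RegressionSpec(
            outcome="y",
            block1=(),
            block2_additions=("exp_years",),
            transforms={"exp_years": "log"},
        )
        fit = fit_ols(spec, data, block=2)
        coef, _, _ = ols_oracle(data["y"], np.log(data["exp_years"].to_numpy()))
        assert fit.estimates[0].b == pytest.approx(coef[1], abs=1e-10)

    def test_logit_transform_applied(self):
        rng = np.random.default_rng(8)
        n = 30
        data = pd.DataFrame(
            {
                "y": rng.normal(0, 1, n),
                "acc": rng.integers(0, 151, n) / 150.0,
            }
        )
        spec = RegressionSpec(
            outcome="y",
            block1=(),
            block2_additions=("acc",),
            transforms={"acc": ("logit", 150)},
        )
        fit = fit_ols(spec, data, block=2)
        transformed = [logit_percent(p, 150) for p in data["acc"]]
        coef, _, _ = ols_oracle(data["y"], np.asarray(transformed))
        assert fit.estimates[0].b == pytest.approx(coef[1], abs=1e-10)

    def test_rank_deficiency_signaled(self):
        data = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0, 4.0, 5.0], "x1": [1.0] * 5, "x2": [2.0] * 5}
        )
        spec = RegressionSpec(outcome="y", block1=("x1",), block2_additions=("x2",))
        with pytest.raises(ValueError):
            fit_ols(spec, data, block=2)

    def test_too_few_cases_rejected(self):
        data = _random_frame(np.random.default_rng(9), 4)
        with pytest.raises(ValueError):
            fit_ols(SPEC, data, block=2)


class TestCompareNested:
    def _fits(self, rng, n=40, effect=0.0):
        data = _random_frame(rng, n)
        data["y"] = data["x1"] * 0.4 + effect * data["x3"] + rng.normal(0, 1, n)
        return fit_ols(SPEC, data, block=1), fit_ols(SPEC, data, block=2)

    def test_no_improvement_zero_f(self):
        fit1, _ = self._fits(np.random.default_rng(10))
        cmp_ = ModelComparison(0.0, 1, 30, 1.0, 0.0)
        fake2 = fit1  # same RSS via identical fit is rejected as non-nested,
        # so assert the formula directly instead
        assert cmp_.f_change == 0.0

    def test_algebraic_identity_with_r_squared_form(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            fit1, fit2 = self._fits(rng, effect=0.3)
            cmp_ = compare_nested(fit1, fit2)
            df_num, df_den = cmp_.df_num, cmp_.df_den
            expected = ((fit2.r_squared - fit1.r_squared) / df_num) / (
                (1.0 - fit2.r_squared) / df_den
            )
            assert cmp_.f_change == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels_anova(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        data = _random_frame(rng, 36)
        fit1 = fit_ols(SPEC, data, block=1)
        fit2 = fit_ols(SPEC, data, block=2)
        cmp_ = compare_nested(fit1, fit2)
        m1 = sm.OLS(data["y"], sm.add_constant(data[["x1", "x2"]])).fit()
        m2 = sm.OLS(data["y"], sm.add_constant(data[["x1", "x2", "x3"]])).fit()
        ref_f, ref_p, _ = m2.compare_f_test(m1)
        assert cmp_.f_change == pytest.approx(ref_f, abs=1e-8)
        assert cmp_.p_change == pytest.approx(ref_p, abs=1e-10)

    def test_null_calibration_small(self):
        rng = np.random.default_rng(13)
        pvals = [compare_nested(*self._fits(rng)).p_change for _ in range(200)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(14)
        fit1, fit2 = self._fits(rng)
        with pytest.raises(ValueError):
            compare_nested(fit2, fit1)


class TestPillai:
    def _data(self, rng, n_per=20, shift=0.0):
        n = 2 * n_per
        y = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["a", "b", "c"])
        y.iloc[n_per:] += shift
        group = ["g1"] * n_per + ["g2"] * n_per
        return y, group

    def test_identical_means_v_near_zero(self):
        rng = np.random.default_rng(15)
        y, group = self._data(rng)
        y.iloc[20:] = y.iloc[:20].to_numpy()  # mirror the groups exactly
        res = pillai_group_test(y, group)
        assert res.pillai_v == pytest.approx(0.0, abs=1e-10)

    def test_single_outcome_reduces_to_anova(self):
        rng = np.random.default_rng(16)
        a = rng.normal(0, 1, 18)
        b = rng.normal(0.8, 1, 22)
        f_anova, df1, df2, p_anova = one_way_anova([a, b])
        y = pd.DataFrame({"a": np.concatenate([a, b])})
        res = pillai_group_test(y, ["g1"] * 18 + ["g2"] * 22)
        assert res.f_approx == pytest.approx(f_anova, rel=1e-8)
        assert res.p == pytest.approx(p_anova, rel=1e-8)
        assert (res.df_num, res.df_den) == (df1, df2)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(17)
        y, group = self._data(rng, shift=0.6)
        res = pillai_group_test(y, group)
        frame = y.copy()
        frame["group"] = group
        ref = MANOVA.from_formula("a + b + c ~ group", data=frame)
        table = ref.mv_test().results["group"]["stat"]
        assert res.pillai_v == pytest.approx(table.loc["Pillai's trace", "Value"], abs=1e-8)
        assert res.f_approx == pytest.approx(table.loc["Pillai's trace", "F Value"], rel=1e-6)
        assert res.p == pytest.approx(table.loc["Pillai's trace", "Pr > F"], abs=1e-8)

    def test_covariate_partialled(self):
        rng = np.random.default_rng(18)
        y, group = self._data(rng, shift=0.0)
        cov = rng.normal(0, 1, len(y))
        for col in y:
            y[col] = y[col] + 0.9 * cov  # outcome depends on covariate only
        res = pillai_group_test(y, group, covariate=cov)
        assert res.p > 0.01  # no group effect once covariate is partialled

    def test_null_calibration_small(self):
        rng = np.random.default_rng(19)
        pvals = []
        for _ in range(200):
            y, group = self._data(rng, n_per=12)
            pvals.append(pillai_group_test(y, group).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_inputs_rejected(self):
        y = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            pillai_group_test(y, ["g1", "g1", "g1"])


class TestRetest:
    def test_identical_administrations(self):
        s = PairedSample((10.0, 12.0, 14.0, 16.0), (10.0, 12.0, 14.0, 16.0))
        rep = retest_report(s)
        assert rep.r == pytest.approx(1.0)
        assert rep.t == 0.0

    def test_shift_with_noise_detected(self):
        rng = np.random.default_rng(20)
        t1 = rng.normal(28.0, 7.0, 28)
        t2 = t1 + 1.5 + rng.normal(0, 0.5, 28)
        rep = retest_report(PairedSample(tuple(t1), tuple(t2)))
        assert rep.r > 0.9
        assert abs(rep.t) > 2.0

    def test_descriptives(self):
        s = PairedSample((1.0, 2.0, 3.0, 10.0), (2.0, 3.5, 4.0, 10.5))
        rep = retest_report(s)
        assert rep.time1.minimum == 1.0
        assert rep.time1.maximum == 10.0
        assert rep.time1.median == 2.5
        assert rep.time2.mean == 5.0
        assert rep.n == 4

    def test_stable_agents_give_positive_reliability(self):
        # same synthetic participants at two time points (different seeds)
        # should correlate positively across replicate mini-cohorts
        from attnbattery.agents import ControllerSpec, GreedyAvoidController
        from attnbattery.moa import MOAConfig, run_session

        rng = np.random.default_rng(21)
        rs = []
        for rep in range(5):
            t1, t2 = [], []
            for i in range(10):
                latency = float(rng.uniform(0.0, 0.6))
                spec = ControllerSpec(
                    kind="greedy_avoid", reaction_latency=latency, seed=1000 + i
                )
                for out, master in ((t1, rep * 1000 + i), (t2, rep * 1000 + 500 + i)):
                    cfg = MOAConfig(
                        n_practice_trials=0,
                        n_recorded_trials=3,
                        max_trial_duration=25.0,
                        master_seed=master,
                    )
                    out.append(run_session(cfg, GreedyAvoidController(spec)).moa_score)
            r, _ = pearson_r(t1, t2)
            rs.append(r)
        assert np.mean(rs) > 0.0
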