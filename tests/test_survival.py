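import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from matrisig.io import SurvivalTable, ValidationError
from matrisig.simulate import simulate_survival_cohort
from matrisig.survival import (
    CoxPH,
    km_estimate,
    logrank_test,
    quartile_stratify,
    signature_score_survival,
)


class TestQuartileStratify:
    def test_one_to_eight(self):
        labels = quartile_stratify(np.arange(1, 9, dtype=float))
        assert list(labels[:2]) == ["low", "low"]
        assert list(labels[-2:]) == ["high", "high"]
        assert list(labels[2:6]) == ["mid"] * 4

    def test_four_distinct_values(self):
        labels = quartile_stratify([1.0, 2.0, 3.0, 4.0])
        assert list(labels).count("low") == 1
        assert list(labels).count("high") == 1

    def test_identical_values_degenerate(self):
        with pytest.raises(ValidationError, match="identical"):
            quartile_stratify([2.0] * 10)

    def test_too_few(self):
        with pytest.raises(ValidationError, match=">= 4"):
            quartile_stratify([1.0, 2.0, 3.0])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([5, 8, 12], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.n_risk, [3, 2, 1])

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([3, 6, 9], [0, 0, 0])
        assert len(km.event_times) == 0
        assert km.survival_at(100.0) == 1.0

    def test_no_censoring_equals_empirical_cdf(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 40)
        km = km_estimate(times, np.ones(40, dtype=int))
        for t in km.event_times:
            assert km.survival_at(t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        km = km_estimate(rng.exponential(5, 60), rng.integers(0, 2, 60))
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all((km.survival >= 0) & (km.survival <= 1))

    def test_empty_error(self):
        with pytest.raises(ValidationError, match="empty"):
            km_estimate([], [])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 80).round(1) + 0.1  # force ties
        events = rng.integers(0, 2, 80)
        km = km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(kmf.predict(t), abs=1e-10)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [2, 4, 6, 2, 4, 6]
        events = [1, 1, 0, 1, 1, 0]
        groups = ["a", "a", "a", "b", "b", "b"]
        stat, df, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_six_patients(self):
        # A: (1,+), (3,cens), (5,+); B: (2,+), (4,+), (6,cens)
        # O_A = 2, E_A = 1/2 + 2/5 + 1/3 + 1/2 = 26/15, V = 0.25+0.24+2/9+0.25
        times = [1, 3, 5, 2, 4, 6]
        events = [1, 0, 1, 1, 1, 0]
        groups = ["A", "A", "A", "B", "B", "B"]
        stat, df, p = logrank_test(times, events, groups)
        o_minus_e = 2 - 26 / 15
        var = 0.25 + 0.24 + 2 / 9 + 0.25
        assert stat == pytest.approx(o_minus_e**2 / var, rel=1e-12)
        assert stat == pytest.approx(0.0739031, rel=1e-5)

    def test_matches_lifelines_two_groups(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(8)
        t1, t2 = rng.exponential(10, 40), rng.exponential(6, 35)
        e1, e2 = rng.integers(0, 2, 40), rng.integers(0, 2, 35)
        stat, df, p = logrank_test(
            np.concatenate([t1, t2]),
            np.concatenate([e1, e2]),
            ["a"] * 40 + ["b"] * 35,
        )
        ll = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert stat == pytest.approx(ll.test_statistic, rel=1e-9)
        assert p == pytest.approx(ll.p_value, rel=1e-9)

    def test_three_group_df(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 60)
        events = np.ones(60, dtype=int)
        groups = np.repeat(["a", "b", "c"], 20)
        stat, df, p = logrank_test(times, events, groups)
        assert df == 2
        assert stat > 0

    def test_empty_group_error(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


def _binary_fixture(seed=0, n=60):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    times = rng.exponential(1.0 / (0.1 * np.exp(0.8 * x)))
    times = times + rng.uniform(0, 1e-6, n)  # tie-free
    events = (rng.random(n) < 0.8).astype(int)
    return times, events, x


class TestCox:
    def test_binary_covariate_matches_score_equation_root(self):
        """The fitted coefficient solves the partial-likelihood score
        equation, verified by an independently coded per-event score
        function and bisection."""
        times, events, x = _binary_fixture()

        def score(beta):
            # direct O(n^2) partial-likelihood score: sum over events of
            # x_i minus the risk-set weighted average of x
            total = 0.0
            for i in range(len(times)):
                if events[i] == 1:
                    risk = times >= times[i]
                    w = np.exp(beta * x[risk])
                    total += x[i] - np.sum(w * x[risk]) / np.sum(w)
            return total

        root = brentq(score, -5, 5, xtol=1e-12)
        fit = CoxPH.from_arrays(times, events, x[:, None], names=["grp"]).fit()
        assert fit.params["grp"] == pytest.approx(root, abs=1e-7)
        assert fit.converged

    def test_efron_equals_breslow_without_ties(self):
        times, events, x = _binary_fixture(seed=2)
        model = CoxPH.from_arrays(times, events, x[:, None], names=["grp"])
        fe = model.fit(ties="efron")
        fb = model.fit(ties="breslow")
        assert fe.params["grp"] == pytest.approx(fb.params["grp"], abs=1e-10)
        assert fe.llf == pytest.approx(fb.llf, abs=1e-10)

    def test_loglik_improves_over_null(self):
        times, events, x = _binary_fixture(seed=3)
        fit = CoxPH.from_arrays(times, events, x[:, None], names=["grp"]).fit()
        assert fit.llf >= fit.llnull

    def test_null_covariate_recovered(self):
        """A covariate independent of hazard lands within 2 SE of zero."""
        rng = np.random.default_rng(10)
        n = 500
        z = rng.normal(size=n)
        times = rng.exponential(10, n)
        events = (rng.random(n) < 0.7).astype(int)
        fit = CoxPH.from_arrays(times, events, z[:, None], names=["z"]).fit()
        assert abs(fit.params["z"]) < 2 * fit.bse["z"]

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        n = 120
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        times = np.ceil(rng.exponential(1.0 / (0.1 * np.exp(0.5 * x1 + 0.3 * x2))))
        events = (rng.random(n) < 0.8).astype(int)
        df = pd.DataFrame({"time": times, "event": events, "x1": x1, "x2": x2})
        fit = CoxPH(SurvivalTable(data=df), ["x1", "x2"]).fit(ties="efron")
        cph = lifelines.CoxPHFitter().fit(df, duration_col="time", event_col="event")
        np.testing.assert_allclose(
            fit.params[["x1", "x2"]], cph.params_[["x1", "x2"]], atol=1e-6
        )
        np.testing.assert_allclose(
            fit.bse[["x1", "x2"]], cph.standard_errors_[["x1", "x2"]], atol=1e-6
        )

    def test_summary_columns(self):
        times, events, x = _binary_fixture(seed=6)
        fit = CoxPH.from_arrays(times, events, x[:, None], names=["grp"]).fit()
        summary = fit.summary()
        assert {"coef", "HR", "se(coef)", "z", "p"} <= set(summary.columns)
        assert (summary["HR"] > 0).all()

    def test_needs_two_events(self):
        with pytest.raises(ValidationError, match="2 events"):
            CoxPH.from_arrays([1, 2, 3, 4], [0, 0, 1, 0], np.arange(4.0)[:, None])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            CoxPH.from_arrays([1, 2, 3, 4], [1, 1, 1, 0], np.ones((4, 1)))

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=30)
        X = np.column_stack([z, 2 * z])
        with pytest.raises(ValidationError, match="collinear"):
            CoxPH.from_arrays(rng.exponential(5, 30), np.ones(30, dtype=int), X)


class TestScoreSurvival:
    def test_planted_hazard_recovered(self):
        """Gene-set score drives hazard with HR 2; the fitted high-vs-low
        hazard ratio lands inside [1.5, 2.7] at n = 400."""
        clin, expr, gene_set, truth = simulate_survival_cohort(
            n=400, beta_high=np.log(2.0), beta_stromal=0.3, seed=12, with_expression=True
        )
        result = signature_score_survival(expr, gene_set, clin)
        hr = result.cox.hazard_ratios["score_high"]
        assert 1.5 <= hr <= 2.7
        assert result.cox.pvalues["score_high"] < 0.05
        assert "stromal_score" in result.cox.params.index

    def test_identical_expression_errors(self):
        clin, expr, gene_set, _ = simulate_survival_cohort(
            n=50, seed=1, with_expression=True
        )
        flat = expr.values.copy()
        flat.loc[:, :] = 1.0
        from matrisig.io import ExpressionMatrix

        with pytest.raises(ValidationError):
            signature_score_survival(ExpressionMatrix(values=flat), gene_set, clin)

    def test_small_join_errors(self):
        clin, expr, gene_set, _ = simulate_survival_cohort(n=30, seed=2, with_expression=True)
        small = expr.values.iloc[:, :5]
        from matrisig.io import ExpressionMatrix

        with pytest.raises(ValidationError, match=">= 8"):
            signature_score_survival(ExpressionMatrix(values=small), gene_set, clin)
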