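import itertools

import numpy as np
import pandas as pd
import pytest

from ctpirp.cohort import FollowUp
from ctpirp.survival import (
    ConvergenceError,
    SurvivalCurve,
    fit_cox,
    information_criteria,
    km_curve,
    km_risk_at,
    predict_node_survival,
)


def fus(pairs):
    return [FollowUp(t, e) for t, e in pairs]


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        curve = km_curve(fus([(t, "rrt") for t in times]), "rrt")
        for k, t in enumerate(times):
            assert curve.survival_at(t) == pytest.approx(1 - (k + 1) / 5, abs=1e-12)

    def test_matches_hand_product_limit_table(self):
        # 6 subjects, interleaved censoring; product-limit by hand:
        # S(1)=5/6, S(2.5)=5/6*3/4=5/8, S(3)=5/8*2/3=5/12, S(5)=0
        curve = km_curve(
            fus([(1, "rrt"), (2, "admin_censor"), (2.5, "rrt"),
                 (3, "rrt"), (4, "admin_censor"), (5, "rrt")]),
            "rrt",
        )
        for t, s in [(1.0, 5 / 6), (2.5, 5 / 8), (3.0, 5 / 12), (5.0, 0.0)]:
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_competing_event_censored_at_its_time(self):
        with_death = km_curve(
            fus([(1, "rrt"), (2, "death"), (3, "rrt")]), "rrt"
        )
        with_censor = km_curve(
            fus([(1, "rrt"), (2, "admin_censor"), (3, "rrt")]), "rrt"
        )
        np.testing.assert_allclose(with_death.survival, with_censor.survival)

    def test_all_censored_is_flat_one(self):
        curve = km_curve(fus([(t, "lost") for t in (1.0, 2.0, 3.0)]), "rrt")
        assert curve.survival_at(3.0) == 1.0

    def test_no_one_at_risk_errors(self):
        with pytest.raises(ValueError, match="at risk"):
            km_curve(fus([(0.5, "rrt")]), "rrt")

    def test_merged_curve_bounded_by_groups_without_censoring(self):
        rng = np.random.default_rng(5)
        g1 = [(0.5 + t, "rrt") for t in rng.exponential(2.0, 80)]
        g2 = [(0.5 + t, "rrt") for t in rng.exponential(0.5, 80)]
        c1, c2 = km_curve(fus(g1), "rrt"), km_curve(fus(g2), "rrt")
        cm = km_curve(fus(g1 + g2), "rrt")
        for t in np.linspace(0.6, 5, 40):
            s1, s2, sm = c1.survival_at(t), c2.survival_at(t), cm.survival_at(t)
            assert min(s1, s2) - 1e-12 <= sm <= max(s1, s2) + 1e-12


class TestKmRiskAt:
    def test_complement_of_survival(self):
        curve = SurvivalCurve(times=[0.5, 4.0], survival=[1.0, 0.8])
        assert km_risk_at(curve, 4.0) == pytest.approx(0.2)

    def test_right_continuity_between_steps(self):
        curve = SurvivalCurve(times=[0.5, 1.0, 2.0], survival=[1.0, 0.9, 0.7])
        assert km_risk_at(curve, 1.5) == pytest.approx(0.1)

    def test_before_entry_errors(self):
        curve = SurvivalCurve(times=[0.5, 1.0], survival=[1.0, 0.9])
        with pytest.raises(ValueError):
            km_risk_at(curve, 0.2)

    def test_recovers_configured_exponential_risk(self):
        # hazard matched to 71.9% net risk at 6 years from a 0.5-year entry
        lam = -np.log(1 - 0.719) / 5.5
        rng = np.random.default_rng(1)
        n = 5000
        t = 0.5 + rng.exponential(1 / lam, n)
        c = 0.5 + rng.uniform(0, 9.5, n)
        data = fus(
            [(min(a, b), "rrt" if a <= b else "admin_censor") for a, b in zip(t, c)]
        )
        assert km_risk_at(km_curve(data, "rrt"), 6.0) == pytest.approx(0.719, abs=0.02)


def cox_loglik_oracle(beta, time, event, x, entry=0.5):
    """Explicit Breslow partial log-likelihood, written out independently."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if entry < time[i] <= time[j]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    def small(self):
        time = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 4.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        return pd.DataFrame({"time": time, "ev": event, "x": x})

    def test_identical_groups_give_null_coefficient(self):
        df = pd.DataFrame(
            {"time": [1, 2, 3, 1, 2, 3], "ev": [1, 1, 0, 1, 1, 0],
             "x": [0, 0, 0, 1, 1, 1]}
        )
        fit = fit_cox(df.astype(float), ["x"], event_col="ev")
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-8)
        assert fit.hazard_ratios["x"] == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_maximization_of_partial_likelihood(self):
        df = self.small()
        fit = fit_cox(df, ["x"], event_col="ev")
        grid = np.arange(-3, 3, 1e-4)
        vals = [
            cox_loglik_oracle(b, df["time"].values, df["ev"].values, df["x"].values)
            for b in grid
        ]
        best = grid[int(np.argmax(vals))]
        assert fit.coefficients["x"] == pytest.approx(best, abs=1e-4)
        assert fit.loglik == pytest.approx(
            cox_loglik_oracle(fit.coefficients["x"], df["time"].values,
                              df["ev"].values, df["x"].values),
            abs=1e-10,
        )

    def test_score_is_zero_at_optimum(self):
        df = self.small()
        fit = fit_cox(df, ["x"], event_col="ev")
        beta = fit.coefficients["x"]
        eps = 1e-6
        t, e, x = df["time"].values, df["ev"].values, df["x"].values
        num_score = (
            cox_loglik_oracle(beta + eps, t, e, x)
            - cox_loglik_oracle(beta - eps, t, e, x)
        ) / (2 * eps)
        assert abs(num_score) < 1e-5

    def test_own_cluster_sandwich_equals_score_residual_oracle(self):
        rng = np.random.default_rng(11)
        n = 60
        x = rng.normal(size=n)
        t = 0.5 + rng.exponential(1 / (0.4 * np.exp(0.6 * x)))
        c = 0.5 + rng.uniform(0, 6, n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "ev": (t <= c).astype(int), "x": x,
             "id": np.arange(n)}
        )
        fit = fit_cox(df, ["x"], event_col="ev", cluster_col="id")
        # independent sandwich evaluation: explicit loops over risk sets
        beta = fit.coefficients["x"]
        time, ev, xs = df["time"].values, df["ev"].values, df["x"].values
        r = np.exp(beta * xs)
        u_times = np.sort(np.unique(time[ev == 1]))
        U = np.zeros(n)
        info = 0.0
        for ut in u_times:
            risk = (time >= ut) & (ut > 0.5)
            s0 = r[risk].sum()
            s1 = (r * xs)[risk].sum()
            s2 = (r * xs * xs)[risk].sum()
            m = s1 / s0
            d = np.sum((time == ut) & (ev == 1))
            info += d * (s2 / s0 - m * m)
            for i in range(n):
                if risk[i]:
                    U[i] -= r[i] * d / s0 * (xs[i] - m)
                if time[i] == ut and ev[i]:
                    U[i] += xs[i] - m
        robust_oracle = (1 / info) * np.sum(U**2) * (1 / info)
        assert fit.robust_covariance.iloc[0, 0] == pytest.approx(
            robust_oracle, rel=1e-8
        )

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(2)
        n = 200
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.5).astype(float)
        t = 0.5 + rng.exponential(1 / (0.3 * np.exp(0.5 * x1 - 0.4 * x2)))
        c = 0.5 + rng.uniform(0, 8, n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "ev": (t <= c).astype(int),
             "x1": x1, "x2": x2, "entry": 0.5}
        )
        fit = fit_cox(df, ["x1", "x2"], event_col="ev", ties="efron")
        cph = CoxPHFitter().fit(df, "time", "ev", entry_col="entry")
        np.testing.assert_allclose(
            fit.coefficients.values, cph.params_.values, atol=1e-5
        )
        np.testing.assert_allclose(
            fit.model_se.values, cph.standard_errors_.values, atol=1e-5
        )

    def test_complete_separation_raises(self):
        # all events in one group occur before anyone in the other is at risk
        df = pd.DataFrame(
            {"time": [1.0, 1.1, 1.2, 5.0, 5.1, 5.2],
             "ev": [1, 1, 1, 1, 1, 1],
             "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]}
        )
        with pytest.raises(ConvergenceError):
            fit_cox(df, ["x"], event_col="ev")

    def test_singular_design_raises(self):
        df = self.small().assign(x2=lambda d: 2 * d["x"])
        with pytest.raises(ConvergenceError, match="singular"):
            fit_cox(df, ["x", "x2"], event_col="ev")

    def test_coverage_of_true_log_hazard_ratio(self):
        """Simulated proportional-hazards cohorts: 95% CIs cover the truth."""
        from ctpirp.simulate import recovery_experiment

        res = recovery_experiment(
            n_replicates=100, n=2000, true_shr=2.0, estimator="cox", seed=7
        )
        assert res["coverage"].iloc[0] >= 0.90
        assert res["n_nonconverged"].iloc[0] == 0

    def test_sandwich_close_to_model_se_on_independent_data(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.normal(size=n)
        t = 0.5 + rng.exponential(1 / (0.3 * np.exp(0.4 * x)))
        c = 0.5 + rng.uniform(0, 8, n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "ev": (t <= c).astype(int), "x": x}
        )
        fit = fit_cox(df, ["x"], event_col="ev")
        assert fit.robust_se["x"] == pytest.approx(fit.model_se["x"], rel=0.10)


class TestBaselineAndPrediction:
    def _fit(self):
        rng = np.random.default_rng(9)
        n = 300
        x = (rng.random(n) < 0.5).astype(float)
        t = 0.5 + rng.exponential(1 / (0.3 * np.exp(0.7 * x)))
        c = 0.5 + rng.uniform(0, 8, n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "ev": (t <= c).astype(int), "x": x}
        )
        return fit_cox(df, ["x"], event_col="ev")

    def test_reference_prediction_is_baseline(self):
        fit = self._fit()
        pred = predict_node_survival(fit, 0.0)
        np.testing.assert_allclose(pred.survival, fit.baseline_survival.survival)

    def test_log2_coefficient_squares_baseline(self):
        fit = self._fit()
        pred = predict_node_survival(fit, np.log(2.0))
        np.testing.assert_allclose(
            pred.survival, fit.baseline_survival.survival**2, atol=1e-12
        )

    def test_positive_coefficient_lowers_survival(self):
        fit = self._fit()
        pred = predict_node_survival(fit, 0.8)
        assert np.all(pred.survival <= fit.baseline_survival.survival + 1e-12)


class TestInformationCriteria:
    def test_null_model_aic_is_minus_twice_loglik(self):
        rng = np.random.default_rng(10)
        t = 0.5 + rng.exponential(2.0, 50)
        df = pd.DataFrame({"time": t, "ev": np.ones(50, int)})
        fit = fit_cox(df, [], event_col="ev")
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(-2 * fit.loglik)
        assert bic == pytest.approx(-2 * fit.loglik)

    def test_seven_level_factor_has_six_df(self, small_cohorts):
        from ctpirp.validation import fit_node_model

        fit, _ = fit_node_model(small_cohorts[0], "rrt", horizon=4.0)
        assert fit.df == 6
        aic, bic = information_criteria(fit)
        assert bic == pytest.approx(-2 * fit.loglik + np.log(fit.n_events) * 6)

    def test_bic_penalty_grows_with_df(self):
        rng = np.random.default_rng(12)
        n = 200
        x = rng.normal(size=n)
        z = rng.normal(size=n)  # irrelevant
        t = 0.5 + rng.exponential(1 / (0.3 * np.exp(0.5 * x)))
        df = pd.DataFrame({"time": t, "ev": np.ones(n, int), "x": x, "z": z})
        f1 = fit_cox(df, ["x"], event_col="ev")
        f2 = fit_cox(df, ["x", "z"], event_col="ev")
        pen1 = f1.bic + 2 * f1.loglik
        pen2 = f2.bic + 2 * f2.loglik
        assert pen2 > pen1
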