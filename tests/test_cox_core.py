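import numpy as np
import pandas as pd
import pytest

import lifelines
from lifelines.statistics import multivariate_logrank_test

from coxval.cox_core import (
    StepCurve,
    baseline_cumhaz,
    baseline_survival,
    fit_cox,
    kaplan_meier,
    logrank_test,
)
from coxval.exceptions import ConfigurationError, ConvergenceError, DataError
from coxval.model_spec import SurvivalSample


def make(times, events, **covs):
    df = pd.DataFrame({"time": times, "event": events, **covs})
    return SurvivalSample(df, "time", "event")


def breslow_loglik(beta, time, event, x):
    """Hand-coded Breslow partial log-likelihood (1 covariate, oracle)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = np.exp(beta * x[time >= time[i]])
            ll += beta * x[i] - np.log(risk.sum())
    return ll


class TestFitCox:
    def test_symmetric_groups_give_zero_coefficient(self):
        # two arms with identical (time, event) multisets
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        fit = fit_cox(make(t, e, g=[0, 0, 0, 0, 1, 1, 1, 1]), ["g"])
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_gridsearch_maximizer(self, toy_sample):
        fit = fit_cox(toy_sample, ["x"], ties="breslow")
        time, event, x = toy_sample.time, toy_sample.event, toy_sample.data["x"].to_numpy()
        grid = np.linspace(-3, 3, 6001)
        lls = [breslow_loglik(b, time, event, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.coefficients[0] == pytest.approx(best, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(np.max(lls), abs=1e-6)

    def test_matches_lifelines_on_simulated_data(self, sim_pair):
        derivation, _ = sim_pair
        fit = fit_cox(derivation, ["x1", "x2", "x3"])
        cph = lifelines.CoxPHFitter().fit(
            derivation.data[["x1", "x2", "x3", "time", "event"]], "time", "event"
        )
        assert np.allclose(fit.coefficients, cph.params_.values, atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-5)

    def test_efron_equals_breslow_without_ties(self, toy_sample):
        fe = fit_cox(toy_sample, ["x"], ties="efron")
        fb = fit_cox(toy_sample, ["x"], ties="breslow")
        assert fe.coefficients[0] == pytest.approx(fb.coefficients[0], abs=1e-10)

    def test_efron_handles_ties_and_matches_lifelines(self):
        rng = np.random.default_rng(5)
        t = rng.integers(1, 6, 60).astype(float)  # heavy ties
        e = rng.integers(0, 2, 60)
        e[0] = 1
        x = rng.normal(size=60)
        s = make(t, e, x=x)
        fit = fit_cox(s, ["x"], ties="efron")
        cph = lifelines.CoxPHFitter().fit(s.data, "time", "event")  # Efron ties
        assert fit.coefficients[0] == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)

    def test_offset_only_loglik_for_lr_tests(self, toy_sample):
        work = toy_sample.copy()
        fit1 = fit_cox(toy_sample, ["x"])
        work.data["lp"] = fit1.coefficients[0] * work.data["x"]
        fit0 = fit_cox(work, [], offset_name="lp")
        # offset at the optimum reproduces the maximised log-likelihood
        assert fit0.log_likelihood == pytest.approx(fit1.log_likelihood, abs=1e-8)
        assert fit0.coefficients.size == 0

    def test_apparent_calibration_identity(self, sim_pair):
        """Refitting a sample's own linear predictor gives slope exactly 1."""
        derivation, _ = sim_pair
        fit = fit_cox(derivation, ["x1", "x2", "x3"])
        work = derivation.copy()
        work.data["lp"] = (
            work.data[["x1", "x2", "x3"]].to_numpy() @ fit.coefficients
        )
        refit = fit_cox(work, ["lp"])
        assert refit.coefficients[0] == pytest.approx(1.0, abs=1e-7)

    def test_no_events_is_a_data_error(self):
        with pytest.raises(DataError, match="no events"):
            fit_cox(make([1, 2], [0, 0], x=[0.0, 1.0]), ["x"])

    def test_separation_raises_convergence_error(self):
        # perfectly separating covariate: monotone likelihood
        t = np.arange(1.0, 21.0)
        x = (t > 10).astype(float)
        with pytest.raises(ConvergenceError):
            fit_cox(make(t, np.ones(20, int), x=x), ["x"])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = kaplan_meier(make([1, 2, 3], [1, 1, 0]))
        assert np.allclose(km.times, [1, 2])
        assert np.allclose(km.values, [2 / 3, 1 / 3])
        assert km.evaluate(3.0)[0] == pytest.approx(1 / 3)
        assert km.evaluate(0.5)[0] == 1.0

    def test_all_censored_gives_unit_survival(self):
        km = kaplan_meier(make([1, 2, 3], [0, 0, 0]))
        assert km.times.size == 0
        assert km.evaluate(2.0)[0] == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 200)
        km = kaplan_meier(make(t, np.ones(200, int)))
        grid = np.quantile(t, [0.1, 0.4, 0.7])
        for g in grid:
            assert km.evaluate(g)[0] == pytest.approx(np.mean(t > g), abs=1e-12)

    def test_matches_lifelines_and_greenwood_se(self, sim_pair):
        derivation, _ = sim_pair
        km = kaplan_meier(derivation)
        kmf = lifelines.KaplanMeierFitter().fit(derivation.time, derivation.event)
        ours = km.evaluate(np.array([1.0, 3.0, 5.0]))
        theirs = kmf.survival_function_at_times([1.0, 3.0, 5.0]).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)
        # Greenwood on the hand toy: S(1)=2/3 with d/(n(n-d)) = 1/6
        toy = kaplan_meier(make([1, 2, 3], [1, 1, 0]))
        assert toy.se[0] == pytest.approx((2 / 3) * np.sqrt(1 / 6), abs=1e-12)


class TestBaselineCumhaz:
    def test_zero_pi_reduces_to_nelson_aalen(self):
        # hand Nelson-Aalen on 4 subjects: t=1,2,3,4 events 1,1,0,1
        s = make([1, 2, 3, 4], [1, 1, 0, 1], _pi=np.zeros(4))
        H = baseline_cumhaz(s)
        assert np.allclose(H.times, [1, 2, 4])
        assert np.allclose(H.values, [1 / 4, 1 / 4 + 1 / 3, 1 / 4 + 1 / 3 + 1 / 1])

    def test_offset_shift_rescales_increments_exactly(self, sim_pair):
        derivation, _ = sim_pair
        s = derivation.with_pi(derivation.data["_true_lp"].to_numpy())
        H0 = baseline_cumhaz(s)
        shifted = s.with_pi(s.pi + 0.7)
        H1 = baseline_cumhaz(shifted)
        assert np.allclose(H1.values, H0.values * np.exp(-0.7), rtol=1e-10)

    def test_increments_positive_finite_and_survival_agrees(self, sim_pair):
        derivation, _ = sim_pair
        s = derivation.with_pi(derivation.data["_true_lp"].to_numpy())
        H = baseline_cumhaz(s)
        inc = np.diff(np.concatenate(([0.0], H.values)))
        assert np.all(inc > 0) and np.isfinite(H.values[-1])
        # exp(-H) close to the product-limit S0 while risk sets are large
        s_exp = baseline_survival(s, method="exp")
        s_pl = baseline_survival(s, method="product-limit")
        big = H.at_risk > 20
        assert np.max(np.abs(s_exp.values[big] - s_pl.values[big])) < 0.01

    def test_no_events_is_a_data_error(self):
        with pytest.raises(DataError):
            baseline_cumhaz(make([1, 2], [0, 0], _pi=[0.0, 0.0]))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        s = make([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1], _group=list("aaabbb"))
        with pytest.warns(UserWarning, match="not recommended"):
            r = logrank_test(s)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_lifelines_multigroup(self, sim_pair):
        derivation, _ = sim_pair
        g = pd.qcut(derivation.data["_true_lp"], 3, labels=["lo", "mid", "hi"])
        s = derivation.copy()
        s.data["_group"] = g
        with pytest.warns(UserWarning):
            ours = logrank_test(s)
        theirs = multivariate_logrank_test(s.time, g, s.event)
        assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.df == 2

    def test_invariant_to_relabelling(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1, 90)
        e = rng.integers(0, 2, 90)
        e[:3] = 1
        g = rng.choice(list("abc"), 90)
        s1 = make(t, e, _group=g)
        relabel = {"a": "z", "b": "y", "c": "x"}
        s2 = make(t, e, _group=[relabel[v] for v in g])
        with pytest.warns(UserWarning):
            r1, r2 = logrank_test(s1), logrank_test(s2)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_single_group_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            logrank_test(make([1, 2], [1, 1], _group=["a", "a"]))


class TestStepCurve:
    def test_csv_roundtrip(self, tmp_path):
        c = StepCurve([1.0, 2.0], [0.8, 0.5], "survival", se=[0.05, 0.08],
                      at_risk=[10, 6], n_events=[2, 3])
        path = tmp_path / "curve.csv"
        c.to_csv(path)
        back = StepCurve.from_csv(path, flavor="survival")
        assert np.allclose(back.values, c.values)
        assert np.allclose(back.se, c.se)

    def test_flavor_monotonicity_enforced(self):
        with pytest.raises(ConfigurationError):
            StepCurve([1.0, 2.0], [0.5, 0.8], "survival")
        with pytest.raises(ConfigurationError):
            StepCurve([1.0, 2.0], [0.8, 0.5], "cumhaz")
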