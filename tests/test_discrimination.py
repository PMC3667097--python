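import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import make_censored_dataset
from coxval.discrimination import (
    KAPPA,
    SIGMA2_PH,
    d_statistic,
    discrimination_report,
    gonen_heller_k,
    harrell_c,
    r2_d,
    r2_pm,
)
from coxval.model_spec import SurvivalSample
from coxval.synthetic_data import SimulationScenario, generate


def brute_force_c(time, event, pi):
    """Exhaustive O(n^2) concordance oracle."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                usable = True
            elif time[i] == time[j] and event[i] == 1 and event[j] == 0:
                usable = True
            else:
                usable = False
            if usable:
                den += 1
                if pi[i] > pi[j]:
                    num += 1
                elif pi[i] == pi[j]:
                    num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_ordering_gives_one(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        s = SurvivalSample(
            pd.DataFrame({"time": t, "event": 1, "_pi": -t}), "time", "event"
        )
        assert harrell_c(s).estimate == 1.0

    def test_five_subject_mixed_censoring_oracle(self):
        df = pd.DataFrame(
            {
                "time": [2.0, 3.0, 3.0, 5.0, 7.0],
                "event": [1, 0, 1, 1, 0],
                "_pi": [0.5, 0.5, -0.2, 0.1, -1.0],
            }
        )
        s = SurvivalSample(df, "time", "event")
        expected = brute_force_c(s.time, s.event, s.pi)
        assert harrell_c(s).estimate == pytest.approx(expected, abs=1e-14)

    def test_matches_bruteforce_on_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            s = make_censored_dataset(rng, int(rng.integers(8, 50)))
            c = harrell_c(s).estimate
            assert c == pytest.approx(brute_force_c(s.time, s.event, s.pi), abs=1e-12)

    def test_se_agrees_with_bootstrap_roughly(self):
        rng = np.random.default_rng(9)
        s = make_censored_dataset(rng, 300)
        analytic = harrell_c(s).se
        reps = []
        for _ in range(120):
            idx = rng.integers(0, 300, 300)
            b = SurvivalSample(s.data.iloc[idx].reset_index(drop=True), "time", "event")
            reps.append(harrell_c(b).estimate)
        boot = np.std(reps, ddof=1)
        assert 0.5 * boot < analytic < 2.0 * boot


class TestGonenHellerK:
    def test_all_equal_pi_gives_half_with_warning(self):
        with pytest.warns(UserWarning, match="0.5"):
            K = gonen_heller_k(np.ones(10))
        assert K.estimate == 0.5

    def test_explicit_double_sum_n4(self):
        pi = np.array([-1.0, 0.2, 0.5, 2.0])
        expected = 0.0
        for i in range(4):
            for j in range(4):
                if i != j:
                    expected += expit(abs(pi[i] - pi[j]))
        expected /= 12
        assert gonen_heller_k(pi).estimate == pytest.approx(expected, abs=1e-14)

    def test_location_invariant_but_not_rank_invariant(self):
        rng = np.random.default_rng(1)
        pi = rng.normal(0, 1, 200)
        k0 = gonen_heller_k(pi).estimate
        assert gonen_heller_k(pi + 5.0).estimate == pytest.approx(k0, abs=1e-12)
        # a strictly increasing nonlinear transform changes K
        assert gonen_heller_k(np.exp(pi)).estimate != pytest.approx(k0, abs=1e-4)

    def test_outcome_independence(self):
        """K uses only the PI distribution, never the outcomes."""
        rng = np.random.default_rng(2)
        s = make_censored_dataset(rng, 100)
        k1 = gonen_heller_k(s.pi).estimate
        permuted = s.data.sample(frac=1, random_state=0)  # outcomes shuffled vs pi
        k2 = gonen_heller_k(permuted["_pi"].to_numpy()).estimate
        assert k1 == pytest.approx(k2, abs=1e-14)

    def test_bootstrap_se_close_to_analytic(self):
        rng = np.random.default_rng(3)
        pi = rng.normal(0, 0.8, 250)
        a = gonen_heller_k(pi, se_method="analytic").se
        b = gonen_heller_k(pi, se_method="bootstrap", n_boot=300, seed=1).se
        assert 0.5 * b < a < 2.0 * b


class TestDStatistic:
    def test_constants(self):
        assert round(KAPPA, 3) == 1.596
        assert round(SIGMA2_PH, 3) == 1.645

    def test_constant_pi_gives_zero_with_warning(self):
        s = SurvivalSample(
            pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0], "_pi": 0.0}),
            "time",
            "event",
        )
        with pytest.warns(UserWarning):
            assert d_statistic(s).estimate == 0.0

    def test_d_approximates_kappa_times_pi_sd(self):
        """For a Normal PI used as the true log-hazard, D ~ kappa * SD(PI)."""
        rng = np.random.default_rng(11)
        n, s_true = 5000, 0.8
        pi = rng.normal(0, s_true, n)
        t = rng.exponential(1.0 / np.exp(pi))
        c = np.full(n, np.quantile(t, 0.8))
        samp = SurvivalSample(
            pd.DataFrame(
                {"time": np.minimum(t, c), "event": (t <= c).astype(int), "_pi": pi}
            ),
            "time",
            "event",
        )
        D = d_statistic(samp)
        assert D.estimate == pytest.approx(KAPPA * s_true, abs=4 * D.se)


class TestExplainedVariation:
    def test_r2_d_values(self):
        assert r2_d(0.0) == 0.0
        assert round(r2_d(1.0), 4) == 0.1927

    def test_r2_pm_values(self):
        assert r2_pm(0.0) == 0.0
        assert round(r2_pm(0.60), 4) == 0.1796

    def test_r2_pm_monotone(self):
        s = np.linspace(0.1, 3, 25)
        v = [r2_pm(x) for x in s]
        assert np.all(np.diff(v) > 0)


class TestRankInvariance:
    def test_c_d_r2d_depend_on_pi_only_through_ranks(self):
        rng = np.random.default_rng(21)
        s = make_censored_dataset(rng, 150)
        transformed = s.copy()
        transformed.data["_pi"] = np.exp(2.0 * s.pi) - 1.0  # strictly increasing
        assert harrell_c(s).estimate == pytest.approx(
            harrell_c(transformed).estimate, abs=1e-12
        )
        assert d_statistic(s).estimate == pytest.approx(
            d_statistic(transformed).estimate, abs=1e-9
        )

    def test_censoring_biases_c_upward_but_not_k(self):
        # Lognormal AFT data: discrimination decays with follow-up time, so
        # heavy right-censoring (which overweights early pairs) inflates c.
        # Under exact PH the pair-level concordance is time-constant and c is
        # censoring-stable, which is why K targets the PH concordance.
        rng = np.random.default_rng(31)
        n = 3000
        pi = rng.normal(0, 0.7, n)
        t = np.exp(-pi + rng.normal(0, 1.0, n))
        full = SurvivalSample(
            pd.DataFrame({"time": t, "event": np.ones(n, int), "_pi": pi}),
            "time",
            "event",
        )
        horizon = np.quantile(t, 0.3)  # heavy administrative censoring
        cens = SurvivalSample(
            pd.DataFrame(
                {
                    "time": np.minimum(t, horizon),
                    "event": (t <= horizon).astype(int),
                    "_pi": pi,
                }
            ),
            "time",
            "event",
        )
        assert harrell_c(cens).estimate > harrell_c(full).estimate
        assert gonen_heller_k(cens.pi).estimate == gonen_heller_k(full.pi).estimate


def test_report_is_internally_consistent(sim_pair):
    derivation, _ = sim_pair
    s = derivation.with_pi(derivation.data["_true_lp"].to_numpy())
    rep = discrimination_report(s)
    assert 0 <= rep.harrell_c.estimate <= 1
    assert 0 <= rep.gonen_heller_k.estimate <= 1
    assert 0 <= rep.r2_d < 1 and 0 <= rep.r2_pm < 1
    assert rep.r2_d == pytest.approx(r2_d(rep.d_statistic.estimate), abs=1e-12)
    frame = rep.to_frame()
    assert list(frame.columns) == ["measure", "estimate", "se"]
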