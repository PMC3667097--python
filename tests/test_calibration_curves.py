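import numpy as np
import pandas as pd
import pytest

from coxval.baseline_smooth import FP2BaselineFit, bootstrap_band
from coxval.calibration_curves import (
    compare_baselines,
    group_hazard_ratios,
    group_mean_curve_from_mean_pi,
    group_mean_curves,
    observed_vs_predicted,
    predict_individual_survival,
)
from coxval.cox_core import baseline_cumhaz
from coxval.exceptions import ConfigurationError
from coxval.model_spec import (
    RiskGrouping,
    SurvivalSample,
    assign_groups,
    compute_pi,
)
from coxval.synthetic_data import SimulationScenario, apparent_scenario, generate


def flat_fit(s0=0.8, time_range=(0.1, 10.0)):
    """A constant-ish baseline for hand calculations: ln H0 = const."""
    lnH = np.log(-np.log(s0))
    return FP2BaselineFit(
        powers=(0.0, 1.0), coefficients=(lnH, 0.0, 0.0), r_squared=1.0,
        time_range=time_range,
    )


class TestPredictIndividual:
    def test_zero_pi_reproduces_s0(self):
        fit = flat_fit(0.8)
        assert predict_individual_survival(fit, 0.0, 1.0)[0] == pytest.approx(0.8)

    def test_log_two_pi_squares_s0(self):
        fit = flat_fit(0.8)
        assert predict_individual_survival(fit, np.log(2.0), 1.0)[0] == pytest.approx(0.64)

    def test_extrapolation_refused_with_guidance(self):
        fit = flat_fit(0.8, time_range=(0.5, 5.0))
        with pytest.raises(ConfigurationError, match="truncate"):
            predict_individual_survival(fit, 0.0, 6.0)


def grouped_sample(pis, groups, times=None):
    n = len(pis)
    df = pd.DataFrame(
        {
            "time": times if times is not None else np.linspace(1, 5, n),
            "event": 1,
            "_pi": pis,
        }
    )
    s = SurvivalSample(df, "time", "event")
    s.data["_group"] = pd.Categorical(groups)
    return s


class TestGroupMeanCurves:
    def test_identical_members_equal_individual_curve(self):
        s = grouped_sample([0.3, 0.3, 0.3], ["a", "a", "a"])
        curves = group_mean_curves(s, flat_fit(0.9), times=[1.0, 2.0])
        ind = predict_individual_survival(flat_fit(0.9), 0.3, [1.0, 2.0])
        assert np.allclose(curves["a"].values, ind)

    def test_two_member_average(self):
        s = grouped_sample([0.0, np.log(2.0)], ["a", "a"])
        curves = group_mean_curves(s, flat_fit(0.9), times=[1.0])
        assert curves["a"].values[0] == pytest.approx((0.9 + 0.81) / 2)

    def test_mean_curve_within_member_envelope(self, sim_pair, bundle):
        _, validation = sim_pair
        v = assign_groups(compute_pi(bundle.model, validation), bundle.grouping)
        times = np.linspace(*bundle.baseline_fit.time_range, 25)
        curves = group_mean_curves(v, bundle.baseline_fit, times=times)
        lnH = bundle.baseline_fit.evaluate_log_cumhaz(times)
        for lab, curve in curves.items():
            pis = v.pi[(v.group == lab).to_numpy()]
            member = np.exp(-np.exp(lnH[None, :] + pis[:, None]))
            assert np.all(curve.values <= member.max(axis=0) + 1e-12)
            assert np.all(curve.values >= member.min(axis=0) - 1e-12)

    def test_group_ordering_preserved_at_all_times(self, sim_pair, bundle):
        _, validation = sim_pair
        v = assign_groups(compute_pi(bundle.model, validation), bundle.grouping)
        times = np.linspace(*bundle.baseline_fit.time_range, 10)
        curves = group_mean_curves(v, bundle.baseline_fit, times=times)
        order = list(curves)  # Good ... Poor
        for a, b in zip(order, order[1:]):
            assert np.all(curves[a].values >= curves[b].values)

    def test_mean_pi_plugin_differs_by_jensen(self):
        s = grouped_sample([-1.0, 1.0], ["a", "a"])
        proper = group_mean_curves(s, flat_fit(0.7), times=[1.0])["a"].values[0]
        plugin = group_mean_curve_from_mean_pi(s, flat_fit(0.7), [1.0])["a"].values[0]
        assert proper < plugin  # exp(-e^x) is convex in PI here

    def test_empty_group_warned_and_omitted(self):
        s = grouped_sample([0.1, 0.2], ["a", "a"])
        s.data["_group"] = pd.Categorical(["a", "a"], categories=["a", "b"])
        with pytest.warns(UserWarning, match="empty"):
            curves = group_mean_curves(s, flat_fit(0.9), times=[1.0])
        assert "b" not in curves


class TestObservedVsPredicted:
    def test_prediction_depends_only_on_pi_distribution(self, bundle):
        """Matching PI values per group give identical predicted columns,
        whatever the outcomes are."""
        pis = np.array([-0.5, -0.2, 0.1, 0.6])
        a = grouped_sample(pis, list("aabb"), times=[1.0, 2.0, 3.0, 4.0])
        b = grouped_sample(pis, list("aabb"), times=[4.0, 3.0, 2.0, 1.0])
        fit = bundle.baseline_fit
        ta = observed_vs_predicted(a, fit, timepoints=(2.0, 3.0)).to_frame()
        tb = observed_vs_predicted(b, fit, timepoints=(2.0, 3.0)).to_frame()
        assert np.allclose(ta["predicted"], tb["predicted"])

    def test_self_consistent_simulation_calibrates(self):
        """Data generated from the published model: observed and predicted
        agree within Monte-Carlo noise in nearly all cells."""
        scn = SimulationScenario(n_subjects=5000, seed=101)
        derivation, validation = generate(scn)
        bundle = apparent_scenario(derivation)
        v = assign_groups(compute_pi(bundle.model, validation), bundle.grouping)
        tab = observed_vs_predicted(
            v, bundle.baseline_fit, timepoints=(1.0, 2.0, 3.0, 4.0, 5.0)
        ).to_frame()
        ok = np.abs(tab["difference"]) < 2 * tab["observed_se"]
        assert ok.mean() >= 0.9

    def test_timepoint_beyond_followup_flagged(self, bundle):
        s = grouped_sample([0.0, 0.1], ["a", "a"], times=[1.0, 2.0])
        tab = observed_vs_predicted(s, flat_fit(0.9), timepoints=(1.5, 9.0)).to_frame()
        row = tab[tab["time"] == 9.0].iloc[0]
        assert not row["available"] and np.isnan(row["observed"])


class TestGroupHazardRatios:
    def test_identical_groups_have_unit_hr(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        s = grouped_sample([0] * 6, list("aaabbb"), times=t)
        hr = group_hazard_ratios(s)
        assert hr.loc[0, "hr"] == pytest.approx(1.0, abs=1e-6)

    def test_recovers_true_log_hazard_ratios(self):
        rng = np.random.default_rng(17)
        true_log_hr = {"g1": 0.0, "g2": 0.5, "g3": 1.2, "g4": 1.6}
        n = 4000
        g = rng.choice(list(true_log_hr), n)
        lam = np.exp([true_log_hr[x] for x in g])
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(0.5, 3.0, n)
        s = grouped_sample(
            np.zeros(n), g, times=np.minimum(t, c)
        )
        s.data["event"] = (t <= c).astype(int)
        hr = group_hazard_ratios(s)
        for _, row in hr.iterrows():
            assert abs(row["log_hr"] - true_log_hr[row["group"]]) < 2 * row["log_hr_se"]

    def test_group_without_events_gets_infinite_se_flag(self):
        s = grouped_sample([0.0] * 6, list("aaabbb"), times=[1, 2, 3, 4, 5, 6])
        s.data.loc[s.data["_group"] == "b", "event"] = 0
        hr = group_hazard_ratios(s)
        row = hr[hr["group"] == "b"].iloc[0]
        assert row["infinite_se"] and row["hr"] == 0.0 and np.isinf(row["hr_se"])


class TestCompareBaselines:
    def test_offset_equivariance_is_exact(self, sim_pair):
        """Shifting the PI by +c rescales the empirical baseline by exp(-c),
        matching a baseline fit whose intercept drops by c."""
        _, validation = sim_pair
        v = validation.with_pi(validation.data["_true_lp"].to_numpy())
        c = 0.9
        H0 = baseline_cumhaz(v)
        H1 = baseline_cumhaz(v.with_pi(v.pi + c))
        assert np.allclose(H1.values, H0.values * np.exp(-c), rtol=1e-10)

    def test_self_consistent_validation_lies_inside_band(self):
        """A wide derivation (small n) band should cover the precise
        empirical baseline of a large self-consistent validation sample."""
        der_scn = SimulationScenario(n_subjects=500, seed=301)
        derivation, _ = generate(der_scn)
        bundle = apparent_scenario(derivation)
        d = compute_pi(bundle.model, derivation)
        band = bootstrap_band(d, n_boot=100, seed=11)
        val_scn = SimulationScenario(n_subjects=4000, seed=302)
        _, validation = generate(val_scn)
        v = compute_pi(bundle.model, validation)
        comp = compare_baselines(v, bundle.baseline_fit, band=band)
        assert comp.band_coverage >= 0.9

    def test_doubled_hazard_is_detected(self):
        """rho = 2 miscalibration yields a far larger baseline discrepancy
        than the self-consistent case."""
        scn0 = SimulationScenario(n_subjects=2000, seed=401)
        derivation, validation0 = generate(scn0)
        bundle = apparent_scenario(derivation)
        comp0 = compare_baselines(compute_pi(bundle.model, validation0), bundle.baseline_fit)
        scn2 = SimulationScenario(n_subjects=2000, baseline_hazard_multiplier=2.0, seed=401)
        _, validation2 = generate(scn2)
        comp2 = compare_baselines(compute_pi(bundle.model, validation2), bundle.baseline_fit)
        assert comp2.max_abs_difference > 3 * comp0.max_abs_difference
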