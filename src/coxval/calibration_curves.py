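"""Risk-group curves: observed vs model-predicted survival (methods 4-7).

Given a transportable baseline S0(t), individual predicted survival is
S(t; PI) = S0(t)^exp(PI).  Per risk group, the *predicted* curve is the
pointwise arithmetic mean of the member-level predicted curves (averaging
survival probabilities, not PIs: by Jensen's inequality plugging the
group-mean PI into S0^exp(.) gives a different, optimistic curve, which is
available only as a labelled diagnostic).  The *observed* curve is the
group Kaplan-Meier estimate.  Superimposing or tabulating the two at
chosen time points is the strictest calibration check a published Cox
model supports.

The module also provides between-group hazard ratios (a sensible
discrimination check, unlike between-group significance tests) and the
comparison of the transported baseline with the offset-constrained
empirical baseline of the validation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .baseline_smooth import BootstrapBand
from .cox_core import StepCurve, baseline_cumhaz, fit_cox, kaplan_meier
from .exceptions import ConfigurationError, DataError
from .model_spec import GROUP_COL, PI_COL, SurvivalSample

__all__ = [
    "GroupCalibrationTable",
    "BaselineComparison",
    "predict_individual_survival",
    "group_mean_curves",
    "group_mean_curve_from_mean_pi",
    "observed_vs_predicted",
    "group_hazard_ratios",
    "compare_baselines",
]


def predict_individual_survival(fit, pi: float, times, allow_extrapolation: bool = False):
    """S(t; PI) = S0(t)^exp(PI) for one subject."""
    if not np.isfinite(pi):
        raise DataError("PI must be finite")
    lnH = fit.evaluate_log_cumhaz(times, allow_extrapolation=allow_extrapolation)
    return np.exp(-np.exp(lnH + pi))


def _grouped(sample: SurvivalSample):
    if not sample.has_group:
        raise ConfigurationError("risk groups have not been assigned")
    g = sample.group
    if hasattr(g.dtype, "categories"):
        labels = list(g.dtype.categories)
    else:
        labels = sorted(g.dropna().unique())
    return g, labels


def group_mean_curves(
    sample: SurvivalSample,
    fit,
    times: Optional[np.ndarray] = None,
) -> dict[str, StepCurve]:
    """Per-group predicted survival: mean of member curves at observed times.

    ``times`` defaults to the sample's observed times that fall inside the
    fitted baseline range.  Empty groups are omitted with a warning.
    """
    g, labels = _grouped(sample)
    pi = sample.pi
    if times is None:
        lo, hi = fit.time_range
        obs = np.unique(sample.time)
        times = obs[(obs >= max(lo, np.min(obs))) & (obs <= hi)]
        times = times[times > 0]
    times = np.asarray(times, dtype=float)
    lnH = fit.evaluate_log_cumhaz(times)
    out = {}
    for lab in labels:
        mask = (g == lab).to_numpy()
        if not mask.any():
            warnings.warn(f"risk group {lab!r} is empty; omitted", UserWarning)
            continue
        # members x times survival matrix, then pointwise mean
        S = np.exp(-np.exp(lnH[None, :] + pi[mask, None]))
        out[lab] = StepCurve(times=times, values=S.mean(axis=0), flavor="survival")
    return out


def group_mean_curve_from_mean_pi(sample, fit, times) -> dict[str, StepCurve]:
    """Diagnostic alternative: plug the group-mean PI into S0^exp(.).

    Differs from the proper average of member curves by Jensen's
    inequality; provided for comparison only.
    """
    g, labels = _grouped(sample)
    pi = sample.pi
    times = np.asarray(times, dtype=float)
    lnH = fit.evaluate_log_cumhaz(times)
    out = {}
    for lab in labels:
        mask = (g == lab).to_numpy()
        if not mask.any():
            continue
        out[lab] = StepCurve(
            times=times,
            values=np.exp(-np.exp(lnH + pi[mask].mean())),
            flavor="survival",
        )
    return out


@dataclass
class GroupCalibrationTable:
    """Observed (KM) vs predicted mean survival per group and time point."""

    table: pd.DataFrame
    timepoints: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def observed_vs_predicted(
    sample: SurvivalSample,
    fit,
    timepoints: Sequence[float] = (2.0, 5.0),
) -> GroupCalibrationTable:
    """Table of observed and predicted survival by risk group.

    One row per (group, time point): number at start, events, observed KM
    survival with Greenwood SE, predicted mean survival, and their
    difference.  Time points beyond a group's follow-up are flagged
    unavailable (NaN observed values).
    """
    g, labels = _grouped(sample)
    pi = sample.pi
    rows = []
    for lab in labels:
        mask = (g == lab).to_numpy()
        if not mask.any():
            warnings.warn(f"risk group {lab!r} is empty; omitted", UserWarning)
            continue
        sub = SurvivalSample(
            sample.data.loc[mask].reset_index(drop=True),
            sample.time_col,
            sample.event_col,
        )
        km = kaplan_meier(sub)
        max_t = sub.time.max()
        for tp in timepoints:
            available = tp <= max_t
            obs = float(km.evaluate(tp)[0]) if available else np.nan
            se = float(km.se_at(tp)[0]) if available and km.se is not None else np.nan
            lnH = fit.evaluate_log_cumhaz(np.array([tp]))
            pred = float(np.exp(-np.exp(lnH[0] + pi[mask])).mean())
            rows.append(
                {
                    "group": lab,
                    "time": tp,
                    "n": int(mask.sum()),
                    "events": int(sub.n_events),
                    "observed": obs,
                    "observed_se": se,
                    "predicted": pred,
                    "difference": obs - pred if available else np.nan,
                    "available": available,
                }
            )
    return GroupCalibrationTable(table=pd.DataFrame(rows), timepoints=tuple(timepoints))


def group_hazard_ratios(sample: SurvivalSample) -> pd.DataFrame:
    """Hazard ratios of each risk group versus the lowest-risk group.

    Cox model with a dummy variable per non-reference group.  HR standard
    errors by the delta method from the log scale.  A group without events
    gets HR = 0 with an infinite-SE flag instead of a failed fit.
    """
    g, labels = _grouped(sample)
    present = [lab for lab in labels if (g == lab).any()]
    if len(present) < 2:
        raise ConfigurationError("hazard ratios need at least two non-empty groups")
    ref = present[0]
    events_by_group = {lab: int(sample.event[(g == lab).to_numpy()].sum()) for lab in present}
    fit_labels = [lab for lab in present[1:] if events_by_group[lab] > 0]
    no_event_labels = [lab for lab in present[1:] if events_by_group[lab] == 0]

    work = sample.copy()
    cols = []
    for lab in fit_labels:
        col = f"_grp[{lab}]"
        work.data[col] = (g == lab).astype(float).to_numpy()
        cols.append(col)
    rows = []
    if cols:
        fit = fit_cox(work, cols)
        for lab, beta, se in zip(fit_labels, fit.coefficients, fit.se):
            hr = float(np.exp(beta))
            rows.append(
                {
                    "group": lab,
                    "reference": ref,
                    "log_hr": float(beta),
                    "log_hr_se": float(se),
                    "hr": hr,
                    "hr_se": hr * float(se),
                    "n": int((g == lab).sum()),
                    "events": events_by_group[lab],
                    "infinite_se": False,
                }
            )
    for lab in no_event_labels:
        rows.append(
            {
                "group": lab,
                "reference": ref,
                "log_hr": -np.inf,
                "log_hr_se": np.inf,
                "hr": 0.0,
                "hr_se": np.inf,
                "n": int((g == lab).sum()),
                "events": 0,
                "infinite_se": True,
            }
        )
    order = {lab: i for i, lab in enumerate(labels)}
    return pd.DataFrame(rows).sort_values("group", key=lambda s: s.map(order)).reset_index(drop=True)


@dataclass
class BaselineComparison:
    """Transported FP2 baseline vs the validation data's empirical baseline."""

    empirical: StepCurve  # survival scale, offset-constrained
    smooth_times: np.ndarray
    smooth_s0: np.ndarray
    max_abs_difference: float  # over event-time deciles, survival scale
    decile_times: np.ndarray
    band: Optional[BootstrapBand] = None
    band_coverage: Optional[float] = None  # share of decile points inside band


def compare_baselines(
    validation: SurvivalSample,
    fit,
    band: Optional[BootstrapBand] = None,
) -> BaselineComparison:
    """Overlay the derivation FP2 baseline on the validation baseline.

    The empirical validation baseline comes from the offset-constrained
    model ln h(t) = ln h0(t) + PI (no coefficient re-estimated) via the
    Breslow estimator; the summary statistic is the maximum absolute
    survival-scale difference over the validation event-time deciles that
    fall inside the fitted range.
    """
    H_emp = baseline_cumhaz(validation, PI_COL)
    emp = StepCurve(times=H_emp.times, values=np.exp(-H_emp.values), flavor="survival",
                    at_risk=H_emp.at_risk, n_events=H_emp.n_events)
    lo, hi = fit.time_range
    ev = validation.time[validation.event == 1]
    ev = ev[(ev >= lo) & (ev <= hi) & (ev > 0)]
    if ev.size == 0:
        raise DataError("no validation event times inside the fitted baseline range")
    deciles = np.percentile(ev, np.arange(10, 100, 10), method="linear")
    deciles = np.unique(np.clip(deciles, lo, hi))
    s_emp = emp.evaluate(deciles)
    s_fp = fit.evaluate_s0(deciles)
    max_diff = float(np.max(np.abs(s_emp - s_fp)))
    grid = np.linspace(max(lo, emp.times.min()), min(hi, emp.times.max()), 200)
    coverage = None
    if band is not None:
        lnH_emp = np.log(-np.log(np.clip(emp.evaluate(deciles), 1e-12, 1 - 1e-12)))
        band_lo = np.interp(deciles, band.times, band.lower)
        band_hi = np.interp(deciles, band.times, band.upper)
        H_at = np.exp(lnH_emp)
        coverage = float(np.mean((H_at >= band_lo) & (H_at <= band_hi)))
    return BaselineComparison(
        empirical=emp,
        smooth_times=grid,
        smooth_s0=fit.evaluate_s0(grid),
        max_abs_difference=max_diff,
        decile_times=deciles,
        band=band,
        band_coverage=coverage,
    )
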