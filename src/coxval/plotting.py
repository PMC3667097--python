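"""Validation figures: PI histogram, group KM, baseline fit, calibration.

All functions return a matplotlib Figure and never show or save anything
themselves; the report writer saves them as SVG.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .calibration_curves import BaselineComparison, group_mean_curves
from .cox_core import StepCurve, kaplan_meier
from .model_spec import GROUP_COL, SurvivalSample

__all__ = [
    "plot_pi_histogram",
    "plot_group_km",
    "plot_baseline_fit",
    "plot_observed_vs_predicted",
    "plot_pi_ecdf_by_group",
    "plot_baseline_comparison",
]


def _step(ax, curve: StepCurve, **kwargs):
    t = np.concatenate(([0.0], curve.times))
    v = np.concatenate(([curve.baseline_value], curve.values))
    ax.step(t, v, where="post", **kwargs)


def plot_pi_histogram(sample: SurvivalSample, grouping=None, label="validation"):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(sample.pi, bins=30, color="steelblue", alpha=0.8)
    if grouping is not None:
        for c in grouping.cutpoints:
            ax.axvline(c, color="k", ls="--", lw=0.8)
    ax.set_xlabel("Prognostic index (centered)")
    ax.set_ylabel("Subjects")
    ax.set_title(f"PI distribution, {label} data")
    fig.tight_layout()
    return fig


def plot_group_km(sample: SurvivalSample, time_unit="years"):
    fig, ax = plt.subplots(figsize=(6, 4))
    for lab, sub in sample.data.groupby(GROUP_COL, observed=True):
        km = kaplan_meier(
            SurvivalSample(sub.reset_index(drop=True), sample.time_col, sample.event_col)
        )
        _step(ax, km, label=str(lab))
    ax.set_xlabel(f"Time ({time_unit})")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="Risk group", fontsize=8)
    ax.set_title("Kaplan-Meier curves by risk group")
    fig.tight_layout()
    return fig


def plot_baseline_fit(baseline: StepCurve, fit, band=None, time_unit="years"):
    """Empirical baseline cumulative hazard with the FP2 fit and its band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    _step(ax, baseline, color="gray", lw=1, label="empirical")
    grid = np.linspace(fit.time_range[0], fit.time_range[1], 200)
    ax.plot(grid, np.exp(fit.evaluate_log_cumhaz(grid)), "k-", label="FP2 fit")
    if band is not None:
        ax.fill_between(band.times, band.lower, band.upper, color="0.8", alpha=0.6,
                        label="bootstrap 95% band")
    ax.set_xlabel(f"Time ({time_unit})")
    ax.set_ylabel("Baseline cumulative hazard")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_observed_vs_predicted(sample: SurvivalSample, fit, time_unit="years"):
    """Overlay jagged group KM curves with the smooth predicted mean curves."""
    fig, ax = plt.subplots(figsize=(6, 4))
    pred = group_mean_curves(sample, fit)
    colors = plt.cm.viridis(np.linspace(0, 0.9, len(pred)))
    for color, (lab, curve) in zip(colors, pred.items()):
        sub = sample.data[sample.data[GROUP_COL] == lab]
        km = kaplan_meier(
            SurvivalSample(sub.reset_index(drop=True), sample.time_col, sample.event_col)
        )
        _step(ax, km, color=color, lw=1, label=f"{lab} (observed)")
        ax.plot(curve.times, curve.values, color=color, ls="--", lw=1.5,
                label=f"{lab} (predicted)")
    ax.set_xlabel(f"Time ({time_unit})")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=6)
    ax.set_title("Observed vs predicted survival by risk group")
    fig.tight_layout()
    return fig


def plot_pi_ecdf_by_group(sample: SurvivalSample):
    fig, ax = plt.subplots(figsize=(6, 4))
    for lab, sub in sample.data.groupby(GROUP_COL, observed=True):
        x = np.sort(sub["_pi"].to_numpy())
        ax.step(x, np.arange(1, len(x) + 1) / len(x), where="post", label=str(lab))
    ax.set_xlabel("Prognostic index")
    ax.set_ylabel("Empirical c.d.f.")
    ax.legend(title="Risk group", fontsize=8)
    fig.tight_layout()
    return fig


def plot_baseline_comparison(comparison: BaselineComparison, time_unit="years"):
    """Transported smooth baseline vs the validation empirical baseline."""
    fig, ax = plt.subplots(figsize=(6, 4))
    if comparison.band is not None:
        surv = comparison.band.to_survival()
        ax.fill_between(surv["time"], surv["lower"], surv["upper"], color="0.85",
                        label="bootstrap 95% band")
    _step(ax, comparison.empirical, color="gray", lw=1, label="empirical (validation)")
    ax.plot(comparison.smooth_times, comparison.smooth_s0, "k-",
            label="FP2 (derivation)")
    ax.set_xlabel(f"Time ({time_unit})")
    ax.set_ylabel("Baseline survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
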