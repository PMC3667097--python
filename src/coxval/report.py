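"""Assemble the seven validation methods into a structured report.

The methods a validation study can run depend on the information level the
derivation publication provides:

* L1 — coefficients (the PI):  method 1 (calibration slope), method 2
  (misspecification / PH check), method 3 (discrimination measures).
* L2 — L1 plus risk-group definition:  methods 4-6 (group KM curves,
  between-group tests [deprecated], hazard ratios).
* L3 — L2 plus a baseline survival function:  method 7 (calibration of
  predicted survival probabilities).

A section appears only when its information level is satisfied; requesting
a calibration assessment without a baseline fit is refused by name.  The
report body is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .baseline_smooth import BaselineLookup, FP2BaselineFit, bootstrap_band
from .calibration_curves import (
    compare_baselines,
    group_hazard_ratios,
    observed_vs_predicted,
)
from .calibration_regression import calibration_slope, misspecification_test, ph_check
from .cox_core import LOGRANK_CAVEAT, logrank_test
from .discrimination import discrimination_report
from .exceptions import ConfigurationError
from .model_spec import (
    PublishedModel,
    RiskGrouping,
    SurvivalSample,
    assign_groups,
    compute_pi,
    truncate_followup,
)

__all__ = ["ValidationReport", "run_validation"]


def _fmt(x, nd=3):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{nd}f}"


@dataclass
class ValidationReport:
    provenance: dict
    sections: dict = field(default_factory=dict)  # name -> markdown str
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    figures: dict = field(default_factory=dict)  # name -> Figure
    information_level: str = "L1"

    def render(self) -> str:
        lines = ["# External validation report", ""]
        for k, v in self.provenance.items():
            lines.append(f"- {k}: {v}")
        lines.append(f"- information level: {self.information_level}")
        lines.append("")
        for name in sorted(self.sections):
            lines.append(self.sections[name])
            lines.append("")
        return "\n".join(lines)

    def write(self, outdir, figures: bool = False) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_path = outdir / "report.md"
        report_path.write_text(self.render())
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        if figures:
            for name, fig in self.figures.items():
                fig.savefig(outdir / f"{name}.svg")
        return report_path


def run_validation(
    model: PublishedModel,
    sample: SurvivalSample,
    grouping: Optional[RiskGrouping] = None,
    baseline: Optional[FP2BaselineFit | BaselineLookup] = None,
    timepoints: Sequence[float] = (2.0, 5.0),
    n_boot: int = 100,
    seed: int = 0,
    truncate: Optional[float] = None,
    include_logrank: bool = True,
    make_figures: bool = False,
    provenance: Optional[dict] = None,
) -> ValidationReport:
    """Run every validation method the supplied information level permits."""
    level = "L3" if baseline is not None else ("L2" if grouping is not None else "L1")
    if baseline is not None and grouping is None:
        raise ConfigurationError(
            "L3 input requires the risk grouping as well (L2): supply cutpoints"
        )
    prov = {
        "software": f"coxval {__version__}",
        "seed": seed,
        "n_subjects": len(sample),
        "timepoints": tuple(timepoints),
        "bootstrap_replicates": n_boot,
        "decisions": (
            "ties=efron; percentiles=linear interpolation (type 7); "
            "group intervals closed left/open right; baseline interpolation "
            "linear on ln H0"
        ),
    }
    if provenance:
        prov.update(provenance)

    if truncate is None and model.max_followup is not None:
        truncate = model.max_followup
    if truncate is not None:
        sample = truncate_followup(sample, truncate)
        prov["followup_truncated_at"] = truncate

    sample = compute_pi(model, sample)
    report = ValidationReport(provenance=prov, information_level=level)

    # Method 1: calibration slope
    sl = calibration_slope(sample)
    report.sections["method_1"] = (
        "## Method 1: Regression on the PI (L1)\n\n"
        f"Calibration slope {_fmt(sl.slope)} (SE {_fmt(sl.se)}); LR test of "
        f"slope = 1: chi2(1) = {_fmt(sl.lr_statistic, 2)}, P = {_fmt(sl.p_value, 3)}.\n"
        f"{sl.interpretation}.\n\n*{sl.caveat}*"
    )

    # Method 2: misspecification and PH
    transformed = model.transformed_columns(sample.data)
    work = sample.copy()
    cols = []
    for j, c in enumerate(transformed.columns):
        col = f"_z{j}"
        work.data[col] = transformed[c].to_numpy()
        cols.append(col)
    ms = misspecification_test(work, cols)
    ph = ph_check(sample)
    report.sections["method_2"] = (
        "## Method 2: Model misspecification / fit (L1)\n\n"
        f"Joint test of beta* = 0 ({ms.test.upper()}): chi2({ms.df}) = "
        f"{_fmt(ms.joint_statistic, 2)}, P = {_fmt(ms.p_value)}. "
        f"(Wald {_fmt(ms.wald_statistic, 2)}, LR {_fmt(ms.lr_statistic, 2)}.)\n\n"
        f"Proportional-hazards check (scaled Schoenfeld, {ph.transform} "
        f"transform): chi2({ph.df}) = {_fmt(ph.global_statistic, 2)}, "
        f"P = {_fmt(ph.p_value)}.\n\n*{ph.caveat}*"
    )
    report.tables["misspecification"] = ms.per_covariate.reset_index(names="term")

    # Method 3: discrimination
    disc = discrimination_report(sample)
    report.sections["method_3"] = (
        "## Method 3: Measures of discrimination (L1)\n\n"
        + disc.to_frame().to_markdown(index=False)
        + f"\n\nPI mean (SD): {_fmt(float(sample.pi.mean()), 2)} ({_fmt(disc.pi_sd, 2)})."
    )
    report.tables["discrimination"] = disc.to_frame()

    if grouping is not None:
        sample = assign_groups(sample, grouping)
        shares = sample.group.value_counts(normalize=True, sort=False)
        report.sections["method_4"] = (
            "## Method 4: Kaplan-Meier curves for risk groups (L2)\n\n"
            "Group shares: "
            + ", ".join(f"{lab} {100 * p:.1f}%" for lab, p in shares.items())
            + "\nSee the group KM figure; wide separation indicates preserved "
            "discrimination, agreement with the published curves rough calibration."
        )
        if include_logrank:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                lr = logrank_test(sample)
            report.sections["method_5"] = (
                "## Method 5: Logrank test between risk groups (L2) — deprecated\n\n"
                f"chi2({lr.df}) = {_fmt(lr.statistic, 2)}, P = {_fmt(lr.p_value)}.\n\n"
                f"*{LOGRANK_CAVEAT}*"
            )
        hr = group_hazard_ratios(sample)
        report.sections["method_6"] = (
            "## Method 6: Hazard ratios across risk groups (L2)\n\n"
            + hr.to_markdown(index=False)
        )
        report.tables["hazard_ratios"] = hr

    if baseline is not None:
        table = observed_vs_predicted(sample, baseline, timepoints=timepoints)
        comparison = compare_baselines(sample, baseline)
        report.sections["method_7"] = (
            "## Method 7: Calibration via the baseline survival function (L3)\n\n"
            + table.to_frame().to_markdown(index=False)
            + "\n\nMax |observed - predicted| baseline survival over event-time "
            f"deciles: {_fmt(comparison.max_abs_difference)}."
        )
        report.tables["calibration"] = table.to_frame()

    if make_figures:
        from . import plotting

        report.figures["pi_histogram"] = plotting.plot_pi_histogram(sample, grouping)
        if grouping is not None:
            report.figures["group_km"] = plotting.plot_group_km(sample, model.time_unit)
            report.figures["pi_ecdf"] = plotting.plot_pi_ecdf_by_group(sample)
        if baseline is not None:
            report.figures["observed_vs_predicted"] = plotting.plot_observed_vs_predicted(
                sample, baseline, model.time_unit
            )
            band = bootstrap_band(sample, n_boot=n_boot, seed=seed)
            comparison = compare_baselines(sample, baseline, band=band)
            report.figures["baseline_comparison"] = plotting.plot_baseline_comparison(
                comparison, model.time_unit
            )
    return report
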