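# coxval

External validation of published Cox proportional-hazards prognostic
models.

A prognostic model should not enter clinical practice until its
discrimination and calibration have been demonstrated on data independent
of those used to build it.  For logistic models this is routine; for Cox
models it is harder, because a Cox model predicts only *relative* hazards —
the baseline hazard is never estimated by the partial likelihood, so
absolute survival probabilities cannot be checked unless the derivation
study also reports a baseline survival function.  `coxval` implements a
complete toolkit for this situation, organised by the level of information
the publication provides:

* **L1 — the coefficients.**  Rebuild the prognostic index
  PI = Σ β̂ₖ·fₖ(xₖ) − c (the linear predictor, centered at the derivation
  mean) *without refitting anything*, then assess:
  - the **calibration slope**: the Cox coefficient on the PI re-estimated
    in the validation data (1 = effect strength preserved, < 1 attenuated),
    with a likelihood-ratio test of slope = 1;
  - **misspecification**: Cox regression on the model's own covariates with
    the PI as an offset, ln h(t) = ln h₀(t) + x′β* + PI, and a joint test
    of β* = 0; plus a Grambsch–Therneau scaled-Schoenfeld check of
    proportional hazards;
  - **discrimination**: Harrell's c, Gönen & Heller's K (outcome-free,
    censoring-robust), the Royston–Sauerbrei D statistic (Cox coefficient
    on rankits scaled by κ = √(8/π) ≈ 1.596), and the explained-variation
    measures R²_D = (D²/κ²)/(σ² + D²/κ²) and R²_PM = s²/(σ² + s²) with
    σ² = π²/6 ≈ 1.645.
* **L2 — plus risk groups.**  Cut the PI at Cox's minimal-information-loss
  centiles (16/50/84 for four groups), then compare Kaplan–Meier curves,
  between-group hazard ratios, and (flagged as deprecated) between-group
  logrank tests.
* **L3 — plus the baseline survival function.**  The package both
  *produces* the transportable baseline on the derivation side — an FP2
  fractional polynomial ln H₀(t) ≈ γ₀ + γ₁ t^p₁ + γ₂ t^p₂ fitted by OLS
  over event times with powers from {−2, −1, −½, 0, ½, 1, 2, 3}, with a
  bootstrap confidence band — and *consumes* it on the validation side:
  individual predictions S(t; PI) = S₀(t)^exp(PI), group-averaged predicted
  curves against group Kaplan–Meier curves, and a direct comparison of the
  transported baseline with the validation data's offset-constrained
  empirical baseline.

A seeded synthetic-data module generates derivation/validation pairs with
known proportional-hazards structure and controllable miscalibration
(slope, baseline scale, case mix, non-PH), so every method is testable
without downloading any data.

## Worked example

Simulate a world whose validation arm attenuates the linear predictor by a
factor 0.8, publish the derivation model, and validate it:

```python
from coxval import (SimulationScenario, generate, apparent_scenario,
                    compute_pi, assign_groups, calibration_slope,
                    discrimination_report, observed_vs_predicted)

scn = SimulationScenario(n_subjects=1500, slope_multiplier=0.8, seed=42)
derivation, validation = generate(scn)
bundle = apparent_scenario(derivation)       # L1 + L2 + L3 "publication"

v = compute_pi(bundle.model, validation)
sl = calibration_slope(v)
print(f"slope {sl.slope:.2f} (SE {sl.se:.2f}), P(slope=1) = {sl.p_value:.3f}")
print(discrimination_report(v).to_frame().round(3).to_string(index=False))

v = assign_groups(v, bundle.grouping)
tab = observed_vs_predicted(v, bundle.baseline_fit, timepoints=(2.0, 5.0))
print(tab.to_frame().round(3).to_string(index=False))
```

prints

```
slope 0.79 (SE 0.05), P(slope=1) = 0.000
                    measure  estimate    se
            Harrell c-index     0.650 0.008
           Gonen & Heller K     0.679 0.003
                D statistic     0.912 0.053
 Explained variation (R2_D)     0.166 0.016
Explained variation (R2_PM)     0.240   NaN
             PI spread (SD)     0.722   NaN
      group  time   n  events  observed  observed_se  predicted  difference
       Good   2.0 229     107     0.895        0.020      0.908      -0.013
       Good   5.0 229     107     0.677        0.031      0.740      -0.063
...
```

The slope estimate 0.79 recovers the generating attenuation of 0.8 and the
LR test correctly rejects slope = 1; the observed-vs-predicted table shows
the mild risk-group miscalibration that attenuation induces (the model
over-separates: it under-predicts survival in the highest-risk group and
over-predicts in the lowest).

## Command line

```sh
coxval simulate examples/scenario.yaml --out-prefix /tmp/sim
coxval validate examples/model.yaml /tmp/sim_validation.csv \
    --groups examples/risk_groups.yaml --baseline examples/baseline.yaml \
    --out /tmp/report --seed 1
```

`validate` runs exactly the methods the supplied information level permits
(model only → methods 1–3; with `--groups` → 4–6; with `--baseline` → 7)
and writes a markdown report, CSV tables and SVG figures.  Other
subcommands (`pi`, `discrim`, `calslope`, `misspec`, `baseline-fit`,
`calibrate`) expose the individual steps.  Exit codes distinguish
configuration (2), data (3) and numerical (4) errors.

Model specifications, risk groupings, baseline fits and simulation
scenarios are all plain YAML and round-trip losslessly; a baseline
published only as a (time, S₀) look-up table is supported via CSV.  Data
are read from delimited text or Stata `.dta` files.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch on freshly simulated data, the apparent-calibration
identity: fitting a Cox model, computing its linear predictor, and
re-fitting a Cox model with that linear predictor as the sole covariate in
the same dataset, reporting the resulting coefficient.

See `docs/methods.md` for the statistical details, numerical choices, and
known limitations.
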