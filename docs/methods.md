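# Methods

## The setting

A Cox proportional-hazards model h(t | x) = h₀(t) exp(PI) is developed on
one dataset and published as a set of regression coefficients on (possibly
transformed) covariates.  A validation study has independent patient-level
data and must judge whether the model's discrimination and calibration
survive transport.  The central discipline is that nothing is refitted:
the prognostic index PI is computed in the validation data exactly as
published, including every covariate transformation, rescaling, and the
centering constant (the derivation mean of the linear predictor, so that
PI = 0 means "average derivation risk").

What can be checked depends on what was published: coefficients only (L1),
coefficients plus risk-group definition (L2), or those plus a baseline
survival function (L3).  Absolute survival predictions — and therefore
strict calibration — need L3.

## Model representation

A published model is a list of terms (covariate, transform, coefficient).
The transform vocabulary {identity, power, power×log, indicator} with an
explicit positive pre-scaling divisor covers fractional-polynomial models
(e.g. a term in (age/100)³·ln(age/100)) and dummy coding; spline-based
models are handled by precomputing the basis columns upstream.  Power and
log transforms refuse non-positive post-scaling values, and missing
covariate values are an error — silent imputation would corrupt a
validation exercise.  The scale divisors must be stated explicitly: a
transformed coefficient is meaningless without them, and published FP
models often omit them (in which case exact reproduction of the PI is
impossible until they are recovered empirically; this is a reporting
defect the toolkit cannot repair).

## Cox machinery

All downstream methods rest on an in-package partial-likelihood fitter
(Newton iterations with step-halving; convergence when the relative
log-likelihood change falls below 1e-9; maximum 100 iterations).  Ties are
handled by Efron's method by default (better small-sample behaviour),
Breslow selectable; the linear predictor is shifted by its maximum before
exponentiation so risk-set sums cannot overflow.  An *offset* — a linear
term with coefficient fixed at exactly 1 — holds the published PI fixed in
the misspecification test and in the empirical baseline.  The
zero-covariate case (offset only) returns the log-likelihood needed for
likelihood-ratio tests.  Monotone likelihood (separation) is reported as a
convergence error rather than silently huge coefficients (diagnosed by
non-convergence or a coefficient beyond ±20 on the log-hazard scale).
Coefficients, standard errors, Schoenfeld residuals and the
proportional-hazards test were cross-checked against lifelines in the test
suite; lifelines cannot replace the implementation because its Cox fitter
has no offset.

Nonparametric estimators: Kaplan–Meier with Greenwood standard errors
(subjects censored at an event time count as at risk at that time); the
Breslow baseline cumulative hazard H₀(t) = Σ d_k / Σ_risk exp(PI_j) with
the PI as fixed offset, which reduces to Nelson–Aalen when all PI = 0.
The displayed baseline survival is exp(−H₀) for consistency with the
smoothed baseline; a product-limit ("Kaplan–Meier-like") alternative is
selectable, and the two agree to < 0.01 while risk sets exceed ~20.

## Discrimination

* **Harrell's c** counts concordant pairs among evaluable pairs (the
  shorter time an event; pairs tied on time evaluable only when exactly
  one member is an event; PI ties score ½).  The standard error is the
  asymptotic U-statistic projection variance of the ratio of the
  concordance and evaluability U-statistics.
* **Gönen & Heller's K** is the pairwise mean of expit(|PI_i − PI_j|) —
  the model-based probability that the higher-risk member of a pair fails
  first.  It never touches the outcome, so it is immune to the upward
  drift censoring induces in c (that drift arises when conditional
  discrimination decays over follow-up, because censoring overweights
  early pairs; under exact PH the pair-level concordance is time-constant
  and c is censoring-stable — the test suite demonstrates both regimes).
  Tied PIs contribute ½, so a constant PI gives exactly 0.5.  The analytic
  SE is the U-statistic projection variance with the published
  coefficients treated as fixed — exactly the external-validation
  situation; a subject bootstrap is selectable.
* **D** is the Cox coefficient on the PI's rankits divided by
  κ = √(8/π): the log hazard ratio between the prognostic halves of an
  idealised Normal PI.  Rankits use Blom's approximation
  Φ⁻¹((i−3/8)/(n+1/4)), averaged within PI ties; the difference from exact
  expected order statistics is O(10⁻³) at validation sample sizes.
* **R²_D = (D²/κ²)/(σ² + D²/κ²)** and **R²_PM = s²/(σ² + s²)** with
  σ² = π²/6, the residual variance a PH model implies on the log
  relative-hazard scale, and s the PI standard deviation.

c, D and R²_D depend on the PI only through its ranks; K is
location-invariant but not rank-invariant; R²_PM uses no outcome at all.
All of these shrink when the validation case mix is narrower than the
derivation case mix — a smaller PI spread is a property of the population,
not a failure of the model, and should be read alongside the calibration
slope.

## Fit and calibration regression

The calibration slope is the Cox coefficient on the PI alone; the LR test
of slope = 1 compares that fit with the PI-as-offset model.  Its P-value
can be anti-conservative because derivation-side coefficient uncertainty
is ignored (by design: the derivation covariance matrix is essentially
never published).  The misspecification test fits the model's own
transformed covariates with the PI offset; the joint test is LR by default
(Wald selectable and always reported alongside), on as many degrees of
freedom as covariates; per-covariate statistics are reported but flagged
secondary.  The PH check is the Grambsch–Therneau scaled-Schoenfeld
correlation test with the Kaplan–Meier time transform by default (identity
and rank selectable).  A PH breach need not destroy discrimination but
calls for scrutiny of calibration over time.

## The transportable baseline (L3)

ln H₀(t) is approximated by a degree-2 fractional polynomial over the
observed event times, by unweighted OLS (weighting by risk-set size is
deliberately not the default), exhaustively searching all 36 power pairs
from {−2, −1, −½, 0, ½, 1, 2, 3} (t⁰ ≡ ln t; repeated powers (p, p) give
t^p and t^p ln t).  The winning pair minimises the residual sum of
squares; the fit records r², the valid time range, and a monotonicity
warning if the fitted curve decreases anywhere in range.  Three
coefficients and a power pair then transport the entire baseline:
S₀(t) = exp(−exp(ln H₀(t))).

Uncertainty: resample derivation subjects with replacement (default
B = 100, seed required and logged); per replicate fit a Cox model to the
PI, predict the Breslow baseline, refit the best FP2, and evaluate on a
grid of 100 equally spaced times between the first and last event time;
the band is mean ± 1.96 SD on the log cumulative-hazard scale,
back-transformed.  Replicates without events are redrawn and counted.

Evaluation outside the fitted time range is refused by default — the
reason validation follow-up is truncated at the derivation maximum is
precisely to avoid extrapolating the baseline.  A baseline published only
as a (time, S₀) look-up table is supported; interpolation is linear on the
ln H₀ scale, which preserves positivity and monotonicity.

## Risk-group calibration

Groups are formed by cutting the PI at Cox's minimal-information-loss
centiles: 16/50/84 for four groups (mean and mean ± 1 SD on a Normal
scale); built-in tables cover 2–5 groups, and arbitrary centile lists are
accepted.  Percentiles use linear interpolation of the empirical
distribution (type 7); intervals are closed on the left and open on the
right, so a PI exactly at a cutpoint goes to the higher-risk group.  (The
percentile definition and the boundary convention are both conventions the
literature leaves open; they are fixed and logged in every report.)

Predicted group curves average the member-level predictions
S₀(t)^exp(PI_i) pointwise — averaging survival probabilities, not PIs;
plugging the group-mean PI into S₀^exp(·) differs by Jensen's inequality
and is available only as a labelled diagnostic.  Observed curves are group
Kaplan–Meier estimates; the observed-vs-predicted table (default time
points 2 and 5 years, configurable) carries Greenwood standard errors and
flags time points beyond a group's follow-up.  Between-group hazard ratios
(dummy-coded Cox, lowest-risk group as reference) are a sensible
discrimination check; between-group logrank tests are implemented because
analysts use them but always carry a deprecation notice — they test the
null hypothesis that the risk groups have identical survival, which is not
a measure of discrimination.

Finally, the transported baseline is compared directly with the validation
data's own empirical baseline, obtained from the offset-constrained model
ln h(t) = ln h₀(t) + PI.  The summary statistic is the maximum absolute
survival-scale difference over the validation event-time deciles; a large
difference signals fundamental miscalibration.

## Synthetic data: what the generator emulates, and what not

Event times are Weibull-PH by inversion, T = (−ln U / (λ e^lp))^(1/ν),
with defaults chosen to resemble a node-positive breast-cancer cohort on a
yearly scale: n = 1000, λ = 0.10, ν = 1.2 (≈ 60 % failures by the 7-year
administrative horizon), three covariates (two standard Normal, one binary
with prevalence 0.4) with log hazard ratios (0.5, −0.3, 0.7), giving a PI
spread of ≈ 0.7, comparable to real prognostic models.  The validation arm
can attenuate the linear predictor (true calibration slope γ), rescale the
baseline hazard (ρ), shrink the Normal covariate SDs (case mix), and make
one coefficient time-varying as β(1 + δ ln t) — which keeps the inversion
closed-form because the hazard stays Weibull with subject-specific shape
ν + δβx (required positive).  A piecewise-exponential baseline is included
for non-smooth hazards.

Not emulated: the joint covariate dependence, measurement heterogeneity,
and informative censoring of real registries.  A green self-consistency
test therefore establishes internal correctness of the estimators under
the stated model, not agreement with any particular published cohort.

## Numerical and design notes

* Monte-Carlo test sizes follow the stated acceptance design (slope
  recovery: 200 replicates of n = 2000 per γ; type-I error: 400
  replicates; case mix: 100 replicates).  Where the design left n open,
  n = 1000 per replicate was fixed a priori as a realistic
  validation-study size within the CI budget.
* The joint misspecification statistic is reported both as LR and Wald;
  publications rarely say which they used, and the two can differ at
  moderate sample sizes.
* Whether published empirical baselines are product-limit or
  exp(−Breslow) is usually unstated; both are provided and agree closely
  away from small risk sets.
* Reports are deterministic given the seed; every convention (ties
  method, percentile definition, boundary rule, interpolation scale) is
  logged in the report provenance so any table cell can be reproduced by
  calling the underlying function.

## Limitations

* Stratified and time-dependent-effect Cox models are out of scope: the
  scheme requires a single time-fixed PI and a unique baseline.
* Model updating/recalibration after a failed validation is out of scope;
  the toolkit diagnoses, it does not repair.
* Missing covariate values are an error, never imputed.
* Exact reproduction of a published PI is impossible when the publication
  omits covariate rescalings; the config format forces scales to be
  explicit for models specified here, but cannot recover unstated ones.
* Calibration at the individual level (without risk groups) is not
  attempted; grouping is used as a technical device for comparing observed
  with predicted survival.
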