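# Methods

## The virtual-controls design

A *virtual control* is a model-predicted counterfactual: for a patient who
received an intervention in a single-arm study, it is the outcome a
prognostic model — fitted beforehand to untreated (or standard-of-care)
subjects — predicts they would have had without it. The treatment effect is
then the systematic discrepancy between observed outcomes and these
per-patient predictions. The design trades the randomized comparator for a
modelling assumption: that the prognostic model transports from the
untreated training population to the people who enrol in the single-arm
study. The package implements the full workflow (fit → validate → pool →
predict → estimate → per-patient report) and a simulation laboratory for
interrogating exactly when that assumption buys a correct decision.

## Prognostic models

Two families, matching the two outcome scales:

* continuous outcome — ordinary least squares,
  `y = β₀ + xᵀβ + ε`, precision indexed by R²;
* binary outcome — logistic regression on the same linear predictor,
  precision summarised by the Brier score and mean event rate.

Fits go through statsmodels (`OLS`, `Logit`). The logistic MLE is capped at
100 iterations with tolerance 1e-8 on the log-likelihood change; detected
separation or non-convergence raises an error rather than returning
divergent coefficients. Rank-deficient designs are rejected with the
collinear columns named. Rows with missing covariates are excluded from
fitting and reported — never imputed, since silent imputation would change
the estimator's contract. Categorical covariates use reference-level dummy
coding (first listed level is the reference).

Each fitted model is exported as a versioned coefficient set (JSON) that
carries, besides intercept and coefficients, the covariate schema with the
observed **support intervals** (training min/max of each continuous
covariate), the training n, the precision index, and the coefficient
covariance matrix. Support intervals drive extrapolation flags: any
prediction for a subject outside the training range is marked, counted, and
surfaced in every downstream estimate and patient report. Pooling new
untreated cohorts refits on the concatenated data, increments the version
and widens the supports; variables present only in newer cohorts extend the
schema, and rows from cohorts that never measured them are treated as
missing there (hence excluded from the extended fit) — the simplest contract
consistent with promoting yesterday's confounder to tomorrow's predictor.

Calibration is reported as the regression of observed on predicted (slope 1,
intercept 0 is perfect); for the logistic family the calibration regression
is on the linear predictor. A zero-variance prediction vector makes the
slope undefined; it is reported as an explicit `None` sentinel, not an
exception.

## Effect estimation

**Continuous outcomes.** Per-subject *added-value scores*
`sᵢ = yᵢ − ŷᵢ`; the mean score estimates the additive effect τ and the
mean/SD ratio is reported as the standardized effect size. Three
uncertainty modes:

* `plugin` — predictions treated as fixed; one-sample t interval and test
  on the scores. This matches how the published case studies analysed
  their data, but it is anti-conservative when the prognostic model is
  itself estimated: the shared coefficient error correlates the scores, and
  at n_train = 500 / n_treated = 100 the naive t test's true size is about
  0.07 rather than 0.05.
* `analytic-propagated` (default whenever the coefficient covariance is
  stored, which our fits always do) — the variance of the mean score adds
  the quadratic form `āᵀ Cov(β̂) ā` of the mean covariate vector in the
  training covariance. This restores the nominal level (verified by the
  calibration tests at 2000 replicates) at negligible cost.
* `bootstrap-propagated` — each replicate resamples the training cohort
  (refit) *and* the treated cohort (re-estimate); percentile interval over
  replicate estimates. Resampling both cohorts is essential: training-only
  resampling would omit the dominant single-arm sampling noise and produce
  intervals narrower than the plugin ones. Failed refits are dropped and
  counted; more than 10% failures aborts.

**Binary outcomes.** Risk difference = observed event proportion − mean
predicted probability (risk ratio alongside). The test compares the
observed event count with the sum of predicted probabilities under the
independent-Bernoulli null — a Poisson-binomial distribution, since the
predictions are per-subject by construction. It is evaluated exactly (pmf
by convolution, two-sided p = 2·min(tails) capped at 1) for n ≤ 20 and by
the continuity-corrected normal approximation with variance Σpᵢ(1−pᵢ)
above. The CI on the risk difference is the normal approximation with the
observed-proportion variance; a subject-resampling bootstrap CI is
available alongside.

## The synthetic-cohort generator

The generator emulates the statistical structure the design assumes and the
bias mechanisms that threaten it:

    y = β₀ + xᵀβ + γ·u + ε,   ε ~ N(0, σ²),   u ~ N(0, 1) hidden

with x standard normal (optionally exchangeably correlated, optional binary
covariates), τ added for treated subjects (log-odds shift for binary
outcomes), and three enrolment mechanisms: none (training cohorts and
unselected single arms), self-selection logistic in an observed covariate,
and self-selection logistic in the hidden confounder u — the "unmeasured
motivation" scenario. Randomized cohorts add a preference fraction π and a
demoralization penalty d subtracted from the outcome of every participant
assigned against their preference.

Key closed forms, used both to parameterise scenarios and as test oracles:

* true prognostic R² = Var(xᵀβ) / (Var(xᵀβ) + γ² + σ²); scenarios can be
  specified by target R², with σ back-solved (infeasible targets, where γ²
  alone exceeds the noise budget, are rejected);
* expected bias of the virtual-control estimator under hidden selection =
  γ · E[u | opt-in], with E[u | opt-in] computed by deterministic quadrature
  of the logistic-weighted normal density (exact to quadrature tolerance —
  no Monte Carlo);
* under 1:1 randomization with preference π, the expected fraction of the
  preferred-treatment arm pleased with its assignment is π, and with
  majority preference for treatment the demoralized RCT's effect estimate
  is biased upward by d·(2π − 1)·(fraction mismatched asymmetry) — for
  π = 0.8 and d = 0.5, +0.30.

Defaults describe a moderately prognostic setting chosen once: three
continuous predictors with β = (0.5, 0.4, 0.3) (linear-predictor variance
0.5), σ = 0.5774 giving R² = 0.60, no treatment effect, no confounding, no
selection, balanced preference, no demoralization; n_train = 500,
n_treated = 100, 100 per randomized arm. The demoralization magnitude has
no empirical anchor; scenario values used in tests (d = 0.5 with 80/20
preference) are illustrative. What the generator does **not** emulate:
real covariate distributions and measurement error, non-linear or
interaction effects, time-to-event outcomes, drift between training and
enrolment periods, and informative missingness. Passing tests therefore
certify the estimator's behaviour *under its own assumptions*, not
transportability to any particular clinical data source.

## Operating characteristics

`run_cell` evaluates one (scenario, design) cell: for the virtual-control
design each replicate regenerates training data, refits, regenerates the
single arm and re-estimates; for the randomized design it generates a
two-arm cohort and applies the standard two-sample comparison (Welch t /
pooled two-proportion z). Aggregates: bias, RMSE, empirical coverage of the
true τ, and the rejection rate of the two-sided α = 0.05 test against zero
(the declared "correct decision" rule; configurable), each with its
binomial or empirical Monte-Carlo standard error. Replicate r of a cell
seeded with s draws from `default_rng([s, r, k])`, k indexing the stream —
every cell is independently reproducible. Replicates raising estimator
errors are recorded and excluded; a cell with more than 5% failures is
flagged invalid.

`r2_sweep` back-solves σ across a grid of target R² values and reports
power per cell, a monotonicity diagnostic (non-decreasing within twice the
combined MC error), and the smallest grid R² reaching a power threshold —
the operational answer to "how accurate does prediction have to be".

`power_two_proportion` gives the power of the two-sided pooled z-test
comparing two proportions: exactly, by enumerating the joint binomial grid
(tails truncated below 1e-12 mass, grids up to 4e6 cells — this covers both
small trials and rare events in very large ones), or by the standard normal
approximation otherwise. The rare-event worked example (excess rate 1 per
100,000, 15,000 per arm) lands deep in the enumerable regime and yields
power ≈ 2e-5.

## Per-patient reports

`patient_report` is a pure function of (models, covariates): point
predictions from the untreated and treated coefficient sets, intervals from
the linear-predictor variance (on the logit scale for the logistic family,
then inverse-transformed), and extrapolation warnings per model. When no
treated-subjects model exists yet, the report optionally degrades to
shifting the untreated prediction by a cohort-level effect estimate — this
is tagged `effect-shift-arithmetic` and never silently presented as an
individualized model, because on the probability scale a constant log-odds
benefit individualizes (the with/without difference genuinely varies across
patients) and a constant shift would misrepresent that. Both interval forms
(analytic and bootstrap-propagated cohort CIs) are emitted where available;
neither is privileged.

## Numerical and design choices

* File formats: cohorts as UTF-8 comma-delimited text with header;
  coefficient sets as JSON with an explicit schema block; scenarios and run
  configs as YAML. All machine-readable outputs have sorted keys for
  diffability.
* Treated/untreated coded 1/0; the outcome scale is declared in
  configuration, never inferred from the data.
* Confidence level defaults to 0.95, two-sided throughout; a single integer
  seed controls all resampling and is recorded in stochastic outputs.
* Degenerate inputs: zero-variance added-value scores report p = 1 (point
  0) or p = 0 with a `degenerate-zero-variance` tag; undefined calibration
  slopes are `None`; accrual failure (selection so extreme that fewer than
  n_treated subjects opt in within 100·n_treated draws) raises a dedicated
  error.
* Monte-Carlo problem sizes in the test suite and acceptance script (2000
  replicates for calibration, 1000 for the bias oracle, 400–600 for design
  comparisons and the R² sweep) were chosen to keep each check's MC
  standard error a few times smaller than the effect it measures while the
  whole suite stays desk-scale on a single CPU.

## Known limitations

* Only linear and logistic families; no survival outcomes, regularization,
  splines or machine-learned predictors — the coefficient-set artifact is
  deliberately the simplest transportable form, with the family field
  extensible.
* The hidden confounder is a single standard-normal variable entering both
  selection and outcome; real confounding is richer.
* No multiplicity adjustment across outcomes and no time-varying
  treatments.
* The design-comparison verdicts depend on the generator's assumptions
  above; they quantify relative robustness of the two designs to the
  modelled mechanisms, not an absolute ranking.
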