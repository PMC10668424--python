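# Methods

This note documents the statistical procedures implemented in `ovarisk`,
the defaults chosen where a design was genuinely open, and what the
synthetic-data experiments can and cannot demonstrate.

## Problem setting

A patient with an adnexal mass is assigned estimated probabilities for five
histological outcomes: benign, borderline, stage I primary invasive, stage
II–IV primary invasive, and secondary metastatic. The four malignant types
need different management, which is why the problem is multiclass rather
than benign/malignant, and why the binary risk of any malignancy is defined
as 1 − p(benign). Data come from multiple centers (gynecological oncology
referral centers and general ultrasound units), so every population-level
performance statistic is treated as a center-level quantity to be pooled by
meta-analysis rather than a single-sample estimate.

## Synthetic multicenter cohort generator

The generator emulates the *structure* the analysis assumes, not any real
joint distribution:

* **Outcome mix.** Global prevalences default to
  (0.62, 0.08, 0.07, 0.18, 0.05). Center-level prevalence vectors are drawn
  from a Dirichlet centered on tilted versions of the global vector
  (concentration 80): oncology centers have their malignant mass scaled by
  1.3 and non-oncology centers are compensated so the global expectation is
  preserved. Between-center variation is what makes the meta-analysis layer
  meaningful; the concentration is configurable.
* **Predictors, per class.** Age ~ Normal (means rising 44→58 years from
  benign to stage II–IV, SD 14); CA125 ~ log-normal (median 14 U/mL benign
  to 300 U/mL stage II–IV); lesion diameter ~ log-normal; proportion of
  solid tissue ~ zero-inflated Beta (52% of benign tumors have no solid
  component); binaries and the papillation category are class-specific
  Bernoulli/categorical. Parameters were calibrated once against published
  validation-cohort descriptives (median age 49, median CA125 25 U/mL,
  median diameter 71 mm, ascites 10%, shadows 14%) and are config, not code.
  The fidelity test asserts median age within ±3 years, median CA125 in
  [20, 32] U/mL and class proportions within 2.5 points at n = 10,000.
* **Known-truth mode.** `generate_from_latent_mlr` draws predictors from the
  class-mixture marginals and then draws the outcome from a softmax of a
  user-supplied (intercept + 9 features) × 4 coefficient matrix with benign
  as reference, returning each patient's true probability vector. This gives
  a closed-form oracle for parameter-recovery and PDI-consistency tests. The
  default coefficient matrix encodes clinically sensible directions; its
  intercepts were calibrated once by simulation to reproduce the default
  outcome mix.
* **CA125 missingness.** The probability of being *measured* is logistic in
  a centered suspicion score (prop_solid + ascites + papillation score / 4)
  with slope 2 by default; the intercept is solved numerically so expected
  missingness equals the requested rate (default 30%). Slope 0 gives MCAR;
  positive slopes give the clinically observed pattern that suspicious
  tumors are measured more often (missingness concentrated among benign
  tumors, i.e. MAR given predictors).

What the generator does **not** reproduce: real correlations among
predictors within class beyond those induced by class membership, ultrasound
measurement error, center-specific predictor shifts, or label noise in
histology. Passing tests on synthetic data therefore demonstrate the
correctness and statistical behavior of the *procedures*, not clinical
performance claims.

## Multiple imputation

CA125 is the only incomplete variable by design. Imputation is Bayesian
predictive mean matching (type 1, donor pool 5) on log CA125, regressed on
the eight other predictors plus the outcome class (outcome-inclusive
imputation is standard when the variable feeds a prediction model; the log
transform handles the right skew). Each of m imputations draws the
regression parameters from their posterior and matches each missing cell to
one of the five observed rows with the closest predicted mean. Default
m = 10; the scaled-down pipeline config uses m = 2. Development and
validation cohorts are always imputed separately. Models are trained on each
completed development dataset (hyperparameters tuned once, on the first) and
validation predictions are averaged over all development × validation
imputation pairs before evaluation — the simplest defensible combination
rule when per-patient probabilities, not scalar statistics, are the object
of interest. Scalar statistics can alternatively be pooled by Rubin's rules
(`pool_across_imputations`).

## Model zoo

All six algorithms consume the same nine predictors (eight in the
without-CA125 variant) and emit five-class probabilities:

| algorithm | implementation | feature handling |
|---|---|---|
| mlr | statsmodels MNLogit (full ML) | restricted cubic splines (3 knots at the 10/50/90th percentiles) on age, log CA125, prop. solid, diameter; ordinal papillation score |
| ridge_mlr | scikit-learn LogisticRegression (L2) | same spline design, standardized; all non-intercept coefficients penalized |
| rf | RandomForestClassifier | raw predictors, papillations one-hot |
| xgboost | XGBClassifier (multi:softprob) | raw predictors, papillations one-hot |
| nn | MLPClassifier, one hidden layer | raw predictors, ordinal papillations, standardized |
| svm | SVC (RBF, probability outputs) | raw predictors, ordinal papillations, standardized |

Choices worth flagging:

* Standard MLR is fitted with statsmodels rather than scikit-learn so that
  coefficient standard errors are available; the parameter-recovery test
  checks that ~95% of generator coefficients land within 2 SE (with 40
  coefficients, demanding *all* within 2 SE would fail ~84% of the time for
  a perfectly specified model). Newton optimization can diverge to NaN while
  reporting convergence, so the fit is accepted only with finite parameters
  and log-likelihood, with L-BFGS/BFGS fallbacks.
* SVM probabilities use libsvm's per-pair Platt scaling combined by pairwise
  coupling (`SVC(probability=True)`) — the standard route from margins to
  multiclass probabilities.
* Tuning maximizes the mean out-of-fold multinomial log-likelihood over a
  stratified, seeded 10-fold split (a proper scoring rule, consistent with
  the calibration emphasis). If the smallest class has fewer members than
  folds, the fold count drops to that size with a logged warning. XGBoost
  early-stops on each fold's held-out data (patience 50, cap 500 rounds);
  the final model uses the mean best iteration. The full tuning record
  (every candidate, per-fold log-likelihoods) is kept on the model spec.
* Two grid presets ship: `DEFAULT_GRIDS` (ridge λ ∈ 10^−4…10^4, 25 points;
  RF mtry × min-node 12 candidates; XGBoost 24; NN 12; SVM 63) and
  `SMALL_GRIDS` (2–3 candidates per algorithm) used by the built-in
  scaled-down experiment config (development n = 1,500, validation n = 800,
  5 centers, m = 2); both are config-overridable. Results in this package's
  tests use the small preset; grid width affects tuning quality, not the
  correctness of any metric.
* No random intercepts by center are used in any model: they do not
  generalize across the six algorithm families, so all models see the
  center-type indicator only.

## Discrimination

PDI uses fractional tie credit: within a 5-tuple (one patient per class),
the class-k patient scores 1 if strictly largest on p_k, 1/m if tied among
m patients including itself, else 0. This makes the uninformative-model
value exactly 0.2 and the perfect-model value exactly 1. The
`sorted_exact` estimator computes the exact value by per-class rank
counting: for each class-k patient, counts of strictly-smaller and tied
values in every other class are combined through the generating polynomial
∏_j (a_j + t_j·u), whose coefficients give the number of tuples with s tied
classes, weighted 1/(1+s). Exhaustive enumeration (the oracle) is used
automatically below 2,000 tuples and available explicitly up to 10^6; a
seeded Monte-Carlo estimator with standard error is kept for cross-checks.
Pairwise c-statistics apply the Mann–Whitney convention (ties 1/2) to the
conditional risk p_l/(p_k+p_l); a zero-sum pair (p_k = p_l = 0) maps to the
no-information value 0.5 rather than dropping the patient, keeping n fixed.

## Calibration

Curves are local-linear lowess smooths (span 0.75, no robustness
iterations — appropriate for 0/1 responses) of the one-vs-rest event
indicator on the predicted probability, evaluated on a 101-point grid over
the observed prediction range and clipped to [0, 1]. Center-specific curves
(computed for centers with ≥ 20 patients and both outcome levels; smaller
centers are logged and contribute only to pooled evaluation) are averaged
pointwise with √n_c weights on grid points covered by at least two centers.
The rescaled ECI divides the mean squared prediction–curve distance by the
mean squared distance of predictions from the overall event rate — the
unique simple scaling that gives exactly 0 on the diagonal and exactly 1 on
the horizontal line; values above 1 (worse than horizontal) are possible
and reported as-is. ECI is evaluated against the pooled (center-averaged)
curve using all patients; predictions outside the curve's range use the
boundary value.

## Clinical utility

Net Benefit at threshold t counts referrals: NB = TP/n − (FP/n)·t/(1−t),
with "refer" defined by risk ≥ t (closed at the threshold). Decision curves
span t = 0.05–0.40 in 1-point steps with the headline at t = 0.10, the
consensus referral threshold. Referrals avoided relative to treat-all equals
(NB_model − NB_all)(1−t)/t. Center-specific NB values are pooled by the same
random-effects machinery as the discrimination metrics (identity scale),
with within-center variances from a multinomial delta method:
Var(NB) = [p₁(1−p₁) + w²p₂(1−p₂) + 2w·p₁p₂]/n for p₁ = TP/n, p₂ = FP/n,
w = t/(1−t). A deterministic frequentist pooling was chosen over a Bayesian
hierarchical model for reproducibility with zero extra dependencies.

## Meta-analysis

DerSimonian–Laird moment estimation of the between-center variance τ²,
inverse-variance weights 1/(v_c + τ²), Wald 95% CI, and Higgins–Thompson
95% prediction interval μ ± t_{k−2,0.975}·√(τ² + SE(μ)²) (k ≥ 3 centers;
undefined and flagged at k = 2). Proportions and c-statistics are pooled on
the logit scale with delta-method variances, guaranteeing back-transformed
intervals inside (0, 1). Within-center variances default to a seeded
nonparametric bootstrap (B = 200) unless the metric supplies a closed form.
A center enters a metric's meta-analysis only if the metric is computable
there (PDI needs all five classes present; pairwise c-statistics need both
classes); exclusions are logged. Coverage of the prediction interval is
verified by simulation (500 replicates with known τ²: empirical coverage
within 3 points of 95%).

## Pipeline and determinism

`run_experiment` wires the stages together: generate/load two cohorts
(development and validation are always two separate inputs; no internal
random splitting), impute, tune/fit per algorithm and CA125 variant, average
validation predictions over imputation pairs, evaluate, and export all
tables (performance summary, probability-range descriptives, decision
reversal matrix, decision curves, calibration curves, pairwise scatter
data) plus a JSON manifest. Without-CA125 models ignore CA125 entirely and
use a single non-imputed path. All randomness descends from one root seed
through named `SeedSequence` children recorded in the manifest; reruns are
byte-identical. The built-in config keeps the full 12-model experiment
around a minute on one CPU.

## Numerical conventions and limitations

* Probabilities are clipped at 1e-12 inside log-likelihoods; predicted
  matrices are renormalized to row sums of 1.
* Ties in hyperparameter selection resolve to the first candidate in grid
  order.
* The degenerate conditional risk and the all-constant-prediction
  calibration curve are handled as documented above (0.5 convention and an
  explicit error, respectively).
* The rescaled-ECI scaling reproduces the two published endpoint conditions
  but is not guaranteed to match other ECI variants away from those
  endpoints.
* Synthetic cohorts cannot validate clinical transportability; headline
  published performance values from the original multicenter patient data
  (e.g. multiclass PDI near 0.41–0.55) are not reproducible from synthetic
  data and are not targets of the test suite.
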