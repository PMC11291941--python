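# Methods

`reserveml` implements, end to end on synthetic cohorts, a pipeline for
estimating cognitive reserve from routine clinical variables: a residual-based
criterion standard, tiered gradient-boosted surrogates of that criterion, and
longitudinal mixed-model validation of whether the surrogates moderate
brain–cognition associations.  This note documents the models, the defaults
and their rationale, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## The criterion: a residual reserve index

Cognitive reserve is operationalised as what brain structure and demographics
*fail* to explain about episodic memory.  With a single composite memory
indicator the latent model reduces to a linear-Gaussian structural model

    memory_i = b0 + b' x_i + R_i + e_i,
    R_i ~ N(0, psi),   e_i ~ N(0, sigma_m^2),

where `x_i` contains the grey-matter signature volume, log white-matter
hyperintensity volume, sex, two race/ethnicity indicators (Black/African
American and Hispanic/Latinx, White as reference), prior test exposure,
Spanish-language administration, and the exposure × Spanish interaction.
Education is deliberately excluded so the criterion retains education-related
variance and education can later be compared against it as a proxy.

With `sigma_m^2 = 0` (the default: the composite indicator is treated as
error-free) the maximum-likelihood fit is *exactly* ordinary least squares,
the posterior-mean (regression-method) factor score of `R_i` is the OLS
residual, and factor-score determinacy is 1.  With `sigma_m^2 > 0` the
posterior mean shrinks the raw residual by `psi / (psi + sigma_m^2)`, which
also equals the determinacy.  Residual variance uses the ML divisor `n`, not
`n - p`; this matters for the exactness of the closed-form oracles in the
test suite.  Scores are standardised to mean 0, SD 1 before use downstream.

The correlation between the latent reserve and an observed surrogate is
estimated with all structural parameters frozen; under the model it equals
the Pearson correlation between surrogate and raw residual divided by the
square root of determinacy, with observed-information standard error
`(1 - r^2) / sqrt(n)`.

## Feature tiers and derived predictors

* **Minimal** (12 features): age, education, sex, diastolic blood pressure,
  pulse pressure, heart rate, height, BMI, ABSI, hip index, waist–hip index,
  self-reported memory concern (binarised: any affirmative → 1).
* **Extended** (+3): 30-point cognitive screener on the MMSE scale, 45-item
  word-reading score, 15-item depression score.
* **Full** (+4): CDR sum of boxes, CDR memory box, ECog informant total and
  memory scores.

Allometric indices follow the power-law form `scale · m · height^a · base^b`.
Defaults: ABSI = waist(m) · BMI^(−2/3) · height^(−1/2); hip index =
hip(cm) · height^0.310 · weight^(−0.482), scaled to reference height 1.66 m
and weight 73 kg so its magnitude stays near the raw hip circumference; the
waist–hip index normalises the waist/hip ratio by height^0.5 · BMI^(1/3) with
scale 1.12.  Published conventions for these indices differ in constants
across cohorts, so exponents and scale are explicit configuration rather than
hard-coded truths; only the measurement-independence structure is relied on.

MoCA scores are mapped to MMSE equivalents through a validated 31-row
monotone crosswalk table (identity by default; a published crosswalk can be
loaded from CSV).  50-item word-reading scores are rescaled to the 45-item
form by proportional rounding (`round(score · 45/50)`, half-up) by default,
with an injectable exact mapping.  Missing source columns propagate as NaN to
exactly the features that depend on them; nothing is imputed — the boosted
trees route missing values natively at both training and prediction time.

## Surrogate training

Each tier's surrogate is an XGBoost regressor trained to predict the
standardised criterion scores: a simple random 75/25 participant split, then
hyperparameter search scored by mean out-of-fold RMSE over a fixed 10-fold
partition of the training set.  The search is surrogate-guided: a scrambled
Sobol initial design, then lower-confidence-bound proposals from a
random-forest surrogate over the unit-normalised search space, up to 200
candidates with early discontinuation after 100 consecutive non-improvements
(both configurable; the tuner's contract is that the returned candidate is
the argmin of all logged candidates).  The default search space is tree depth
2–8, learning rate 10^−2–0.3 (log), minimum child weight 1–20, row/column
subsampling 0.5–1, 100–1500 trees, and L2 regularisation 10^−3–10 (log).

Several experiments in the tests and the acceptance script use a fixed,
deliberately modest configuration (depth 3, learning rate 0.08, 300 trees,
90% row/column subsampling) instead of a full search; tier ordering and
moderation conclusions are insensitive to tuning at that scale, and the tuner
contract is exercised separately.

## External validation: the moderation ladder

Executive function at each visit is modelled by Gaussian linear mixed models
with correlated random intercept and random time slope per participant,
fitted by maximum likelihood (not REML, because the ladder compares
fixed-effect structures by likelihood-ratio tests):

* **E1, covariates only** — age (centred at 70), education (centred at 12),
  sex, word reading (centred at 32), each with its time interaction; time;
  baseline grey matter, grey-matter change, baseline × time; and the full
  moderation block for the comparison proxies (education and word reading:
  proxy × baseline, proxy × change, proxy × baseline × time).  Including the
  comparison-proxy moderation in the baseline model means every later stage
  measures the candidate proxy's increment *beyond* conventional proxies.
* **E2** = E1 + reserve, reserve × time (2 df).
* **E3** = E2 + reserve × baseline grey matter (1 df).
* **E4** = E3 + reserve × baseline × time + reserve × grey-matter change
  (2 df).

The stage increments (2, 1, 2) are structural; consecutive stages are
compared by chi-square LRTs on the identical listwise-complete row set.
Parameter counts include fixed effects, the random-effect covariance (3
parameters, or 2 after a diagonal fallback), and the residual variance.  If
any stage's random-effect covariance hits the singular boundary, all four
stages are refitted with independent random effects so the compared models
share one covariance structure.  A negative deviance difference within 1e-6
is clamped to zero; anything larger marks the comparison unavailable rather
than reporting a nonsense chi-square.  Nested stages are warm-started from
the previous stage's covariance solution, which changes log-likelihoods by
less than 1e-9 and roughly halves fitting time.

Every reported log-likelihood is checked (in the test suite) against a direct
evaluation of the marginal multivariate-normal density
`y_i ~ N(X_i b, Z_i G Z_i' + s^2 I)` summed over participants.

Predicted trajectories for a reference profile (70-year-old woman, 12 years
of education, average baseline volume) are fixed-effects-only predictions on
a time grid with grey-matter change equal to rate × time, at atrophy rates
−0.05, −0.10, −0.15 SD/year.

## The synthetic cohort generator

The generator is the package's study design: it fixes the conditions under
which every claim is tested.  Latent structure: disease stage ~ N(0,1);
reserve R ~ N(0, 0.6²), independent of stage.  Memory follows the criterion
model above with residual noise SD 0.35, so the criterion's ceiling
correlation with R is 0.6/√(0.6²+0.35²) ≈ 0.86.  Clinical features are
linear-Gaussian in (standardised R, disease stage, demographics), then
rounded and clamped into their legal ranges; CDR and ECog are monotone
transforms of a shared latent severity score `stage − 0.8·z_R + noise`,
preserving their ordinal structure without item-level modelling.

Default loadings were calibrated once, at design time, to the qualitative
contrasts the method is meant to exhibit: education and word reading are
*weak* reserve proxies (criterion correlations ≈ 0.19 and 0.32), the
screener and informant ratings are strong ones, and vitals/anthropometrics
are nearly uninformative.  Under these conditions held-out surrogate
correlations come out near 0.26 (Minimal), 0.42 (Extended), 0.47 (Full) —
the Minimal ≪ Extended < Full ordering that motivates the tier design.

The longitudinal arm generates annual visits (4 by default) with atrophy
rate −0.10 ± 0.08 SD/year plus a −0.06/SD disease-stage coupling — a spread
wide enough to cover the cognitively normal-to-dementia range — and an
executive-function mixed model whose slope effect of grey-matter change is
attenuated by reserve: coefficient `0.55 − theta·z_R` with `theta = 0.8`.
Positive `theta` therefore always means high reserve buffers atrophy.
`null_config` zeroes only `theta`, leaving every other reserve pathway (main
effects, intercept moderation) intact, which makes it a sharp null for the
slope-moderation test specifically.  Moderation coefficients were chosen so
the expected ladder chi-squares at n = 2000 sit in the tens-to-hundreds
range characteristic of well-powered cohort analyses of this design.

Features the validation cohorts never collected (waist and hip by default,
hence ABSI/hip-index/waist–hip-index) are emitted entirely missing, and
surrogate scores are still produced for every participant via missing-value
routing.

### What the generator does not emulate

Real cohorts have informative dropout, visit-schedule irregularity,
site/scanner effects, practice effects beyond a simple exposure indicator,
non-Gaussian and heteroscedastic measurement error, and clinical features
with skewed, zero-inflated or threshold-driven distributions.  Passing tests
demonstrate that the pipeline's statistics behave correctly under a known
generative model — parameter recovery, calibrated type-I error, expected
power ordering — not that the fitted constants transfer to any real
population.

## Numerical choices

* RRI fitting uses `lstsq`/normal equations; rank deficiency is diagnosed by
  pivoted QR and reported with the offending column names; listwise deletion
  with logged counts is used for missing data (keeps ML exactness).
* Mixed models: L-BFGS with a conjugate-gradient retry on non-convergence;
  singular-boundary detection at eigenvalue ratio 1e-10.
* Tree SHAP attributions are computed by the boosted ensemble itself
  (path-dependent formulation) in single precision; local accuracy
  (base value + attributions = prediction) is exact up to float32
  accumulation, about 1e-8 per tree — comfortably below 1e-6 for ensembles
  up to ~150 trees, and ~2e-6 for 300-tree models.  Gain importance is
  normalised to sum to one; ties break by feature order; a model with no
  splits reports all-zero importances.
* Type-I-error calibration of the slope-moderation LRT uses 500 simulated
  null cohorts of 500 participants × 4 visits.  Maximum-likelihood LRTs on
  this design are mildly anticonservative at small cohort sizes (the
  empirical rejection rate at 5% falls from ≈6.6% at n=150 to ≈5–6% at
  n≥300 as the random-effect ML bias shrinks), which is why the calibration
  cohorts are the largest routinely affordable size rather than the smallest
  detectable one.
* All randomness flows from per-stage seeds expanded deterministically from
  one master seed (`SeedSequence`), and XGBoost runs single-threaded with
  `tree_method="hist"`, so every pipeline stage is bit-reproducible.

## Known limitations

* The single-indicator criterion model cannot separate measurement error
  from reserve without an externally supplied `sigma_m^2`.
* The "Bayesian" tuner is a lower-confidence-bound random-forest surrogate,
  chosen for determinism and zero extra dependencies; it makes no claim of
  matching any particular Bayesian-optimisation implementation beyond the
  stopping-rule and argmin contracts.
* The moderation ladder assumes Gaussian outcomes and linear mean structure;
  no generalised or nonlinear mixed models.
* Attribution is path-dependent tree SHAP; interventional SHAP with a
  background sample is not implemented.
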