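# Methods

This document specifies the model implemented by `popsynth`, the parameters
and defaults it uses, how the bundled truth generators are constructed, the
numerical choices, and the known limitations. All numbers quoted here were
computed by this repository's test suite or by
`python scripts/acceptance.py --seed 1 --out results/acceptance.json`.

## 1. Two-step synthesis

**Secure zone (fit + export).** On the confidential table, the package

1. extracts the exact joint frequency table of the *seed* variables
   (demo: single-year age 0–105, gender, region, urbanicity). A minimum
   cell size gate (default 10) applies one of two policies: `waive` keeps
   sub-threshold strata with an explicit flag, `drop` removes them;
2. fits, for each outcome variable k in a declared sequence, a regression of
   that variable on the seed variables and outcomes 1..k−1, separately per
   stratum of a declared stratifier (demo: gender);
3. exports a JSON bundle containing only the plan, the seed-strata counts,
   and per stratum model the coefficient vector, its covariance matrix,
   the residual SD (gaussian), the frozen design encoding (spline knots,
   category levels and reference, centring constants), and fit provenance.
   No exported array has length equal to the fit-population row count; this
   is asserted by an acceptance test that recursively scans the serialized
   bundle.

**Open zone (synthesis).** From the bundle alone, the package expands the
seed table into exactly its counts (seed joint distribution is conserved
*exactly*, not in expectation) and then draws each outcome in sequence from
its stratum model:

- gaussian: linear predictor + N(0, residual_sd); for probability-type
  outcomes the model operates on the logit scale (outcome clamped to
  [1e-6, 1−1e-6] before the logit at fit time) and the draw is mapped back
  through the inverse logit;
- logistic: Bernoulli at the inverse-logit of the linear predictor;
- multinomial: baseline-category logits turned into a category draw.

A stratum in which the outcome was constant at fit time is exported as a
degenerate model that re-emits the constant.

## 2. Design matrices

Every encoding decision is made at fit time and stored in the bundle so the
open zone rebuilds the identical matrix:

- **Age splines.** Natural (restricted) cubic splines in the
  truncated-power construction: a linear column plus df−1 nonlinear columns
  that are cubic between knots and linear beyond the boundary knots,
  divided by (t_last − t_first)² to keep columns on a comparable scale.
  Default df = 4 with knots at equally spaced quantiles; the knots are
  stored and reproduce the basis bit-exactly on new data.
- **Categoricals.** One-hot with the reference = most frequent observed
  level. All *declared* levels are kept in the term even if unobserved in
  the fit data; their columns are all-zero at fit time (identified only
  through the ridge penalty, i.e. shrunk to "same as reference") but remain
  encodable at synthesis time, where rare levels can legitimately occur.
- **Missing predictors.** Missing-indicator method: the value is filled at
  the stored centre (continuous) or reference level (categorical) and a 0/1
  missingness column is appended. Used in the demo for BMI and smoking as
  predictors of the cancer indicators, since those are survey-scope
  variables unobserved for most of the population.
- Continuous predictors are centred at their observed fit-time mean, so the
  missing fill value 0 means "average".

## 3. Estimation

- **Gaussian** models are ordinary least squares (statsmodels OLS, pinv
  solver, so rank-deficient designs from unobserved declared levels get the
  minimum-norm solution).
- **Logistic and multinomial** models maximize a ridge-penalized
  log-likelihood, loglike(b) − α/2·‖b‖², with α = 1e-4 applied on a
  column-rescaled design (each column divided by its max absolute value).
  The penalized objective is strictly concave (Hessian ≤ −αI), so a unique
  maximum exists even under quasi-complete separation, where the
  unpenalized MLE does not (this occurs in practice: rare level × rare
  level zero cells). It is maximized by damped Newton from zero with
  backtracking line search; convergence is declared when the max absolute
  penalized score is below 1e-3 (at most 200 iterations, errors otherwise
  — the fit never silently returns a non-converged point). The reported
  covariance is the inverse penalized observed information. Estimates and
  covariances are mapped back to the raw design scale. Against an
  unpenalized reference fit on a well-conditioned problem the relative
  coefficient difference is below 1e-3 (unit-tested).

### Multiple imputation for survey nonresponse

Survey-scope outcomes with item nonresponse are imputed by chained
equations before fitting: M = 5 copies, 10 sweeps, drawing each missing
value from the fitted conditional model of that variable given the seeds
and the other survey-scope variables (with per-draw parameter noise).
Observed cells are never altered. The M per-copy fits are pooled with
Rubin's rules: Q̄ = mean of estimates, W = mean of covariances, B = sample
covariance of estimates, T = W + (1 + 1/M)B. The pooled model carries
coefficient Q̄ and covariance T. An acceptance test verifies the textbook
hand computation (estimates {1, 3}, variances {0.5, 0.5} → T = 3.5; B = 0
for identical estimates).

### Parameter uncertainty and calibration

- `draw_parameters=True` redraws each stratum model's coefficient vector
  from N(Q̄, T) once per replicate before synthesis, propagating estimation
  uncertainty into the synthetic data.
- `calibration_targets={var: m}` rescales the per-row probabilities of a
  binary variable by one common factor c, capped at 1, chosen by bisection
  (tolerance 1e-10; the capped mean is monotone in c) so the synthetic mean
  equals m. Targets outside (0, 1) or above the attainable supremum (the
  fraction of rows with nonzero probability) are errors. Measured absolute
  mean error with active capping: 3.5e-12 over 1000 rows.

## 4. Randomness

Every random draw comes from a dedicated PCG64 stream keyed by
`SeedSequence([seed, replicate, sequence_position, stratum_index, salt])`
(salt 7 for parameter redraws). Consequences: the same seed reproduces a
synthesis bit-for-bit; replicates share the seed frame but have independent
outcome draws; and a change in one variable's model does not perturb the
draws of unrelated variables.

## 5. Consistency audit

`SynthesisResults.consistency_audit` compares every realized synthetic
marginal with the model-implied (Rao–Blackwellized) marginal: the mean over
rows of the per-row probability (categorical families) or the per-row
conditional mean (gaussian). For logit-gaussian probability outcomes the
per-row mean requires an integral over the residual, evaluated by 20-node
Gauss–Hermite quadrature. The audit reports z = (realized − implied) /
Monte-Carlo SE. At the demo scale (n = 100 000, 46 audited marginals) the
maximum |z| is ≈ 2.0 (seed 0) / 2.9 (seed 1).

## 6. Truth generators (validation scenarios)

The package validates itself against simulators whose generating equations
are known exactly (`popsynth.scenarios`):

- **demo** — 4 seed variables; a 14-level income source with realistic
  registry frequencies; two percentile variables constructed by rank
  transform to an exactly uniform marginal (100·(rank+0.5)/n); household
  type/size; 7-level migration background; a lognormal BMI analogue,
  smoking, activity (survey scope, ~3% survey with age bias 1.3 per decade
  and MAR-by-age item nonresponse); two rare cancer indicators; four
  chronic-disease probability columns. Measured at n = 100 000, seed 1:
  first-position categorical marginal within 0.101 pp of truth, seed joint
  counts conserved exactly (max diff 0 over 2525 strata).
- **recovery** — a minimal chain whose fitted design equals the generating
  design, so every fitted coefficient has a known target. Over 200
  replicates at n = 20 000, each of the 16 coefficients lies within 3
  reported SEs of its target in ≥ 99.5% of replicates (nominal ≥ 95%).
- **misspec** — a chain v1..v4 where each step adds a pure
  (region × age>50) XOR effect with zero main effects, which the
  main-effects fit cannot represent. Total-variation distance between truth
  and synthesis grows along the sequence: 0.055 → 0.125 → 0.199 → 0.245.
- **mi** — one survey variable (bmi = 25 + 0.08·(age−40) + N(0,2)) with
  strong MAR-by-age nonresponse (35% base rate, slope 0.9 per decade).
  The M = 5 pooled survey mean is within |z| = 0.55 total-SEs of the
  pre-nonresponse truth while the complete-case mean is off by |z| ≈ 20
  (a bias of ≈ 0.85 BMI units).

## 7. Evaluation utilities

- `four_moments`: mean, SD (ddof = 1), moment skewness g1 = m3/m2^1.5 and
  excess kurtosis g2 = m4/m2² − 3 (population moment ratios); verified
  against brute-force sums to 1e-10, with [1..5] → (3, 1.5811, 0, −1.3)
  and uniform g2 ≈ −1.2.
- `stratified_compare`: per age-class × gender stratum, Wilson 95%
  intervals for proportions and t intervals for means, with small cells
  (< 30) flagged rather than hidden. Age classes: <20 → 1, decades 2..7,
  80+ → 8.
- `total_variation`: TV distance on category frequencies (continuous
  variables via a common 30-bin grid).
- `disclosure_match_rate`: fraction of original key combinations that occur
  in the synthetic data, with an independent-marginals baseline for
  context.

## 8. Limitations

- **Shape misspecification.** Conditionally gaussian draws cannot reproduce
  skewed or heavy-tailed truths: synthetic BMI has skew ≈ 0.006 and excess
  kurtosis ≈ −0.014 where the (lognormal) truth has skew ≈ 0.64. Percentile
  variables are likewise synthesized as gaussian mixtures, not exactly
  uniform.
- **Main-effects only.** Interactions not in the predictor set are lost,
  and the error *accumulates* along the sequence (misspec scenario above).
  Stratifying by gender captures gender interactions only.
- **Rare events.** With ~3000 survey rows, coefficients tied to ~10 events
  (e.g. a cancer's missing-indicator terms) are noisy; downstream rare
  prevalences can be off by tens of percent in relative terms while still
  within model-implied Monte-Carlo bounds.
- **Unobserved declared levels** are shrunk to the reference category by
  the ridge penalty rather than estimated.
- **The ridge penalty** (α = 1e-4 on the scaled design) introduces a bias
  that is negligible at the fitted sample sizes (relative coefficient shift
  ~1e-6 at n = 4000) but grows for tiny strata; it is the price of a
  well-defined estimate under separation.
- The disclosure gate controls export *shape* (counts, coarse strata,
  coefficients only) and minimum cell sizes; it is not a formal privacy
  guarantee such as differential privacy.
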