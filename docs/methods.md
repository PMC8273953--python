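# Methods

## Normative model

Each of the five battery tests is modelled as a linear function of age and
years of education on a healthy-volunteer sample:

    score_i = β₀ + β_age·age_i + β_edu·edu_i + ε_i,   ε_i ~ N(0, σ²)

`fit_test_model` estimates (β₀, β_age, β_edu) by ordinary least squares
(statsmodels) and the residual SD as `sqrt(RSS / (n − 3))` — the unbiased
multiple-regression convention with three estimated mean parameters. The
published Cameroonian table reports SDs without naming the estimator; the
n − 3 residual SD is this package's assumption and is what the generator and
all tests use consistently. The LTT is always fitted and scored on its
error-adjusted composite `(1 + errors/100) × time`, since that composite is
the defined LTT result. Fitting is per-test complete-case: a volunteer
missing one result drops out of that test's regression only, which maximises
usable n and mirrors per-variable denominators in clinical tables.

Preconditions: at least 10 volunteers with a result, and a full-rank design
(constant age or education raises a fitting error naming the predictor).

`fit_norms` fits all five tests, scores the fitting sample with the fresh
norms, and calibrates the PHES population mean/SD and cut-off from those
scores — the same closed loop a standardisation study performs.

## Scoring

The deficit Z is `(observed − expected)/σ`, negated for the DST (the only
test where more points mean better performance), so positive deficit always
means worse than expected. Banding is a step function onto {−3 … +1}:

    z < −1 → +1;  −1 ≤ z ≤ 1 → 0;  1 < z ≤ 2 → −1;  2 < z ≤ 3 → −2;  z > 3 → −3

Boundary ties go to the less pathological band, and the +1 bonus requires
strictly better than 1 SD — the narrative banding rules state "less than
− 1 SD" strictly but leave the other boundaries open; extending that
strictness symmetrically is this package's choice. The source text labels
its reversed banding block "SDT", but the SDT is a timed test (seconds);
applying a lower-is-worse rule to it would reward slowness, so the reversed
block is read as describing the DST. Deficit Zs are kept at full floating
precision; nothing is rounded before banding.

PHES is the integer sum of the five component points, bounded in [−15, +5].
The cut-off is `floor(mean − 2·SD)` of the normative population's PHES:
flooring reproduces the published −3 from −0.08 − 2×1.28 = −2.64 and is
well-defined for any inputs (PHES is integer-valued, and flooring takes the
conservative threshold). MHE classification defaults to *strictly below* the
cut-off; an inclusive at-or-below rule is exposed (`MheRule.LESS_EQUAL`)
because published phrasing of such cut-offs is often ambiguous.

## Cohort statistics

* Prevalence is reported with its raw numerator/denominator.
* Odds ratios are cross-product ratios at full precision; the reporting
  layer truncates (not rounds) to two decimals, the convention the source
  cohort table verifiably used (e.g. 2.0289… → 2.02, 4.6875 → 4.68). A zero
  cell makes the OR undefined (NaN); the Haldane–Anscombe +0.5 correction is
  available behind an explicit switch, off by default.
* Confidence intervals are Woolf log-OR intervals,
  `exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d))`. The interval method was not
  stated by the source; Woolf was chosen because it reproduces the printed
  intervals at one-decimal truncation (e.g. male sex [0.136, 2.004] →
  "[0.1–2.0]"). Exact conditional intervals are out of scope.
* Group contrasts use per-variable complete-case denominators. Quantitative
  variables: Shapiro–Wilk normality (per group) and Levene variance
  homogeneity gate the choice between the equal-variance t-test and the
  Mann–Whitney U; categorical variables use the chi-square test unless any
  expected cell is below 5, then Fisher's exact test. All tests are
  two-sided at α = 0.05 with no multiplicity correction (matching standard
  univariate cohort-table practice). Degenerate inputs (singleton or
  constant groups, empty margins) return a comparison marked not-computable
  rather than raising. Test internals are delegated to scipy.stats.
* Percentages render half-up to one decimal.

## Synthetic cohorts

The generator emulates the standardisation study's design so every pipeline
stage is testable without clinical data.

* **Volunteers** (`gen_volunteers`): age is drawn from weighted bands —
  default weights 29/31/19/17/6 over [20,30), [30,40), [40,50), [50,60),
  [60,72], the volunteer sample's band counts — uniformly within a band (the
  study reports only band counts); education is a truncated Gaussian per
  band with the study's band means, SDs and ranges; sex is Bernoulli at the
  study's male share (54/102). Each test result is the normative linear
  predictor plus Gaussian residual noise.
* **Cirrhotic patients** (`gen_cirrhotics`): the same measurement model with
  every test shifted `deficit_shift` residual SDs towards worse performance
  (additive on the deficit-Z scale — the simplest mechanism consistent with
  the banding model), demographic offsets (default +11 y age, −2 y
  education, the cirrhotic-vs-volunteer mean differences), and clinical
  covariates drawn independently at the cirrhotic cohort's marginal
  prevalences (ascites 34%, jaundice 18%, prior GI bleed 16%, Child–Pugh
  A/B/C 60.5/27.9/11.6% with 14% missingness). The default
  `deficit_shift = 2.0` SD makes the expected component −1.5 points and the
  mean PHES ≈ −7.5, a realistic moderately impaired cohort.
* **Numerical guards**: generated times are floored at 10 s and the DST is
  rounded to a non-negative integer, so Gaussian tails cannot produce
  impossible raw values; the LTT is generated composite-first, with a
  Poisson(5) error count and the time back-solved, so only the composite's
  distribution is contractual.
* **Determinism**: identical (n, model, config, seed) yields an identical
  cohort; all draws go through one `numpy.random.default_rng(seed)`.

What the generator does *not* emulate: between-patient heterogeneity of the
deficit (a fixed shift understates the PHES variance and overstates the MHE
prevalence relative to a real mixed-severity cohort), the joint distribution
of age and education within patients (independence given group is assumed),
correlations between clinical covariates, and biochemical variables. Passing
tests therefore demonstrate the pipeline's arithmetic and statistical
machinery under the stated measurement model, not clinical validity on real
cohorts.

## Problem sizes

The test suite and acceptance script use n = 1000–2000 synthetic subjects
per replicate and 100 replicates for recovery/coverage checks, sizes at
which OLS standard errors are small enough for 3-SE coverage statements to
be sharp while the whole suite stays fast. The dense banding oracle uses a
0.001 grid over deficit Z ∈ [−5, 5]; the odds-ratio cross-check sweeps all
2×2 tables with cells in 1…30 exhaustively.

## Known limitations

* The built-in constants are the printed two-decimal values; the authors'
  unrounded coefficients are unavailable, so scores very close to band
  boundaries could differ from the original instrument's.
* Normative validity is only claimed over the standardisation sample's
  support (ages 20–72, education ≥ 4 y); the package does not guard against
  extrapolation beyond it.
* No logistic or multivariable modelling of MHE predictors; contrasts are
  univariate by design.
* Alternate normative populations must be supplied as model files; no
  re-estimation of other countries' published equations is attempted.
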