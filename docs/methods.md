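# Methods

## The problem

Adolescent surveys often collect self-reported (SR) height and weight.
Self-report is biased: height tends to be over-reported and weight
under-reported, and the weight under-report is largest among adolescents
with overweight or obesity.  BMI and weight-status prevalence computed from
self-reports therefore understate overweight/obesity.  When a survey wave
contains *both* measured and self-reported anthropometrics, a linear
correction can be estimated there and then applied to waves that have only
self-reports.

## Correction model

For each outcome y ∈ {measured weight, measured height} we fit a single
pooled linear equation

    y_i = β0 + β_sr · SR_i + Σ_j β_j x_ij + ε_i

where `SR_i` is the self-reported analogue of the outcome and the `x_ij`
are candidate covariates: age in months, perceived pubertal development
(1–5), weight status implied by the self-reported BMI (UW/HW/OW/OB, healthy
weight reference), body-size self-estimation (3 levels, "about right"
reference), a dieting-to-lose-weight indicator, CES-D depressive-symptom
score (0–60), self-rated health (1–5), self-esteem (1–5), race/ethnicity
(White reference), sex (male reference) and parent education (college-degree
reference).  Categorical predictors are dummy-coded as whole class-variable
blocks so each outcome has one regression equation.

Estimation is weighted least squares with the sampling weights treated as
probability weights, normalised to sum to n.  Under that convention the
Gaussian log-likelihood at the plug-in variance is
`ll = -n/2 (log 2πσ̂² + 1)` with `σ̂² = Σ w̃ e²/n`, and
`AIC = 2k − 2 ll` with k counting intercept + slopes + error variance.
R² is the weighted explained-variance fraction.  Point estimates and
standard errors come from `statsmodels` WLS; the likelihood, AIC and R² are
computed by this package because the convention above (probability weights,
σ² counted in k) is part of the method's definition here.  Design-based
(stratum/PSU) variance is out of scope: weights enter point estimates, and
confidence intervals are model-agnostic approximations.

### Block-wise AIC selection

`aic_select` performs backward elimination over whole predictor blocks: from
the full model, the single block whose removal lowers AIC most is dropped,
repeatedly, until no removal lowers AIC.  The self-report analogue of the
outcome is always retained.  Determinism is fixed by two conventions the
procedure itself does not dictate: blocks are evaluated in their declared
candidate order, and an exact AIC tie keeps the block.  A removal that
leaves the design rank-deficient is skipped.  Because AIC tolerates a block
whose improvement is within the 2-per-parameter penalty, a truly null
one-degree-of-freedom block survives selection with probability ≈
P(χ²₁ > 2) ≈ 0.16; multi-dummy null blocks are removed more reliably
(≈ 0.91 for a four-dummy block).  That is a property of AIC, not a defect
of the implementation, and the tests assert exclusion *rates*, not
certainties.

### Interaction screening

`screen_interactions` takes the selected model and considers all pairwise
products of the retained predictors — dummy×dummy, dummy×continuous,
continuous×continuous — as candidate blocks.  "Significant predictors"
eligible for screening are exactly the blocks retained by AIC selection, not
p-value-thresholded terms.  Product columns that are constant or linearly
dependent on the current design are pruned.  One interaction block is added
per round (greedy, largest AIC drop), until no addition lowers AIC.

### Applying the correction

`correct_record` evaluates both fitted equations on a record's design
vector, converts the corrected height and weight to metric, computes
corrected BMI = kg/m², and classifies weight status.  Records are canonical
metric internally (cm, kg) with the source unit system recorded at ingest;
conversion into a model's unit system (2.54 cm/in, 0.45359237 kg/lb) is
automatic and lossless, so a unit error can only arise from genuinely
incompatible objects (e.g. weight and height models serialized in different
unit systems).  Missing covariates are never imputed: fitting and
application are complete-case, with dropped-record counts reported.

### The bundled published equations

`published_models()` returns the two fixed coefficient sets this package
ships for the correction of a specific US adolescent panel survey: a weight
equation (9 blocks; race/ethnicity, sex and parent education eliminated
during its selection) and a height equation (all candidate blocks retained,
including individually non-significant race levels kept because the class
variable contributed, and a single pooled "less than college" parent-
education term).  Two caveats are deliberate:

* **Units.** The source publication does not state the unit system of its
  equations; slopes of 0.95 (weight) and 0.85 (height) with intercepts 8.20
  and 9.53 are only dimensionally sensible in pounds and inches, the
  survey's native units, so the bundled models are flagged `imperial` and
  conversion to metric happens after correction, before BMI.
* **Precision.** Coefficients are stored at their printed two-decimal
  precision (age enters as −0.01 and 0.00), so predictions carry rounding
  error of order 0.005 × covariate magnitude and exact reproduction of the
  original study's corrected values is not possible from the printed
  equations alone.

Models serialize to versioned JSON with coefficients written as decimal
strings (`repr` of the float), which round-trips bit-exactly.

## Weight-status classification

BMI is weight/height² (kg/m²; 703·lb/in² for imperial inputs).  For ages
under 240 months, BMI maps to an age/sex-specific z-score through an LMS
growth reference — z = ((x/M)^L − 1)/(L·S), or log(x/M)/S when L = 0 — and
to a percentile 100·Φ(z).  Categories are half-open: UW < 5th ≤ HW < 85th ≤
OW < 95th ≤ OB, so a percentile of exactly 85 is overweight.  At 240 months
and older the adult cutoffs apply (UW < 18.5 ≤ HW < 25 ≤ OW < 30 ≤ OB,
lower bounds inclusive, the WHO convention).  LMS parameters are linearly
interpolated in age between tabulated rows; other reference
implementations may interpolate differently, which can move a borderline
case by a sub-percentile amount.  Ages outside the table raise an explicit
range error rather than extrapolating — in particular there is no silent
chart-edge extrapolation just under age 20.

The growth reference is an input (CSV `sex,agemos,L,M,S`, sex coded 1/2 or
`male`/`female`), not an embedded dataset; users may supply the real CDC
table in that layout.  The bundled generator provides a synthetic fixture.

## Evaluation metrics

* **Weighted Pearson correlation** between BMI series, by direct
  weighted-moment summation.
* **Contingency tables**: 4×4 weighted percentages, rows = assigned status
  (SR or corrected), columns = reference status (measured).  With that
  orientation, "above the diagonal" means the reference exceeds the assigned
  status, i.e. underestimation; `underestimation_rate`,
  `overestimation_rate` and `overall_misclassification` (100 − trace)
  decompose the table and sum to 100 exactly.  Raw counts are retained when
  weights are uniform.  Tables re-entered from rounded publications may sum
  to slightly off 100; `from_percentages` accepts a relaxed total tolerance
  (default ±0.5) while freshly computed tables are validated at 1e-9.
* **Threshold diagnostics**: positives are BMI ≥ threshold on both axes;
  sensitivity/specificity/PPV/NPV from weighted cell masses.  95% CIs use
  the Wilson score interval (default) or exact Clopper–Pearson, on a Kish
  effective sample size n_eff = (Σw)²/Σw² of each metric's denominator
  group.  With uniform weights everything reduces to the unweighted
  formulas.  `compare_diagnostics` reports percentage-point deltas and a
  CI-overlap flag (non-overlap being the conventional "clearly different"
  marker, with the usual caveat that overlap is not a significance test).
* Display rounding is one decimal for table percentages and three decimals
  for diagnostics; internal values are never rounded.

## Synthetic cohorts

`generate_cohort` emulates the structure the method assumes, not any real
survey:

1. Sex, integer age in months (default 144–264, so both pediatric and adult
   classification routes are exercised), race/ethnicity and parent education
   from fixed marginals; lognormal sampling weights (σ = 0.3, mean 1).
2. Latent height from a sex-specific exponential-approach growth curve;
   latent BMI through the LMS fixture with z ~ N(0.4, 1), which yields
   roughly US-like overweight/obesity prevalence; latent weight =
   BMI·(height/100)².  For ages past the fixture edge the 240-month row is
   used (adult-age records are classified by adult cutoffs anyway).
3. Self-reports = latent values + Gaussian perception noise (1.8 cm,
   2.2 kg).
4. Measured values are generated *given* the self-reports: measured weight =
   SR weight + under-report(SR status, sex) + optional covariate effects +
   N(0, 2.0 kg); measured height = SR height − over-report(sex) +
   N(0, 1.2 cm).

Two generative choices are deliberate and matter for interpretation.
First, the independent residual is placed on measured-given-self-report
(algebraically the same relationship as "SR = measured − bias + noise", with
the noise relabelled), which makes the fitted regression *correctly
specified*, so parameter-recovery tests have an exact truth to recover.  A
generator that drew measured values first and then added noise to the
self-report would instead create an errors-in-variables attenuation, and no
linear fit could recover the nominal coefficients.  Second, the reporting
bias is keyed to the *self-reported* weight status — the same derived
predictor the correction models use — for the same reason.  Consequently,
passing recovery tests demonstrate that the estimation and selection
machinery is correct, not that real self-report bias follows this model;
with real data the fitted equation is a predictive approximation, exactly as
it is in the source methodology.

Default bias magnitudes are seeded from reported adolescent biases: female
under-report pinned at 1.02 kg in the overweight/obesity strata (−0.3 kg UW,
0.4 kg HW), male {−0.3, 0.1, 0.5, 0.8} kg across UW/HW/OW/OB (sex-wide male
mean ≈ 0.2 kg); height over-report 1.2 cm (male) / 0.8 cm (female).  These
are illustrative defaults.  Covariates are generated from the *latent*
status: body-size estimation is the coarsened status plus N(0, 0.6)
misperception on the 3-level scale; dieting is Bernoulli with
status-dependent logits {−4.0, −1.9, −0.7, −0.2} plus −1.5 for males
(≈19% of females, ≈5% of males); CES-D, self-esteem and self-rated health
are clipped Gaussians with small status loadings; puberty is an age-linked
rounded Gaussian on 1–5.

In the default configuration the covariate→measured-weight effects are zero,
so the bias is purely status- and sex-dependent and the 1.02 kg figure holds
exactly in expectation within the female OW/OB stratum.  The
parameter-recovery configuration (`recovery_config`) switches on dieting
(+0.45 kg), body-size estimation (−0.8/+1.6 kg) and puberty (+0.12 kg)
effects and uses a single-sex (female) cohort so that per-sex generative
coefficients are identified by one pooled fit; race/ethnicity has no
generative effect there and serves as the designated pure-noise block for
selection checks.  `oracle_refit_check` requires a single-sex configuration
for this reason and raises a data error otherwise.

All randomness flows from one seed through named `SeedSequence` children
split per variable, so adding a covariate stream does not perturb existing
draws; identical configurations give byte-identical cohort CSVs.

The synthetic growth fixture covers 144–240 months per sex with a smooth,
strictly increasing median BMI curve (≈17.8→23.2 kg/m² male, 18.1→21.9
female), L in [−3, 1], S in [0.05, 0.2], and a small seeded perturbation an
order of magnitude below the monthly median increment so monotonicity is
preserved.  BMI z-draws are clipped to ±3 (and the LMS power-branch base
floored) so the inverse transform stays in its support; this truncates
roughly the top 0.1% of the BMI tail.

## Sex-specific versus pooled fitting

The correction can be framed either as pooled equations with sex as a
covariate or as separate per-sex refits.  This package fits pooled models by
default (sex is a candidate block); a stratified fit falls out naturally by
passing a single-sex cohort, because zero-variance dummy columns are dropped
from the design rather than raising a collinearity error.  Neither mode is
asserted to be the "right" one — published practice is ambiguous on this
point — and both are exercised in the tests.

## Known limitations

* The synthetic generator omits school-cluster sampling structure,
  longitudinal growth trajectories and realistic population pyramids; it is
  a validation instrument, not a population model.
* Wilson/Clopper–Pearson intervals on a Kish effective n approximate, but do
  not reproduce, survey design-based CIs.
* AIC block selection is not a consistent model-selection procedure; weak
  null blocks are sometimes retained (see above), so downstream code should
  treat "retained" as "useful for prediction", not "significant".
* The published equations' two-decimal coefficients bound how closely any
  reimplementation can match the original corrected values.

## Problem sizes used by the test suite and acceptance script

Worked-example arithmetic on published tables is exact and instantaneous.
Parameter recovery uses one n = 10 000 cohort for the 3-SE slope check and
20 replicates of n = 10 000 for the noise-block exclusion rate;
direction-of-effect uses 10 replicates of n = 3 000 with full refit and
apply.  These sizes give Monte-Carlo error comfortably below the asserted
margins while keeping the full suite around a minute on one CPU.
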