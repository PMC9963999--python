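# Methods

## The problem

Pre-participation cardiac screening of paediatric athletes must separate
training-related cardiac enlargement from early cardiomyopathy.  Raw
cut-offs fail because chamber dimensions scale with body size and age, and
because residual scatter itself grows with body size (heteroscedasticity).
`paedz` implements covariate-adjusted normative models that express a
measurement as a Z-score — the number of covariate-specific standard
deviations it lies from the population mean — for male Arab and black
paediatric athletes aged 11–18 years.

## Models

**Structural measures** (LVIDd, IVSd, PWTd, LV mass, LV volume, aortic
root, LAD, LA volume) use an allometric mean in body surface area with an
additive chronological-age term:

    mean(BSA, age) = a · BSA^b + c · age
    rsd(BSA, age)  = d + e · BSA + f · age
    Z = (obs − mean) / rsd

The typography of the source equation admits a second parse with age in
the exponent, `a · BSA^(b + c·age)`.  Only the additive form reproduces
the published worked example (IVSd 8.5 mm, BSA 1.76 m², age 13 →
Z = 1.91; the exponent form gives ≈ 0.89), so additive is the default and
`exponent_age` is retained as a selectable variant.

**Functional measures** (transmitral Doppler velocities and ratios, TDI
annular velocities, E/e′ ratios) use a second-order polynomial of
chronological age:

    mean(age) = a·age² + b·age + c,    rsd(age) = d + e·age

**LVEF** shows no association with body size or age and is modelled as a
plain normal distribution; the lower reference limit is mean − 2·SD, i.e.
Z = −2 (1.96·SD is available via `LvefModel(n_sd=1.96)`).

Z-scores are always reported signed.  The published functional worked
example prints the magnitude (1.87) of what the equation yields as −1.87
(observed 4.3 below the predicted mean 6.24); `ZScoreResult.abs_z` exposes
the magnitude for display.

## Regressed SD (RSD)

Residual scatter is modelled as a linear function of the mean-model
covariates, estimated by ordinary least squares of scaled absolute
residuals.  Under normal errors E|r| = σ·√(2/π), so absolute residuals
must be multiplied by **√(π/2) ≈ 1.253** to be unbiased for σ.  (Source
descriptions of this procedure sometimes state the reciprocal factor
√(2/π); only √(π/2) produces fitted Z with unit variance, which our
calibration tests confirm to within 1% at n = 10⁵.)  The constant is
configurable (`estimate_rsd(k=...)`).  The fitted SD surface is floored at
a small positive value (default 1e-6) when evaluated; fitted models whose
RSD is non-positive anywhere on the fitted covariate hull are rejected at
construction.

## Fitting

* Structural: trust-region nonlinear least squares (SciPy `least_squares`,
  `trf`), tolerance 1e-10, max 200 iterations, deterministically
  initialised from a log–log regression of the measure on BSA (slope → b,
  exp(intercept) → a, c = 0).  No random restarts, so fits are exactly
  reproducible.  An optional single reweighted refit with weights 1/rsd²
  is available (`StructuralZ(reweight=True)`) and off by default, matching
  the single-pass procedure the models were originally built with.
* Functional: ordinary least squares on {age², age, 1}.
* LVEF: sample mean and SD; Shapiro–Wilk normality screen at α = 0.05
  (warning, never an abort); Pearson association screen against BSA,
  chronological and biological age at α = 0.01.
* Sample floor: 30 complete records per measure (configurable).  This is
  far below the ≥120-per-age-group design target of a real nomogram study
  and exists so the pipeline is exercisable on small inputs; it is logged.

### Identifiability caveat

Under the study covariate structure (BSA and age correlated ≈ 0.75, BSA
exponent b near zero for wall thickness), the three mean coefficients are
collinear: the fitted mean surface is estimated to ~1% but individual
near-zero coefficients (b, and the age slope c for IVSd) carry sampling
SEs comparable to or larger than their own magnitude at n = 417.
Recovery tests therefore assert the identifiable quantities — the scale
coefficient, the mean function, and the calibration of fitted Z — and
hold individual weak coefficients only to 3·SE sanity bounds.

## Diagnostics battery

A normative model is adequate when its Z-scores are independent of the
covariates it adjusted for.  For a Z vector the battery reports:

* Pearson correlation of Z with BSA, chronological age, biological age and
  heart rate; two-sided p from the t-distribution with n−2 df; effect
  flag at p ≤ 0.05, interaction flag at p ≤ 0.01.
* Pooled-variance two-sample t-test for an ethnicity effect, reporting the
  signed mean difference (black − arab; the direction convention is ours
  and is stated in the report).
* ΔR² for ethnicity-specific coefficients: R² of the pooled mean fit vs
  the combined R² of per-ethnicity fits, both against the grand total sum
  of squares so the delta is well defined; delta ≥ 5% is flagged
  clinically significant.
* Exceedance rates: % of each ethnicity with Z ≥ 2 and Z ≤ −2, boundary
  inclusive, denominator the non-missing Z per group.

No multiple-testing correction is applied across the battery — p-values
are deliberately raw screening statistics, as in the original adequacy
analyses this battery reproduces.  The same battery runs against
externally published equations (`ExternalModelSpec`), including the
log-linear BSA form `z = (ln obs − (α + β·ln BSA))/σ` used by
log-transformation-based references; the coefficient values of published
external models are user-supplied, never bundled.

Heart-rate dependence: peak A, E/A and septal a′ are known to retain a
residual HR association.  Their results carry an `hr_caution` flag and the
battery adds an HR note when the correlation is significant; no HR
normalisation is applied (HR-to-flow dynamics are too entangled for a
simple covariate adjustment, and Z remains age-adjusted regardless).

## Synthetic cohort generator

No public dataset exists for this population, so the generator is the
package's test bed and emulates the screening cohort's statistical
structure: 297 Arab + 120 black male athletes; age ~ Uniform(11, 18) y;
BSA = 0.5125 + 0.075·age + N(0, 0.13) m² truncated to [0.8, 2.4] by
per-record rejection (cohort mean ≈ 1.6, SD ≈ 0.20, corr(age, BSA) ≈
0.75); biological age = chronological + 1.0 y (+0.5 y extra in the black
group) + N(0, 0.6), matching the reported cohort means (biological 16.5 vs
16.0 y against chronological ≈ 15 y); HR = 95 − 1.5·age + N(0, 10) bpm.
Structural/functional measures are drawn from their model means with SD
equal to the model RSD; LVEF ~ N(60, 5.8)% independent of covariates (its
−2Z limit is then 48.4%).

Generating coefficients: IVSd and average E/e′ use the published
worked-example values as truth; all other entries in
`default_true_models()` are **synthetic inventions** at physiologically
plausible adolescent-athlete levels (e.g. LVIDd ≈ 48 mm, lateral e′ ≈
15 cm/s at mid-cohort covariates), chosen once and fixed.  They make the
pipeline exercisable; they are not clinical reference values.

What the generator does **not** emulate: inter-observer measurement error,
sport- and training-dose-specific remodelling, non-uniform age intake,
skewed or non-normal residuals, and missingness patterns.  Passing tests
therefore demonstrate the estimators and diagnostics are correct and
calibrated under the assumed model, not that the model family suffices
for any real population.

## Numerical choices

* BSA: Mosteller by default; DuBois and Haycock selectable; the formula
  used is recorded in every coefficient file so results are
  self-describing.
* Linear dimensions are stored in mm; the loader converts cm-declared
  columns.
* Out-of-envelope covariates set a warning flag on the result rather than
  raising — screening practice routinely meets boundary cases.
* Z is displayed to 2 dp; full precision is kept internally.
  `invert_z` is the exact algebraic inverse (identity to 1e-12).
* Missing optional covariates (biological age, HR) are represented as
  absent, never imputed; diagnostics that need them are skipped with a
  note.
* Longitudinal tracking flags |Z| ≥ 2 and a between-visit change
  |ΔZ| ≥ 1.5; the drift threshold is a configurable chart-review
  heuristic, not a validated clinical rule.

## Problem sizes used in the test suite

Calibration checks use n = 10⁵ residual draws (RSD estimator, exceedance
tails), n = 10⁴ cohorts for asymptotic normality of true-model Z, 20
replicate cohorts of n = 417 for parameter recovery, and 200 null
replicates for the type-I calibration of the covariate flags — sizes at
which the binomial/Monte-Carlo error of each checked quantity is small
relative to its tolerance.

## Known limitations

* Male 11–18 y Arab/black athletes only; nothing here transfers to
  female, white, younger or adult populations.
* The polynomial/allometric families are assumed, not selected; no
  LMS/GAMLSS-style flexible centile estimation.
* No bootstrap or profile confidence intervals on fitted coefficients.
* The command-line `calc` mirrors a clinic calculator but is not a
  medical device; outputs are screening aids, not diagnoses.
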