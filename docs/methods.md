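# Methods

## Process model

The condition is strictly congenital: a single compartment *C* of prevalent
cases is fed only by birth (birth prevalence *C*(0, *t*), a proportion of
births in calendar year *t*) and drained only by the excess-mortality
hazard *χ*(*a*, *t*) (deaths per person-year among prevalent cases at age
*a*, year *t*).  No later incidence, no remission, no protective effect.
On the discrete age × year grid (single-year ages, single calendar years)
the prevalence proportion is integrated along cohort characteristics with
exact per-step survival factors

    p(a, t) = p(a-1, t-1) * exp(-(chi(a-1, t-1) + chi(a, t)) / 2),

which is exact for piecewise-linear hazards and unconditionally positive.
Cohorts already alive at the left edge of the grid are handled by the
boundary rule that rates are constant across cohorts before the first data
year: their pre-window history uses the first year's hazard profile and
birth prevalence.  A logistic variant dp/da = −χ p (1−p) is available in
the solver for conditions where the rare-disease linearization is in doubt;
at prevalences near 3/1,000 the (1−p) correction is below 0.5% and the
linear form is the default throughout.

## Data model

Observations are cell-level rates: survey prevalence (positives /
respondents, one cell per age, sex, year) and cause-specific mortality
(CHD-coded deaths / midyear population).  An observation with value *y*,
effective sample size *n* and prediction *μ* contributes

    log(y + δ) ~ Normal( log(μ + δ) − μ / (2 n (μ + δ)²),  s² )
    s² = 1 / (n (μ + δ)) + τ²

* **Offset δ.**  Default is the half-count rule δ = 0.5/*n* per
  observation: log(count + ½) is nearly unbiased for the log mean even at
  the couple-of-events-per-cell sparsity the survey produces, and zero
  cells retain finite density (they are never dropped).  A fixed per-measure
  δ can be supplied via `ModelConfig.offset_delta`.
* **Mean correction.**  The second-order delta-method term
  −μ/(2n(μ+δ)²) accounts for E[log(k+c)] ≠ log(λ+c) at small expected
  counts λ; without it the fitted prevalence is biased low by roughly
  c/λ (≈20% at two expected events per cell).
* **Scale.**  1/(n(μ+δ)) is the delta-method sampling variance of the log
  rate (the reciprocal expected event count); τ (default 0.1) is a global
  log-scale dispersion absorbing extra-sampling noise.  During fitting the
  scales are frozen at the current iterate's predictions and the fit is
  repeated (3 reweighting passes by default).  Freezing matters: scales
  computed from observed values up-weight upward-fluctuated cells (+30%
  bias in simulation), while a μ-dependent s inside the objective rewards
  inflating predictions through the −log s term (+17% drift on noise-free
  data).  The standalone `loglik_offset_lognormal` keeps the plain density
  form (mean log(μ+δ), scale at μ) for direct use.

Predictions aggregate the surfaces over the observation's age interval with
population weights: mean of *p* for prevalence, mean of *p·χ* for mortality
rates.  Age-0 prevalence observations are excluded by default
(age-differential nonresponse in surveys of infants); the flag
`exclude_age_zero_prevalence` restores them.

## Priors / penalties

Second-order finite-difference penalties on the log surfaces, divided by
2σ² with σ = 1: for log χ across ages, along cohort diagonals, and a mixed
age×year cross difference (the "cross-smoothing" term is implemented as the
mixed second difference — an interpretation, since no formula is standard);
for log *p* along cohorts only.  The penalty is zero exactly when the log
surface is affine in each penalized direction, so it shrinks toward locally
log-linear age and period structure without fixing levels.

## Parameterization and optimization

Birth prevalence is a single free parameter per sex (constant over time,
the default) or one per year knot (`constrain_constant_birth_prevalence =
False`); both are kept because a time-specific *C*(0, *t*) and a
constant-birth-prevalence assumption are each defensible and the data here
cannot separate them.  log χ lives on knots — ages 0, 1, then every 5
years; calendar years every 5 — with bilinear interpolation to the grid.
All parameters are log-scale and box-bounded (χ ∈ [1e−8, 4] /yr,
birth prevalence ∈ [1e−7, 0.05]).

The objective (negative penalized log-likelihood) has an exact analytic
gradient: the cohort recursion is differentiated by a reverse (adjoint)
sweep over ages, so a full fit is a fraction of a second and the bootstrap
is cheap.  Optimization is L-BFGS-B from a deterministic start — crude
pooled rates, with the hazard age profile initialized by a short fixed
point χ(a) = crude_csmr(a)/p(a), re-solving p each pass (five passes).
Without the age-aware start the optimizer can drop into a basin where the
infant hazard collapses to zero.  Convergence uses ftol 1e−10 / projected
gradient 1e−6 with a 1,000-iteration cap; non-convergence is flagged on the
results object and warned, never silent.

## Synthetic data

`ScenarioConfig` defaults define the study conditions: death counts
1968–2010 and survey responses 1997–2011 (children under 18, age 0
included so the exclusion rule is exercisable), ages 0–100, both sexes.
Truth surfaces: birth prevalence 3.29 (male) and 3.23 (female) per 1,000,
constant over time; hazard

    chi(a, t) = (0.5 · exp(−a/2) + 0.01) · exp(−(ln 3 / 42)(t − 1968)),

i.e., infant-concentrated, near-flat in adulthood, log-linear in calendar
time, declining threefold across the window — matching the reported infant
mortality-rate decline of about 170 → 53 per 100,000 person-years.  Death
counts are Poisson with mean N·p·χ against a constant 2,000,000 population
per age/sex/year cell (the magnitude of a single-year US age class);
survey positives are Binomial(700, p) per cell — roughly double the
per-cell size of the real survey, whose cell counts are not published, and
chosen to give visibly noisy prevalence data (a couple of positives per
cell).  Each output table has its own (seed, table) random stream, so
identical configurations are byte-identical and adding a table perturbs
nothing.

What the generator does *not* emulate: multistage survey design, weights
and nonresponse; individual multiple-cause certificates (the tabulation
module has its own record-level fixtures); ICD-revision coding drift;
population age structure and migration (the population is flat in age and
time).  Passing tests therefore demonstrate correctness of the estimator
under a clean version of the data-generating process, not robustness to
real-data artifacts.

## Uncertainty

Parametric bootstrap: replicate datasets are drawn from the fitted data
model — log(y* + δ) ~ Normal(corrected mean at the point predictions, s²
at those predictions) — and refitted warm-started from the point estimate,
with scales kept frozen at the generating predictions (in a parametric
bootstrap those scales *are* the fitted model).  Draws are not clipped at
zero: the offset log-normal's support is y > −δ, and clipping shifts
replicate refits upward by several percent; prevalence draws are capped at
1 only.  Intervals are 2.5th/97.5th percentiles of replicates; derived
quantities (counts, banded aggregates) are computed per replicate and then
percentiled, so nonlinear aggregates are handled correctly.  Non-converged
replicates are dropped with a warning; more than 20% dropped is an error.
Default 1,000 replicates for production use, 100–200 in the test suite.

## Projection and aggregation

Past the data window, birth prevalence and χ are held constant across
cohorts (the final year's values) and the surface is re-solved on the
extended grid; extending and truncating back reproduces the original
surfaces.  Prevalent counts are p·N; if the population table stops short
of the horizon the last observed year is held constant with a warning.
Reporting bands: 0 (standing in for 0–51 weeks; sub-annual ages are not
modelled), 1–4, 5–9, 10–14, 15–19, 20–64 (the adult band; the upper bound
is configurable because published usage varies between 64 and 65), and
females 15–49.

Under constant post-window rates and a stationary population the adult age
profile converges to a fixed shape.  Convergence is slow by construction:
cohorts born during the declining-hazard window remain in the 20–64 band
for up to 64 years after rates freeze.  With the default scenario the
year-over-year change in adult prevalence per capita is still ≈0.65% per
year 40 years past the window (the acceptance script computes this) and
falls below 0.1% per year only ~65 years out, once in-window cohorts have
left the band (the projection tests compute this decay).  "Plateau" at the
40-year horizon therefore means visibly flattening growth, not completed
convergence.

## Simulation sizes in the test suite

Chosen as the package's own desk-scale study design: parameter recovery
uses 20 seeded replicates of the full default scenario (both sexes);
bootstrap coverage uses 50 seeded replicates × 200 bootstrap draws of a
reduced single-sex scenario (ages 0–70, deaths 1991–2010, survey
1997–2011, hazard knots at ages 0, 1, 5, 15, 30, 50, 70 and 10-year year
knots).  Moment checks on the generators use 1,000 seeded draws per cell.

## Known limitations

* Identifiability of adult χ rests entirely on the p·χ product plus
  smoothing: adult prevalence data do not exist in this design, so adult
  hazard errors of ±20% trade off against opposite prevalence errors.
* The offset log-normal is an approximation to the binomial/Poisson cell
  likelihoods; the half-count offset and mean correction remove the
  leading small-count bias but a few percent of residual bias remains at
  one expected event per cell.
* Bootstrap intervals inherit the smoothing prior's shrinkage; they are
  approximately calibrated for birth prevalence (checked by simulation)
  but not guaranteed for every derived functional.
* ICD code maps default to documented approximations of the cardiac
  anomaly ranges (745.0–747.49 / Q20–Q26, excluding peripheral vessels);
  the authoritative revision-specific lists should be supplied via a map
  file for production use.
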