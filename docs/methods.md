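# Methods

## The model

Follow-up time since diagnosis is split into intervals (Lexis expansion).
Person-interval `ik` carries observed deaths `d_ik` (0/1 individually, a
count after collapsing), person-time `y_ik`, and expected background
deaths `d*_ik = y_ik * rate(sex, attained age, calendar year, deprivation)`
from a population life table. The excess mortality rate is
`lambda+_ik = (d_ik - d*_ik) / y_ik`, and the model is log-linear in the
excess rate:

    d_ik ~ Poisson(mu_ik),    mu_ik = d*_ik + y_ik * exp(x_ik' beta).

Equivalently, a Poisson GLM with the non-canonical link `ln(mu - d*)` and
offset `ln(y)`. The baseline excess hazard is either piecewise constant
(interval indicators) or a restricted cubic spline of time on a finely
(monthly) split dataset. Exponentiated contrasts of `beta` are excess
mortality rate ratios (EMRRs).

Assumptions: the excess and background hazards add; the background rate is
known (life table) and constant within an interval; the excess rate is
constant within an interval times `exp(x'beta)`; no left truncation;
calendar time is decimal years.

## Estimation

Fisher scoring on the exact Poisson log-likelihood
`sum d ln(mu) - mu`:

* score `X' [(d/mu - 1) e]` and expected-information weights `e^2 / mu`,
  with `e = y * exp(x'beta)`;
* because the mean is parameterised as `d* + e` with `e > 0`, every
  iterate automatically satisfies `mu > d*` and the modified link stays
  defined — no feasibility projection is needed;
* step-halving whenever a proposed step would decrease the likelihood,
  plus a trust-region-style cap (max coefficient step 10) and a ridge
  fallback if the information matrix becomes numerically singular, which
  happens when a cell has no excess deaths and its coefficient drifts to
  the boundary (-inf). Such fits are flagged `converged = False` and the
  covariance uses a pseudo-inverse;
* starting values: all zeros except the intercept,
  `ln(max(sum(d - d*), 0.5 * sum(d)) / sum(y))`;
* convergence: relative log-likelihood change < 1e-10 *and*
  max |delta beta| < 1e-8, within 100 iterations. The spec of a
  convergence test matters here: with the OR of the two conditions the
  score at the reported optimum can still be ~1e-5.

Rows with `d < d*` (negative observed excess) are retained — the
likelihood is defined for any `d >= 0` — since discarding them would bias
the estimates. Zero-length rows are dropped at the splitting stage.

Two covariances are exposed: the inverse *observed* information (default,
`cov_model`) and the inverse *expected* information (`cov_expected`, the
classic IRLS covariance). They coincide when `d* = 0`.

### Collapsing

Grouped fitting sums `d`, `d*`, `y` over cells. With `exact=True` cells
are additionally keyed on the background rate `d*/y`, making the collapsed
likelihood equal to the individual one up to a constant (so coefficients
and model SEs reproduce to machine precision). With `exact=False` cells
are the plain covariate-by-interval cross-classification — the layout
registry analyses actually use — which is an approximation when background
rates vary within cells.

## Overdispersion

### Score test

The generated variable

    z_ik = ((lambda+ - lambda+_hat)^2 - lambda+) / lambda+_hat

is regressed on `lambda+_hat` without intercept (ordinary least squares);
the slope estimates `alpha` in `Var = E + alpha E^2`, and its t statistic
(one-sided, n - 1 df) is the test. This excess-rate-scale form is the
default (`scale="rate"`).

A structural caveat, verified by the calibration experiments in the test
suite: for a Poisson person-interval row, `Var(lambda+) = mu / y^2`, which
equals `E(lambda+)` only when `y = 1` and `d* = 0`. On grouped cells with
large person-time, `E[z] ≈ -1`; on individual rows with partial exposures
the `1/y` terms give z a heavy right tail. Either way the rate-scale z is
not centred under the Poisson null, so the test's type-I error is not the
nominal level (the suite measures ≈ 0.08 at a nominal 0.05 on 175-cell
layouts, with essentially no power against genuine rate heterogeneity).

For grouped data the package therefore also provides `scale="count"`:

    z_ik = ((d - mu_hat)^2 - d) / mu_hat   regressed on mu_hat,

which is centred under any Poisson model. It inherits a conservative bias
when the number of cells is small relative to the parameter count (fitted
means absorb part of the squared residuals), but it has real, monotone
power against rate heterogeneity and is what the simulation harness and
the demo report use.

### Dispersion parameter

`phi = chi^2 / df` with `df = rows - parameters`. Both Pearson
conventions are implemented:

* `pearson_rate` (default): `sum((lambda+ - lambda+_hat)^2 / lambda+_hat)`
  — the formula printed alongside the quasi-likelihood variance
  `phi (X'WX)^{-1}` with `W = diag(lambda+_hat)`;
* `pearson_count`: `sum((d - mu_hat)^2 / mu_hat)`.

The two differ by a person-time factor per row and are *not*
interchangeable. On grouped cells the rate-scale statistic scales like
`mean(1/y)` under the null (it can sit far below 1 for large cells and
explode on near-empty ones), so it does not estimate the variance
inflation of the counts; the count-scale statistic converges to 1 under
the Poisson model and to the true dispersion constant on
quasi-Poisson-generated data. Simulation harness, demo and coverage
corrections therefore use the count-scale phi; the rate-scale value is
always reported alongside.

### Corrected variances

* **Scaled (quasi-likelihood):** `cov = phi * cov_base`; every SE is
  multiplied by `sqrt(phi)` exactly.
* **Sandwich:** `(X'WX)^{-1} (X'SX) (X'WX)^{-1}` in two conventions.
  `"paper"`: `W = diag(lambda+_hat)`, `S = diag((lambda+ -
  lambda+_hat)^2)` — the formula on the excess-rate scale with unit
  person-time weights. `"irls"`: the exact estimating-equation form for
  this GLM — `W` the IRLS working weights `e^2/mu` and `S` the squared
  score contributions `((d - mu) e / mu)^2`; with `d* = 0` this equals the
  textbook HC0 robust variance of a Poisson rate regression (cross-checked
  against an independent implementation in the tests). The spec text
  reused the rate-scale `S` for both conventions, but only the
  score-based meat satisfies that cross-check, so that is what `"irls"`
  computes.
* **RLE:** per-coefficient `var_corrected / var_uncorrected`; equals phi
  identically for the scaled correction.

### NB2

Gamma (log-gamma intercept) heterogeneity of the excess rate gives
marginally negative binomial counts with `Var = mu + alpha mu^2` and the
same modified mean `mu = d* + y exp(x'beta)`. `alpha` is estimated from
the auxiliary regression (clamped at 0, where NB2 collapses to Poisson
exactly) and held fixed while `beta` is fitted by Fisher scoring on the
NB2 likelihood; a profile-likelihood `alpha` is available but not the
default, and `alpha` is not re-iterated after fitting. The covariance is
the inverse observed information at the optimum. Collapsed counts are
treated as NB2 with a common `alpha` (no exposure-dependent dispersion).

## Flexible baselines

Truncated-power restricted cubic splines: with boundary knots
`k_min < k_max` and interior knots `k_1..k_m`,

    z_1 = t
    z_{j+1} = (t - k_j)^3_+ - l_j (t - k_min)^3_+ - (1 - l_j)(t - k_max)^3_+
    l_j = (k_max - k_j) / (k_max - k_min),

cubic and C2 between the boundary knots, exactly linear outside. Default
knot placement: minimum, maximum and the 25th/50th/75th centiles of the
*uncensored* event times (equally spaced centiles for other knot counts),
using linear-interpolation sample quantiles — conventions differ between
packages at small n, so the rule is recorded in the `KnotSet`. Whether
censored exit times should enter the centiles is genuinely ambiguous; the
package follows the event-time reading and exposes the choice through the
`event_times` argument.

Flexible designs are built on monthly split data with time evaluated at
the midpoint of each row's person-time (configurable to interval entry).
Time-dependent effects are products of each spline column with each
non-reference covariate indicator. The raw truncated-power columns are
kept for transparency; a QR-orthonormalised variant (identical fitted
values, much better conditioning) is available via `orthogonalize=True`.
Untransformed time is the spline argument; log-time is available but off
by default. `EMRR(t)` between two covariate settings is
`exp(delta(t)' beta)` with pointwise delta-method intervals; times outside
the boundary knots extrapolate linearly and are flagged.

## The synthetic generator

Emulates a population-based breast-cancer registry: five age bands
(<50, 50-59, 60-69, 70-79, >=80; reference <50), five deprivation
quintiles (reference Q1), integer diagnosis years 1997-2005,
administrative censoring at 7 years. Background mortality is
`a exp(b*age)` with a multiplicative deprivation gradient and a mild
calendar drift (defaults a = 5e-5, b = 0.087, +5% per quintile, -1% per
year), yielding realistic female all-cause rates (~0.01 at 60, ~0.1 at
85). The default baseline excess hazard declines from 0.10 to 0.03 per
year over follow-up; the default log-EMRRs are ln(0.75), ln(0.88),
ln(1.71), ln(3.39) for age and ln(1.05), ln(1.16), ln(1.27), ln(1.48) for
deprivation — the magnitudes typical of deprivation gradients in breast
cancer survival. A smooth baseline and linear-in-time drifts of the
deprivation log-EMRRs support the flexible-model experiments.

Death times are drawn as competing exponentials within piecewise-constant
hazard segments (exact for piecewise hazards); ages at diagnosis are
integral so the generating background hazard agrees exactly with the
life-table lookup of the splitting module on any split nested in whole
years. Only all-cause exit and status are recorded — cause labels never
exist, matching the relative-survival premise.

**Frailty.** `frailty_theta` is the variance of a mean-1 gamma multiplier
on the excess hazard; `frailty_level` chooses where it lives.

* `"cell"` (default): an independent multiplier per age-band x quintile x
  follow-up-year cell, i.e. heterogeneity of the excess *rate* beyond the
  covariates (unmodelled spatial/institutional effects). Collapsed excess
  counts are then exactly gamma-mixed Poisson: `Var = mu + theta *
  mu_excess^2`, the E + alpha E^2 structure the overdispersion machinery
  targets. This is the mechanism used in the calibration, power and
  coverage experiments.
* `"subject"`: one multiplier per person — the classic survival frailty.
  Important negative result, verified by a dedicated test: because each
  subject dies at most once, person-level frailty leaves grouped counts
  essentially equidispersed (count-scale phi ≈ 1, no score-test power, no
  CI under-coverage even at theta = 1); it changes the shape of the
  marginal hazard rather than the dispersion of the counts. It is
  retained for contrast and for hazard-shape studies, but it cannot
  induce the overdispersion the correction methods address.

What the generator does **not** emulate: real English life tables, cohort
attrition other than administrative censoring, informative censoring,
period effects on the excess hazard, within-cell covariate measurement
error. Passing tests therefore demonstrate the estimators' behaviour
under a correctly-specified additive-hazards world with known background
rates, not robustness to life-table error or informative follow-up.

## Experiment sizes and numerical choices

Simulation experiments use cohorts of 500 subjects (score-test
calibration/power; 1000 and 200 replicates), 2000 subjects x 200
replicates (coverage repair), 8000 (dispersion reduction) and 20000 (EMRR
curve recovery and large-sample EMRR checks) — sizes at which the checked
asymptotics are visible while a full suite completes in minutes on one
CPU. Dispersion summaries across replicates are reported as medians:
chi-square/df on sparse cell layouts has a heavy right tail and a single
near-empty cell can dominate a mean. CI coverage uses the 1.96 normal
quantile. Shapiro-Wilk normality of standardized residuals is delegated
to scipy and subsampled above 4999 values. Ties between background and
excess death at identical times (probability zero) resolve to background.

## Known limitations

* The rate-scale score test and rate-scale phi are faithful to their
  printed definitions but statistically unreliable off the `y = 1, d* = 0`
  design; the count-scale forms are the recommended practice and the
  package makes both explicit rather than silently substituting.
* `alpha` for NB2 is a moment-style estimate, not ML; with few cells it
  can be badly negative (clamped) or inflated.
* No clustered sandwich, no HC1-HC3 small-sample corrections, no
  random-effects (true frailty-model) estimation, no period analysis, no
  cure models.
* Boundary MLEs (cells with no excess deaths) are flagged, not resolved;
  consider coarser intervals or merged cells in small samples.
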