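# peremfit

Excess-mortality (relative survival) regression for population-based
disease research, with tools to **test and correct for overdispersion**.

In registry studies the cause of death is unknown or unreliable, so the
mortality attributable to a disease is estimated by contrasting observed
all-cause deaths with the deaths *expected* from population life tables.
`peremfit` implements the piecewise exponential regression excess mortality
(PEREM) model in the GLM framework: follow-up since diagnosis is split into
intervals, and the death count of person-interval `ik` is modelled as
Poisson with mean

```
mu_ik = d*_ik + y_ik * exp(x_ik' beta)
```

where `d*_ik` is the expected number of background deaths (person-time
`y_ik` times the life-table rate) and `exp(x' beta)` is the excess
mortality rate `lambda+ = (d - d*) / y`. This is the "modified link"
`ln(mu - d*)` with offset `ln(y)`; exponentiated coefficients are excess
mortality rate ratios (EMRRs).

The Poisson assumption `Var(lambda+) = E(lambda+)` is often too strong:
heterogeneity of the excess rate beyond the covariates makes the variance
behave like `E + alpha*E^2` and silently shrinks standard errors. The
package provides:

* a regression-based **score test** for overdispersion (auxiliary
  no-intercept regression of a generated variable on the fitted rate), in
  the excess-rate-scale form and a count-scale form recommended for
  grouped data;
* the quasi-likelihood dispersion `phi = chi^2 / df` and **scaled**
  variances `phi * (X'WX)^-1`;
* **sandwich** (Huber–White) robust variances;
* **negative binomial (NB2)** regression with the same modified mean
  structure, `alpha` seeded from the auxiliary regression;
* **flexible PEREM models**: restricted cubic splines of follow-up time on
  finely split data, with time-dependent covariate effects and
  `EMRR(t)` curves with delta-method confidence bands;
* a **synthetic registry generator** (life table + cohort with known
  log-linear effects, optional gamma frailty on the excess rate, and
  administrative censoring) used as the test bed throughout, plus a
  replication harness for calibration/coverage experiments;
* per-coefficient **relative loss in efficiency** (RLE), the variance
  ratio of a corrected fit to the uncorrected one.

## Worked example

`peremfit demo` simulates a breast-cancer-shaped cohort (five age bands,
five deprivation quintiles, 7-year administrative censoring, gamma rate
heterogeneity theta = 0.5), fits models A (Poisson), B (scaled SE),
C (robust SE) and D (NB2) on collapsed person-interval cells, then a
flexible monthly-split spline model with a time-dependent deprivation
effect:

```
$ peremfit demo --n 10000 --theta 0.5 --seed 5
Piecewise exponential excess mortality models on a synthetic cohort
n = 10000 subjects, 4511 deaths, frailty variance theta = 0.5

score test (count scale): alpha_hat = 0.2245, t = 11.20, one-sided p = 1.433e-22
dispersion phi (count-scale Pearson/df) = 7.221; rate-scale = 0.050
Shapiro-Wilk p (standardized residuals) = 5e-05

A = Poisson, B = scaled SE, C = robust (sandwich) SE, D = NB2
term              A: EMRR       SE    B: SE     RLE%    C: SE     RLE%  D: EMRR       SE     RLE%
-------------------------------------------------------------------------------------------------
ageband[50-59]       0.84   0.0552   0.1484   722.05   0.1756  1011.01     0.87   0.1454   692.63
ageband[60-69]       0.56   0.0619   0.1664   722.05   0.1988  1030.04     0.63   0.1709   761.47
ageband[70-79]       1.43   0.0527   0.1417   722.05   0.2045  1503.00     1.44   0.1650   978.39
ageband[>=80]        2.44   0.0630   0.1694   722.05   0.1983   989.24     2.56   0.1911   918.53
dep[2]               0.83   0.0651   0.1751   722.05   0.2161  1100.28     0.84   0.1769   737.76
dep[3]               0.86   0.0638   0.1715   722.05   0.2266  1260.46     0.84   0.1748   750.43
dep[4]               1.46   0.0569   0.1528   722.05   0.2090  1350.47     1.30   0.1650   841.62
dep[5]               1.25   0.0585   0.1572   722.05   0.1928  1085.05     1.27   0.1685   829.55

flexible model (monthly split, 5 knots [0.0, 0.82, 1.7, 3.52, 7.0], time-dependent deprivation): phi = 8.637
EMRR(t) Q5 vs Q1 with 95% CI:
  t = 0.10y  EMRR = 1.81  (1.29, 2.55)
  ...
  t = 5.00y  EMRR = 1.52  (1.11, 2.07)
```

Reading the output: the score test rejects equidispersion decisively
(p ≈ 1e-22) — by construction, since the generator put gamma heterogeneity
(variance 0.5) on the excess rate. Model A's SEs are therefore too small;
scaling by `sqrt(phi)` (B), the sandwich estimator (C) and NB2 (D) all
widen them, at an efficiency loss (RLE, printed in percent: variance
inflated ~7–15x). The age-band EMRR point estimates wander around their
generating values (0.75, 0.88, 1.71, 3.39) by exactly the extra noise the
corrected intervals now acknowledge. The flexible model's `EMRR(t)` curve
tracks the deprivation effect over follow-up time.

The same steps are scriptable: `peremfit simulate`, `peremfit split`,
`peremfit fit [--family nb2] [--terms ...]`, `peremfit odtest`,
`peremfit correct --method scaled|sandwich`, or directly from Python via
`simulate_cohort`, `split_followup`, `merge_expected`, `collapse`,
`fit_perem`, `score_test`, `estimate_phi`, `scale_variance`,
`sandwich_variance`, `fit_negbin`, `place_knots`, `predict_emrr_over_time`.

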