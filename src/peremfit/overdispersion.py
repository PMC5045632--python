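"""Overdispersion: score test, dispersion estimate, corrected variances, RLE.

A Poisson excess-mortality model assumes the variance of the rate equals
its mean.  Heterogeneity of the rate parameter (e.g. unmodelled frailty)
makes the variance behave like E + alpha*E^2 instead; ignoring it leaves
the coefficients consistent but understates their standard errors.

This module provides, on top of a fitted PEREM model:

* a regression-based score test of H0: alpha = 0 vs H1: alpha > 0, built
  from the generated variable z = ((lp - lp_hat)^2 - lp) / lp_hat regressed
  on lp_hat without intercept (lp = observed excess rate, lp_hat = fitted);
* the quasi-likelihood dispersion phi = chi-square / df;
* scaled (quasi-Poisson) and sandwich (Huber-White) covariance corrections;
* the relative loss in efficiency (RLE), the per-coefficient variance ratio
  of a corrected fit to the uncorrected reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .perem import FitResult


@dataclass
class ScoreTestResult:
    """Auxiliary-regression score test for overdispersion."""

    alpha_hat: float
    t_stat: float
    p_value_one_sided: float
    n_obs: int
    per_obs_z: np.ndarray

    def reject(self, level: float = 0.05) -> bool:
        return self.p_value_one_sided < level


@dataclass
class DispersionEstimate:
    phi: float
    statistic_used: str
    df: int


@dataclass
class CorrectedVariance:
    """A corrected covariance matrix plus per-coefficient RLE vs the base fit."""

    method: str
    cov: np.ndarray
    se: np.ndarray
    rle: np.ndarray
    names: list


def score_test(fit: FitResult, scale: str = "rate") -> ScoreTestResult:
    """Test H0: Var(lambda_plus) = E(lambda_plus) against alpha > 0.

    The generated dependent variable z = ((lp - lp_hat)^2 - lp) / lp_hat is
    regressed on lp_hat through the origin; the slope estimates alpha in
    Var = E + alpha*E^2 and its t statistic (n - 1 df, one-sided) is the
    score test.  Rows with negative observed excess rates (d < dstar) enter
    as-is: the formula stays defined and excluding them would bias z.

    ``scale="rate"`` (default) uses the excess rates lp = (d - dstar)/y
    directly.  Note that for a Poisson row Var(lp) = mu/y^2 differs from
    E(lp) whenever y != 1 or dstar > 0, so the rate-scale z is not centred
    at zero under a Poisson generating model with heterogeneous person-time.
    ``scale="count"`` applies the same construction to the counts,
    z = ((d - mu_hat)^2 - d)/mu_hat regressed on mu_hat, which is centred
    under any Poisson model and is the recommended form on grouped data.
    """
    lp_hat = fit.lambda_plus_hat
    if np.any(lp_hat <= 0):
        raise ValueError("score test requires positive fitted excess rates")
    n = len(lp_hat)
    if n < 3:
        raise ValueError("score test undefined with fewer than 3 rows")
    if scale == "rate":
        obs, pred = fit.lambda_plus_obs, lp_hat
    elif scale == "count":
        obs, pred = fit.d, fit.mu_hat
    else:
        raise ValueError("scale must be 'rate' or 'count'")
    z = ((obs - pred) ** 2 - obs) / pred
    sxx = float(np.sum(pred**2))
    alpha = float(np.sum(z * pred) / sxx)
    resid = z - alpha * pred
    s2 = float(np.sum(resid**2) / (n - 1))
    se = np.sqrt(s2 / sxx)
    t = alpha / se if se > 0 else np.inf * np.sign(alpha)
    p = float(stats.t.sf(t, df=n - 1))
    return ScoreTestResult(alpha, float(t), p, n, z)


def estimate_phi(fit: FitResult, statistic: str = "pearson_rate") -> DispersionEstimate:
    """Dispersion parameter phi = chi-square / df.

    ``statistic`` selects the goodness-of-fit statistic: the rate-scale
    Pearson chi-square (default), the count-scale Pearson chi-square, or the
    deviance.  The two Pearson conventions differ by a person-time factor
    per row and generally disagree; the rate-scale form matches the quasi-
    likelihood variance function phi * lambda_plus.
    """
    if fit.df <= 0:
        raise ValueError("phi undefined: no residual degrees of freedom")
    stats_map = {
        "pearson_rate": fit.pearson_rate,
        "pearson_count": fit.pearson_count,
        "deviance": fit.deviance,
    }
    if statistic not in stats_map:
        raise ValueError(f"unknown statistic {statistic!r}")
    return DispersionEstimate(stats_map[statistic] / fit.df, statistic, fit.df)


def scale_variance(fit: FitResult, phi: float, use: str = "model") -> CorrectedVariance:
    """Quasi-likelihood correction: covariance scaled by phi, SEs by sqrt(phi)."""
    if np.isscalar(phi) is False and hasattr(phi, "phi"):
        phi = phi.phi
    if phi <= 0:
        raise ValueError("phi must be positive")
    base = fit.cov_model if use == "model" else fit.cov_expected
    cov = phi * base
    se = np.sqrt(np.diag(cov))
    rle_ = np.diag(cov) / np.diag(fit.cov_model)
    return CorrectedVariance("scaled", cov, se, rle_, fit.names)


def sandwich_variance(fit: FitResult, w_convention: str = "irls") -> CorrectedVariance:
    """Huber-White robust covariance (X'WX)^-1 (X'SX) (X'WX)^-1.

    Two conventions for the bread/meat are provided:

    ``"paper"``
        W = diag(lambda_plus_hat) and S = diag((lp - lp_hat)^2), the formula
        on the excess-rate scale with unit weights for person-time.
    ``"irls"``
        the exact modified-link fit: W are the IRLS working weights
        (y*lp_hat)^2 / mu and S the squared per-row score contributions
        ((d - mu) * y * lp_hat / mu)^2, i.e. the standard HC0 estimator for
        this GLM.  With dstar = 0 this equals the textbook robust variance
        of a Poisson rate regression.
    """
    X = fit.X
    lp = fit.lambda_plus_obs
    lp_hat = fit.lambda_plus_hat
    if w_convention == "paper":
        w = lp_hat
        meat_diag = (lp - lp_hat) ** 2
    elif w_convention == "irls":
        w = fit.W
        score = (fit.d - fit.mu_hat) * fit.y * lp_hat / fit.mu_hat
        meat_diag = score**2
    else:
        raise ValueError("w_convention must be 'paper' or 'irls'")
    bread_inv = X.T @ (X * w[:, None])
    try:
        bread = np.linalg.inv(bread_inv)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular X'WX") from err
    meat = X.T @ (X * meat_diag[:, None])
    cov = bread @ meat @ bread
    se = np.sqrt(np.diag(cov))
    rle_ = np.diag(cov) / np.diag(fit.cov_model)
    return CorrectedVariance("sandwich", cov, se, rle_, fit.names)


def rle(corrected: CorrectedVariance, reference: FitResult) -> np.ndarray:
    """Relative loss in efficiency: var_corrected / var_reference per coefficient.

    Interpreted as the proportional inflation of each coefficient's variance
    needed to account for overdispersion (1 = no loss).
    """
    if list(corrected.names) != list(reference.names):
        raise ValueError("coefficient sets of corrected and reference fits differ")
    return np.diag(corrected.cov) / np.diag(reference.cov_model)
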