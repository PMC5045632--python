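"""Negative binomial (NB2) excess-mortality regression.

Subject-level heterogeneity of the excess rate can be represented by a
multiplicative gamma (log-gamma intercept) random effect; marginally the
death counts then follow a negative binomial distribution whose variance is
mu + alpha*mu^2.  The mean keeps the modified structure of the Poisson
model, mu = dstar + y*exp(x'beta), so the Poisson PEREM model is recovered
exactly at alpha = 0.

The dispersion alpha is, by default, taken from the auxiliary regression of
the overdispersion score test (clamped at zero, since the NB2 variance
requires alpha >= 0) and held fixed while beta is estimated by maximum
likelihood; a profile-likelihood estimate of alpha is available as an
option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .model import CategoricalSpec
from .overdispersion import score_test
from .perem import FitError, FitResult, fit_perem


@dataclass
class NegBinFit:
    """A fitted NB2 excess-mortality model with fixed dispersion alpha."""

    alpha: float
    beta: np.ndarray
    names: list
    cov: np.ndarray
    mu_hat: np.ndarray
    lambda_plus_hat: np.ndarray
    loglik: float
    converged: bool
    source_fit: FitResult | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def estimate_alpha(fit: FitResult, scale: str = "rate") -> float:
    """NB2 dispersion seeded from the score test's auxiliary regression.

    The auxiliary slope estimates alpha in Var = E + alpha*E^2; negative
    slopes (under-dispersion) are clamped to zero, where the NB2 model
    collapses to Poisson.  ``scale`` is passed to :func:`score_test`; on
    grouped data with heterogeneous person-time the ``"count"`` scale is
    the consistent estimator of the NB2 dispersion of the counts.
    """
    alpha = score_test(fit, scale=scale).alpha_hat
    if alpha < 0:
        warnings.warn(
            "auxiliary regression slope is negative; alpha clamped to 0 "
            "(NB2 collapses to the Poisson model)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(alpha)


def _nb2_loglik_parts(d, mu, alpha):
    r = 1.0 / alpha
    return (
        special.gammaln(d + r)
        - special.gammaln(r)
        - special.gammaln(d + 1.0)
        + d * np.log(alpha * mu / (1.0 + alpha * mu))
        - r * np.log1p(alpha * mu)
    )


def fit_negbin(
    split: pd.DataFrame,
    spec: CategoricalSpec,
    alpha: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
    profile_alpha: bool = False,
) -> NegBinFit:
    """Fit the NB2 model with mean dstar + y*exp(x'beta) at fixed alpha.

    Parameters
    ----------
    alpha
        NB2 dispersion (>= 0).  If ``None`` it is estimated from the Poisson
        fit's auxiliary regression (:func:`estimate_alpha`); with
        ``profile_alpha=True`` it is instead chosen to maximise the profile
        likelihood.
    """
    poisson = fit_perem(split, spec, tol=tol)
    if alpha is None and not profile_alpha:
        alpha = estimate_alpha(poisson)
    if alpha is not None and alpha < 0:
        raise FitError("alpha must be non-negative")

    d = poisson.d
    dstar = poisson.dstar
    y = poisson.y
    X = poisson.X

    def loglik(beta, a):
        eta = np.clip(X @ beta, -700, 700)
        e = y * np.exp(eta)
        mu = dstar + e
        return float(np.sum(_nb2_loglik_parts(d, mu, a))), e, mu

    def solve_beta(a):
        """Fisher scoring with step-halving on the fixed-alpha NB2 likelihood."""
        beta = poisson.beta.copy()
        ll, e, mu = loglik(beta, a)
        ok = False
        for _ in range(max_iter):
            dldmu = d / mu - (1.0 + a * d) / (1.0 + a * mu)
            score = X.T @ (dldmu * e)
            w = e * e / (mu * (1.0 + a * mu))  # (dmu/deta)^2 / Var
            H = X.T @ (X * w[:, None])
            try:
                step = np.linalg.solve(H, score)
            except np.linalg.LinAlgError as err:
                raise FitError("singular NB2 information matrix") from err
            big = np.max(np.abs(step))
            if big > 10.0:
                step *= 10.0 / big
            factor = 1.0
            for _ in range(50):
                cand = beta + factor * step
                ll_c, e_c, mu_c = loglik(cand, a)
                if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                    break
                factor *= 0.5
            delta = np.max(np.abs(cand - beta))
            rel = abs(ll_c - ll) / (abs(ll) + 1e-12)
            beta, ll, e, mu = cand, ll_c, e_c, mu_c
            if rel < tol or delta < 1e-8:
                ok = True
                break
        return beta, ll, ok

    if profile_alpha:
        def prof(log_a):
            return -solve_beta(np.exp(log_a))[1]

        opt = optimize.minimize_scalar(prof, bounds=(-12, 5), method="bounded")
        alpha = float(np.exp(opt.x))

    if alpha == 0.0:
        return NegBinFit(
            alpha=0.0,
            beta=poisson.beta,
            names=poisson.names,
            cov=poisson.cov_model,
            mu_hat=poisson.mu_hat,
            lambda_plus_hat=poisson.lambda_plus_hat,
            loglik=poisson.loglik,
            converged=poisson.converged,
            source_fit=poisson,
        )

    beta, ll, ok = solve_beta(alpha)
    if not ok:
        warnings.warn(
            f"NB2 fit did not converge in {max_iter} iterations", RuntimeWarning, stacklevel=2
        )
    eta = X @ beta
    e = y * np.exp(eta)
    mu = dstar + e
    # observed information: second derivatives of the NB2 log-likelihood
    dldmu = d / mu - (1.0 + alpha * d) / (1.0 + alpha * mu)
    d2ldmu2 = -d / mu**2 + alpha * (1.0 + alpha * d) / (1.0 + alpha * mu) ** 2
    w = -(d2ldmu2 * e * e + dldmu * e)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    return NegBinFit(
        alpha=float(alpha),
        beta=beta,
        names=poisson.names,
        cov=cov,
        mu_hat=mu,
        lambda_plus_hat=np.exp(eta),
        loglik=ll,
        converged=ok,
        source_fit=poisson,
    )
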