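"""Piecewise exponential excess-mortality (PEREM) model fitting.

The model is a Poisson GLM on person-interval data with mean

    mu = dstar + y * exp(x' beta),

i.e. the "modified" link ln(mu - dstar) with offset ln(y): the linear
predictor models the log *excess* mortality rate lambda_plus = exp(x'beta),
while the expected background deaths dstar enter the mean additively.  With
dstar = 0 the model reduces to an ordinary Poisson rate regression.

Estimation is Fisher scoring (IRLS) on the exact Poisson log-likelihood
with step-halving whenever a step would decrease the likelihood.  Because
the mean is parameterised as dstar + y*exp(eta), fitted means always exceed
dstar and the modified link stays defined throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import CategoricalSpec, DesignError


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """A fitted PEREM model.

    Attributes
    ----------
    beta, names
        Coefficients on the log excess-rate scale and their column names.
    cov_model
        Model-based covariance: inverse observed information at the optimum.
    cov_expected
        Inverse expected (Fisher) information — the classic IRLS covariance.
    eta, lambda_plus_hat, mu_hat
        Linear predictor, fitted excess rate exp(eta) and fitted mean
        dstar + y*exp(eta) per row.
    W
        Diagonal IRLS working weights (y*exp(eta))^2 / mu.
    pearson_rate
        Rate-scale Pearson chi-square: sum((lp - lp_hat)^2 / lp_hat) with
        lp = (d - dstar)/y.
    pearson_count
        Count-scale Pearson chi-square: sum((d - mu)^2 / mu).
    """

    beta: np.ndarray
    names: list
    cov_model: np.ndarray
    cov_expected: np.ndarray
    eta: np.ndarray
    lambda_plus_hat: np.ndarray
    mu_hat: np.ndarray
    W: np.ndarray
    X: np.ndarray
    d: np.ndarray
    dstar: np.ndarray
    y: np.ndarray
    loglik: float
    deviance: float
    pearson_rate: float
    pearson_count: float
    df: int
    converged: bool
    iterations: int
    spec: object = None
    data: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        """Model-based standard errors (observed information)."""
        return np.sqrt(np.diag(self.cov_model))

    @property
    def lambda_plus_obs(self) -> np.ndarray:
        """Observed excess rate per row: (d - dstar) / y."""
        return (self.d - self.dstar) / self.y

    def summary(self) -> pd.DataFrame:
        se = self.se
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.beta,
                "se": se,
                "emrr": np.exp(self.beta),
                "emrr_lo": np.exp(self.beta - 1.96 * se),
                "emrr_hi": np.exp(self.beta + 1.96 * se),
            }
        )


def _poisson_loglik(d, mu):
    # constant terms (ln d!) dropped; 0*ln(0) treated as 0
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(mu), 0.0)
    return float(np.sum(term - mu))


def fit_perem(
    split: pd.DataFrame,
    spec: CategoricalSpec,
    tol: float = 1e-10,
    max_iter: int = 100,
    on_nonconvergence: str = "warn",
) -> FitResult:
    """Maximise the modified-link Poisson likelihood by Fisher scoring.

    Parameters
    ----------
    split
        Person-interval (or collapsed) data with columns ``d`` (deaths,
        non-negative), ``dstar`` (expected deaths, >= 0), ``y`` (person-time,
        > 0) and the covariates named by ``spec``.
    spec
        Design specification (:class:`~peremfit.model.CategoricalSpec` or
        :class:`~peremfit.splines.FlexibleSpec`).
    tol
        Convergence: relative change in log-likelihood below ``tol`` or
        max absolute coefficient update below 1e-8.
    """
    d = split["d"].to_numpy(dtype=float)
    dstar = split["dstar"].to_numpy(dtype=float) if "dstar" in split.columns else np.zeros(len(split))
    y = split["y"].to_numpy(dtype=float)
    if np.any(d < 0):
        raise FitError("negative death counts")
    if np.any(y <= 0):
        raise FitError("non-positive person-time; drop zero-length rows before fitting")
    if np.any(dstar < 0):
        raise FitError("negative expected deaths")

    X, names = spec.design(split)
    n, p = X.shape
    if n < p:
        raise FitError(f"{n} rows cannot identify {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise FitError("design matrix is rank deficient")

    excess_total = np.sum(d - dstar)
    if excess_total <= 0 and np.sum(d) == 0:
        raise FitError("no observed deaths: the excess rate is unidentifiable")
    start_num = max(excess_total, 0.5 * np.sum(d))
    beta = np.zeros(p)
    beta[0] = np.log(start_num / np.sum(y))

    eta = X @ beta
    e = y * np.exp(eta)
    mu = dstar + e
    ll = _poisson_loglik(d, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score = X.T @ ((d / mu - 1.0) * e)
        w = e * e / mu  # expected-information weights
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            # near-boundary iterates (cells with no excess deaths) can make
            # the information numerically singular; regularise the step
            ridge = 1e-10 * (np.trace(H) / p + 1.0)
            step = None
            for _ in range(12):
                try:
                    step = np.linalg.solve(H + ridge * np.eye(p), score)
                    break
                except np.linalg.LinAlgError:
                    ridge *= 100.0
            if step is None:  # pragma: no cover - ridge always succeeds
                raise FitError("singular information matrix")
        # trust-region-style cap: boundary drift (cells with no excess
        # deaths) can make near-singular information propose huge steps
        big = np.max(np.abs(step))
        if big > 10.0:
            step *= 10.0 / big
        # step-halving: retreat while the likelihood decreases or overflows
        factor = 1.0
        for _ in range(50):
            cand = beta + factor * step
            eta_c = X @ cand
            with np.errstate(over="ignore"):
                e_c = y * np.exp(np.clip(eta_c, -700, 700))
            mu_c = dstar + e_c
            ll_c = _poisson_loglik(d, mu_c)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            factor *= 0.5
        delta = cand - beta
        beta, eta, e, mu = cand, eta_c, e_c, mu_c
        rel = abs(ll_c - ll) / (abs(ll) + 1e-12)
        ll = ll_c
        if rel < tol and np.max(np.abs(delta)) < 1e-8:
            converged = True
            break
    if not converged:
        msg = f"PEREM fit did not converge in {max_iter} iterations"
        if on_nonconvergence == "raise":
            raise FitError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    lp_hat = np.exp(eta)
    w_exp = e * e / mu
    info_exp = X.T @ (X * w_exp[:, None])
    # observed information: -(d^2 ll / d beta^2)
    w_obs = d * e * e / mu**2 + e * (1.0 - d / mu)
    info_obs = X.T @ (X * w_obs[:, None])
    try:
        cov_model = np.linalg.inv(info_obs)
        cov_expected = np.linalg.inv(info_exp)
    except np.linalg.LinAlgError:
        # boundary MLE (a cell with no excess deaths drives its coefficient
        # to -inf); report the generalised inverse and flag the fit
        warnings.warn(
            "information matrix numerically singular at the optimum; "
            "covariance uses a pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        cov_model = np.linalg.pinv(info_obs)
        cov_expected = np.linalg.pinv(info_exp)
        converged = False

    lp_obs = (d - dstar) / y
    pearson_rate = float(np.sum((lp_obs - lp_hat) ** 2 / lp_hat))
    pearson_count = float(np.sum((d - mu) ** 2 / mu))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_term = np.where(d > 0, d * np.log(d / mu), 0.0)
    deviance = float(2.0 * np.sum(dev_term - (d - mu)))

    return FitResult(
        beta=beta,
        names=names,
        cov_model=cov_model,
        cov_expected=cov_expected,
        eta=eta,
        lambda_plus_hat=lp_hat,
        mu_hat=mu,
        W=w_exp,
        X=X,
        d=d,
        dstar=dstar,
        y=y,
        loglik=ll,
        deviance=deviance,
        pearson_rate=pearson_rate,
        pearson_count=pearson_count,
        df=n - p,
        converged=converged,
        iterations=it,
        spec=spec,
        data=split,
    )


def pearson_chi2_rate(fit: FitResult) -> float:
    """Rate-scale Pearson chi-square, sum((lp - lp_hat)^2 / lp_hat)."""
    lp_hat = fit.lambda_plus_hat
    if np.any(lp_hat <= 0):  # impossible for exp(eta); guarded regardless
        raise FitError("non-positive fitted excess rate")
    return float(np.sum((fit.lambda_plus_obs - lp_hat) ** 2 / lp_hat))


def predict_excess_rate(
    fit: FitResult,
    newdata: pd.DataFrame,
    cov: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Fitted excess rates exp(x'beta) with delta-method CIs on the log scale."""
    X, _ = fit.spec.design(newdata)
    eta = X @ fit.beta
    V = fit.cov_model if cov is None else cov
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, V, X))
    z = stats.norm.ppf(0.5 + level / 2)
    return pd.DataFrame(
        {
            "excess_rate": np.exp(eta),
            "lo": np.exp(eta - z * se),
            "hi": np.exp(eta + z * se),
            "se_log": se,
        }
    )


def emrr(
    fit: FitResult,
    x1: dict,
    x2: dict,
    cov: np.ndarray | None = None,
    level: float = 0.95,
) -> dict:
    """Excess mortality rate ratio between two covariate settings.

    EMRR = exp((x1 - x2)' beta); the CI is the delta-method interval on the
    log scale using the supplied covariance (model-based by default).
    """
    delta, _ = fit.spec.contrast(x1, x2)
    V = fit.cov_model if cov is None else cov
    logr = float(delta @ fit.beta)
    se = float(np.sqrt(delta @ V @ delta))
    z = stats.norm.ppf(0.5 + level / 2)
    return {
        "emrr": np.exp(logr),
        "lo": np.exp(logr - z * se),
        "hi": np.exp(logr + z * se),
        "se_log": se,
        "se_emrr": np.exp(logr) * se,  # delta method on the ratio scale
    }


def residual_diagnostics(fit: FitResult, max_shapiro: int = 4999, rng=None) -> dict:
    """Rate-scale standardized Pearson residuals and a normality check.

    Residuals are r = (lambda_plus - lambda_plus_hat) / sqrt(lambda_plus_hat),
    so that sum(r^2) equals the rate-scale Pearson chi-square.  The returned
    table pairs each residual with its fitted excess rate for the classic
    residual-vs-fitted heteroscedasticity plot; the Shapiro-Wilk p-value is
    computed on at most ``max_shapiro`` residuals (random subsample beyond).
    """
    lp_hat = fit.lambda_plus_hat
    resid = (fit.lambda_plus_obs - lp_hat) / np.sqrt(lp_hat)
    table = pd.DataFrame({"fitted_excess_rate": lp_hat, "residual": resid})
    sample = resid
    if len(sample) > max_shapiro:
        rng = np.random.default_rng(0) if rng is None else rng
        sample = rng.choice(sample, size=max_shapiro, replace=False)
    if np.allclose(sample, sample[0]):
        p = 1.0  # degenerate (e.g. perfect fit): nothing to test
    else:
        p = float(stats.shapiro(sample).pvalue)
    return {"table": table, "shapiro_p": p, "residuals": resid}
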