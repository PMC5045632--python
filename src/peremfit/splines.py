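"""Restricted cubic splines of follow-up time and flexible model designs.

The flexible excess-mortality model replaces the piecewise-constant
baseline by a smooth function of time: follow-up is split finely (monthly
by default) and the log baseline excess rate is a restricted (natural)
cubic spline, optionally interacted with covariates to give time-dependent
effects (non-proportional excess hazards).

The basis is the truncated-power form.  With boundary knots k_min < k_max
and interior knots k_1 < ... < k_m, the spline is

    s(t) = g0 + g1*z1 + ... + g_{m+1} z_{m+1},   z1 = t,
    z_{j+1} = (t - k_j)_+^3 - l_j (t - k_min)_+^3 - (1 - l_j)(t - k_max)_+^3,
    l_j = (k_max - k_j) / (k_max - k_min),

which is cubic between the boundary knots, C2-continuous everywhere, and
exactly linear outside [k_min, k_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CategoricalSpec, DesignError, _dummies


@dataclass(frozen=True)
class KnotSet:
    """Boundary and interior knots with a record of how they were placed."""

    boundary: tuple
    interior: tuple
    rule: str = "manual"

    def __post_init__(self):
        all_k = (self.boundary[0], *self.interior, self.boundary[1])
        if len(all_k) != len(set(all_k)) or list(all_k) != sorted(all_k):
            raise ValueError(f"knots must be strictly increasing, got {all_k}")
        if len(self.interior) < 1:
            raise ValueError("a restricted basis needs at least one interior knot")

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary[0], *self.interior, self.boundary[1]], dtype=float)

    @property
    def n_basis(self) -> int:
        """Number of basis columns, m + 1 for m interior knots."""
        return len(self.interior) + 1


def place_knots(event_times, n_knots: int = 5) -> KnotSet:
    """Place knots at the extremes and equally spaced centiles of event times.

    With the default ``n_knots = 5`` the boundary knots sit at the minimum
    and maximum and the interior knots at the 25th, 50th and 75th centiles
    of the (uncensored) event times; other counts use equally spaced
    centiles.  Quantiles follow the linear-interpolation convention of
    ``numpy.quantile`` (conventions differ between packages at small n).
    """
    t = np.asarray(event_times, dtype=float)
    t = t[np.isfinite(t)]
    if n_knots < 3:
        raise ValueError("need at least 3 knots for a restricted basis")
    if len(np.unique(t)) < n_knots:
        raise ValueError(
            f"need at least {n_knots} distinct event times, got {len(np.unique(t))}"
        )
    probs = np.linspace(0.0, 1.0, n_knots)
    ks = np.quantile(t, probs)
    if len(np.unique(ks)) < n_knots:
        raise ValueError("tied centiles: event times too concentrated for these knots")
    return KnotSet(
        boundary=(float(ks[0]), float(ks[-1])),
        interior=tuple(float(k) for k in ks[1:-1]),
        rule=f"centiles:{n_knots}",
    )


def rcs_basis(t, knots: KnotSet) -> np.ndarray:
    """Evaluate the restricted cubic spline basis z_1..z_{m+1} at times t."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    kmin, kmax = knots.boundary
    span = kmax - kmin
    cols = [t]
    for kj in knots.interior:
        lam = (kmax - kj) / span
        z = (
            np.maximum(t - kj, 0.0) ** 3
            - lam * np.maximum(t - kmin, 0.0) ** 3
            - (1.0 - lam) * np.maximum(t - kmax, 0.0) ** 3
        )
        cols.append(z)
    return np.column_stack(cols)


@dataclass
class FlexibleSpec:
    """Spline-baseline design with optional time-dependent covariate effects.

    Columns: intercept, the m+1 spline basis columns of follow-up time,
    indicator columns for each covariate in ``terms``, and — for every
    covariate in ``td_terms`` — products of each spline column with each
    non-reference level indicator.  Time is evaluated per row at the
    midpoint of the person-time in the interval (``time_eval="midpoint"``,
    the default) or at interval entry.

    ``orthogonalize=True`` replaces the raw truncated-power columns (plus
    intercept) by a QR-orthonormalised set spanning the same space: fitted
    values are identical, but the columns are far better conditioned.
    """

    terms: Sequence[str] = ()
    knots: KnotSet | None = None
    td_terms: Sequence[str] = ()
    time_eval: str = "midpoint"
    orthogonalize: bool = False
    log_time: bool = False
    levels: dict = field(default_factory=dict)
    _qr_transform: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        unknown = set(self.td_terms) - set(self.terms)
        if unknown:
            raise DesignError(f"time-dependent terms {sorted(unknown)} not among model terms")
        if self.time_eval not in ("midpoint", "start"):
            raise DesignError("time_eval must be 'midpoint' or 'start'")
        if self.knots is None:
            raise DesignError("FlexibleSpec requires a KnotSet")

    def _times(self, data: pd.DataFrame) -> np.ndarray:
        if "t" in data.columns:
            t = data["t"].to_numpy(dtype=float)
        elif self.time_eval == "midpoint":
            t = (data["tstart"].to_numpy() + data["tstop"].to_numpy()) / 2.0
        else:
            t = data["tstart"].to_numpy(dtype=float)
        return np.log(t) if self.log_time else t

    def _spline_block(self, t: np.ndarray) -> tuple[np.ndarray, list[str]]:
        Z = rcs_basis(t, self.knots)
        names = [f"rcs{j}" for j in range(1, Z.shape[1] + 1)]
        if self.orthogonalize:
            B = np.column_stack([np.ones(len(t)), Z])
            if self._qr_transform is None:
                q, r = np.linalg.qr(B)
                self._qr_transform = np.linalg.inv(r) * np.sqrt(len(t))
            Z = (B @ self._qr_transform)[:, 1:]
            names = [f"rcs{j}.orth" for j in range(1, Z.shape[1] + 1)]
        return Z, names

    def design(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        t = self._times(data)
        Z, znames = self._spline_block(t)
        blocks = [np.ones((len(data), 1)), Z]
        names = ["(Intercept)"] + znames
        for col in self.terms:
            if col not in self.levels:
                self.levels[col] = sorted(pd.unique(data[col]).tolist())
            Xc, nm = _dummies(data[col], self.levels[col], col)
            blocks.append(Xc)
            names.extend(nm)
            if col in self.td_terms:
                for i, zn in enumerate(znames):
                    blocks.append(Xc * Z[:, [i]])
                    names.extend(f"{n}:{zn}" for n in nm)
        return np.column_stack(blocks), names

    def contrast(self, x1: dict, x2: dict):  # pragma: no cover - thin guard
        raise DesignError(
            "time-dependent contrasts require predict_emrr_over_time, not a static contrast"
        )


def build_flexible_design(
    split_fine: pd.DataFrame,
    terms: Sequence[str],
    knots: KnotSet,
    td_terms: Sequence[str] = (),
    time_eval: str = "midpoint",
    orthogonalize: bool = False,
) -> tuple[FlexibleSpec, np.ndarray, list]:
    """Assemble a flexible design on finely split data.

    Returns the spec (reusable for fitting and prediction) together with the
    design matrix and column names evaluated on ``split_fine``.
    """
    spec = FlexibleSpec(
        terms=tuple(terms),
        knots=knots,
        td_terms=tuple(td_terms),
        time_eval=time_eval,
        orthogonalize=orthogonalize,
    )
    X, names = spec.design(split_fine)
    return spec, X, names


def predict_emrr_over_time(
    fit,
    contrast: tuple[dict, dict],
    times,
    cov: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """EMRR(t) between two covariate settings with pointwise delta-method CIs.

    ``contrast`` is a pair of covariate dictionaries (e.g. ``({"dep": 5},
    {"dep": 1})``).  Times outside the boundary knots are allowed — the
    spline extrapolates linearly there — and flagged in the output.
    """
    from scipy import stats

    spec: FlexibleSpec = fit.spec
    x1, x2 = contrast
    times = np.atleast_1d(np.asarray(times, dtype=float))

    def rows(setting):
        df = pd.DataFrame({"t": times})
        for col in spec.terms:
            if col not in setting:
                raise DesignError(f"contrast must set every model term; missing {col!r}")
            df[col] = setting[col]
        X, _ = spec.design(df)
        return X

    delta = rows(x1) - rows(x2)
    V = fit.cov_model if cov is None else cov
    logr = delta @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", delta, V, delta))
    z = stats.norm.ppf(0.5 + level / 2)
    kmin, kmax = spec.knots.boundary
    return pd.DataFrame(
        {
            "t": times,
            "emrr": np.exp(logr),
            "lo": np.exp(logr - z * se),
            "hi": np.exp(logr + z * se),
            "se_log": se,
            "extrapolated": (times < kmin) | (times > kmax),
        }
    )
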