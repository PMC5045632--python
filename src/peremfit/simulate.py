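"""Synthetic cohorts with known background mortality and excess hazards.

The generator emulates a population-based cancer registry study: women
diagnosed over a span of calendar years, five age bands and five
deprivation quintiles, background mortality taken from a life table
(exponential in age with a deprivation gradient and a mild calendar
trend), and a multiplicative excess hazard

    h_excess(t) = u * lambda0(t) * exp(x' beta),

with known log-linear covariate effects beta, a piecewise-constant (or
smooth) baseline lambda0 declining over follow-up, and an optional gamma
frailty u (mean 1, variance theta) that multiplies only the excess hazard
— heterogeneity of the excess rate is exactly the mechanism that produces
inherent overdispersion with marginal variance E + alpha*E^2.  Background
and excess death times are drawn as competing exponentials within
piecewise-constant hazard segments; all-cause exit time and status are
recorded, never the cause, matching the relative-survival premise.

Ages at diagnosis are integral and diagnosis years integer, so the
generating background hazard agrees exactly with the life-table lookup of
the splitting module (entry convention) on any split grid nested in whole
years of follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .model import CategoricalSpec
from .overdispersion import estimate_phi, sandwich_variance, scale_variance, score_test
from .perem import fit_perem
from .splitting import collapse as collapse_cells
from .splitting import merge_expected, split_followup

AGE_BAND_LABELS = ("<50", "50-59", "60-69", "70-79", ">=80")
AGE_BAND_RANGES = ((30, 49), (50, 59), (60, 69), (70, 79), (80, 94))


@dataclass(frozen=True)
class SimConfig:
    """True parameters of the synthetic registry cohort.

    Defaults mimic the shape of a breast-cancer registry illustration:
    five age bands (reference <50) and five deprivation quintiles
    (reference Q1) with log-linear effects on the excess rate, diagnosis
    years spanning 1997-2005, administrative censoring at 7 years, and a
    yearly piecewise-constant baseline excess hazard declining from
    0.10/year.  Background mortality is a * exp(b*age) with a multiplicative
    deprivation gradient and calendar drift.
    """

    n_subjects: int = 500
    age_band_probs: Sequence[float] = (0.25, 0.20, 0.25, 0.20, 0.10)
    dep_probs: Sequence[float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    #: log EMRR per age band vs <50
    beta_age: Sequence[float] = tuple(np.log([0.75, 0.88, 1.71, 3.39]))
    #: log EMRR per deprivation quintile vs Q1
    beta_dep: Sequence[float] = tuple(np.log([1.05, 1.16, 1.27, 1.48]))
    #: linear drift of the log EMRR per year of follow-up for Q2..Q5
    #: (time-dependent deprivation effect; 0 = proportional excess hazards)
    beta_dep_slope: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
    #: baseline excess hazard per follow-up year (events per person-year)
    baseline_excess: Sequence[float] = (0.10, 0.08, 0.06, 0.05, 0.04, 0.035, 0.03)
    #: optional smooth baseline lambda0(t); overrides ``baseline_excess`` and
    #: is applied on a piecewise-constant monthly grid
    smooth_baseline: Callable | None = None
    #: variance of the mean-1 gamma frailty on the excess hazard
    frailty_theta: float = 0.0
    #: where the frailty lives: "cell" draws an independent gamma multiplier
    #: for every (age band x deprivation x follow-up year) cell, i.e.
    #: heterogeneity of the excess *rate* beyond the covariates — this is the
    #: mechanism that makes collapsed excess counts marginally negative
    #: binomial, Var = mu + theta*mu_excess^2.  "subject" draws one frailty
    #: per person (the classic survival frailty); with at most one death per
    #: person it induces essentially no marginal overdispersion in grouped
    #: counts and is provided for contrast.
    frailty_level: str = "cell"
    t_max: float = 7.0
    years: tuple = (1997, 2005)
    #: background rate a*exp(b*age + g*(dep-1) + c*(year-year0))
    lt_a: float = 5e-5
    lt_b: float = 0.087
    lt_dep_gradient: float = 0.05
    lt_year_drift: float = -0.01
    seed: int | None = None

    def true_effects(self) -> dict:
        """Map design column names to generating log-EMRR values."""
        truth = {}
        for label, b in zip(AGE_BAND_LABELS[1:], self.beta_age):
            truth[f"ageband[{label}]"] = b
        for q, b in zip(range(2, 6), self.beta_dep):
            truth[f"dep[{q}]"] = b
        return truth


@dataclass
class SimResult:
    cohort: pd.DataFrame
    lifetable: LifeTable
    config: SimConfig
    truth: dict = field(default_factory=dict)


def make_lifetable(config: SimConfig) -> LifeTable:
    """Complete female life table covering every stratum the cohort can attain."""
    ages = np.arange(AGE_BAND_RANGES[0][0], AGE_BAND_RANGES[-1][1] + int(config.t_max) + 2)
    years = np.arange(config.years[0], config.years[1] + int(config.t_max) + 2)
    deps = np.arange(1, 6)
    grid = pd.MultiIndex.from_product([ages, years, deps], names=["age", "year", "dep"]).to_frame(
        index=False
    )
    rate = (
        config.lt_a
        * np.exp(config.lt_b * grid["age"])
        * np.exp(config.lt_dep_gradient * (grid["dep"] - 1))
        * np.exp(config.lt_year_drift * (grid["year"] - config.years[0]))
    )
    if np.any(rate <= 0) or not np.all(np.isfinite(rate)):
        raise ValueError("life-table parameters yield non-positive rates")
    table = grid.assign(sex="F", rate=rate)
    return LifeTable(table[["sex", "age", "year", "dep", "rate"]])


def _baseline_pieces(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Segment starts and per-segment baseline excess rates on [0, t_max)."""
    if config.smooth_baseline is not None:
        starts = np.arange(0.0, config.t_max, 1.0 / 12.0)
        mids = starts + 1.0 / 24.0
        return starts, np.asarray(config.smooth_baseline(mids), dtype=float)
    rates = np.asarray(config.baseline_excess, dtype=float)
    n_years = int(np.ceil(config.t_max))
    if len(rates) < n_years:
        raise ValueError(f"baseline_excess needs {n_years} yearly values")
    return np.arange(0.0, n_years, 1.0), rates[:n_years]


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimResult:
    """Draw a cohort under the configured excess-hazard model.

    Identical (config, seed) pairs reproduce the cohort exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    lifetable = make_lifetable(config)

    band_idx = rng.choice(5, size=n, p=np.asarray(config.age_band_probs) / np.sum(config.age_band_probs))
    lo = np.array([r[0] for r in AGE_BAND_RANGES])
    hi = np.array([r[1] for r in AGE_BAND_RANGES])
    age = rng.integers(lo[band_idx], hi[band_idx] + 1)
    dep = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.dep_probs) / np.sum(config.dep_probs))
    year_dx = rng.integers(config.years[0], config.years[1] + 1, size=n)

    beta_age = np.concatenate([[0.0], np.asarray(config.beta_age, dtype=float)])
    beta_dep = np.concatenate([[0.0], np.asarray(config.beta_dep, dtype=float)])
    log_emrr = beta_age[band_idx] + beta_dep[dep - 1]
    theta = config.frailty_theta
    if config.frailty_level not in ("cell", "subject"):
        raise ValueError("frailty_level must be 'cell' or 'subject'")
    n_years = int(np.ceil(config.t_max))
    if theta > 0 and config.frailty_level == "subject":
        u_subj = rng.gamma(1.0 / theta, theta, size=n)
    else:
        u_subj = np.ones(n)
    if theta > 0 and config.frailty_level == "cell":
        # one multiplier per (age band, quintile, follow-up year) cell
        u_cell = rng.gamma(1.0 / theta, theta, size=(5, 5, n_years))
    else:
        u_cell = np.ones((5, 5, n_years))

    piece_starts, piece_rates = _baseline_pieces(config)
    # segment grid: union of baseline pieces and whole years (background updates)
    seg_starts = np.unique(np.concatenate([piece_starts, np.arange(0.0, config.t_max)]))
    seg_starts = seg_starts[seg_starts < config.t_max]
    seg_stops = np.append(seg_starts[1:], config.t_max)
    piece_of = np.searchsorted(piece_starts, seg_starts, side="right") - 1

    exit_time = np.full(n, config.t_max)
    event = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for s0, s1, pk in zip(seg_starts, seg_stops, piece_of):
        if not alive.any():
            break
        idx = np.nonzero(alive)[0]
        k = int(np.floor(s0))
        h_bg = lifetable.lookup(
            np.full(len(idx), "F"), age[idx] + k, year_dx[idx] + k, dep[idx]
        )
        # time-dependent effects evaluated at the segment midpoint (the
        # hazard is piecewise-constant on the segment grid)
        slope = np.concatenate([[0.0], np.asarray(config.beta_dep_slope, dtype=float)])
        h_ex = (
            u_subj[idx]
            * u_cell[band_idx[idx], dep[idx] - 1, min(k, n_years - 1)]
            * piece_rates[pk]
            * np.exp(log_emrr[idx] + slope[dep[idx] - 1] * (s0 + s1) / 2.0)
        )
        t_bg = rng.exponential(1.0, size=len(idx)) / h_bg
        t_ex = rng.exponential(1.0, size=len(idx)) / h_ex
        t_die = np.minimum(t_bg, t_ex)
        dies = t_die < (s1 - s0)
        died_idx = idx[dies]
        exit_time[died_idx] = s0 + t_die[dies]
        event[died_idx] = 1
        alive[died_idx] = False

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age.astype(float),
            "sex": "F",
            "dep": dep,
            "year_dx": year_dx.astype(float),
            "time": exit_time,
            "status": event,
            "ageband": np.asarray(AGE_BAND_LABELS)[band_idx],
        }
    )
    truth = config.true_effects()
    truth["theta"] = config.frailty_theta
    return SimResult(cohort=cohort, lifetable=lifetable, config=config, truth=truth)


def default_spec() -> CategoricalSpec:
    """Interval + age band + deprivation, references <50 and Q1."""
    return CategoricalSpec(
        terms=("ageband", "dep"),
        baseline="interval",
        levels={"ageband": list(AGE_BAND_LABELS), "dep": [1, 2, 3, 4, 5]},
    )


def prepare_split(
    sim: SimResult,
    boundaries=None,
    collapse: bool = True,
) -> pd.DataFrame:
    """Split, merge expected deaths and (optionally) collapse a simulated cohort."""
    cfg = sim.config
    if boundaries is None:
        boundaries = np.arange(0.0, cfg.t_max + 1.0)
    split = split_followup(sim.cohort, boundaries, restriction=cfg.t_max)
    split = merge_expected(split, sim.lifetable)
    if collapse:
        split = collapse_cells(split, by=["ageband", "dep"], exact=False)
    return split


def recovery_experiment(
    config: SimConfig,
    n_reps: int,
    seed: int = 0,
    collapse: bool = True,
    boundaries=None,
    level: float = 0.05,
) -> dict:
    """Repeatedly simulate, fit and correct; summarise calibration.

    Per replicate the cohort is simulated, split, merged with its life
    table, optionally collapsed, and fitted with the Poisson PEREM model;
    the score test, the rate-scale dispersion estimate and the scaled and
    sandwich variance corrections are recorded along with 95% CI coverage
    of the generating log-EMRRs under each variance.

    Returns ``{"replicates": DataFrame, "summary": DataFrame}`` where the
    summary holds, per coefficient, bias, empirical SD, mean SE and CI
    coverage for model-based, scaled and sandwich variances, plus overall
    score-test rejection rate and mean phi.
    """
    rng = np.random.default_rng(seed)
    spec_proto = default_spec()
    truth = config.true_effects()
    rows = []
    failures: list[int] = []
    for rep in range(n_reps):
        sim = simulate_cohort(config, seed=int(rng.integers(2**31 - 1)))
        split = prepare_split(sim, boundaries=boundaries, collapse=collapse)
        spec = replace(spec_proto, levels=dict(spec_proto.levels))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_perem(split, spec)
        except Exception:
            failures.append(rep)
            continue
        if not fit.converged or fit.lambda_plus_hat.min() < 1e-12:
            failures.append(rep)
            continue
        st = score_test(fit)
        phi_rate = estimate_phi(fit, "pearson_rate").phi
        # variances are scaled by the count-scale phi: on grouped data with
        # heterogeneous person-time only the count-scale statistic estimates
        # the variance inflation of the counts (see docs/methods.md)
        phi = estimate_phi(fit, "pearson_count").phi
        scaled = scale_variance(fit, max(phi, 1e-12))
        sand = sandwich_variance(fit, "irls")
        for j, name in enumerate(fit.names):
            if name not in truth:
                continue
            b, se_m = fit.beta[j], np.sqrt(fit.cov_model[j, j])
            rows.append(
                {
                    "rep": rep,
                    "term": name,
                    "true": truth[name],
                    "estimate": b,
                    "se_model": se_m,
                    "se_scaled": scaled.se[j],
                    "se_sandwich": sand.se[j],
                    "phi": phi,
                    "phi_rate": phi_rate,
                    "score_p": st.p_value_one_sided,
                    "reject": st.p_value_one_sided < level,
                }
            )
    reps = pd.DataFrame(rows)

    def cover(se):
        return (np.abs(reps["estimate"] - reps["true"]) <= 1.96 * se).groupby(reps["term"]).mean()

    summary = pd.DataFrame(
        {
            "bias": (reps["estimate"] - reps["true"]).groupby(reps["term"]).mean(),
            "emp_sd": reps.groupby("term")["estimate"].std(),
            "mean_se_model": reps.groupby("term")["se_model"].mean(),
            "mean_se_scaled": reps.groupby("term")["se_scaled"].mean(),
            "mean_se_sandwich": reps.groupby("term")["se_sandwich"].mean(),
            "coverage_model": cover(reps["se_model"]),
            "coverage_scaled": cover(reps["se_scaled"]),
            "coverage_sandwich": cover(reps["se_sandwich"]),
        }
    )
    per_rep = reps.drop_duplicates("rep")
    summary.attrs["rejection_rate"] = float(per_rep["reject"].mean())
    summary.attrs["mean_phi"] = float(per_rep["phi"].mean())
    summary.attrs["n_failed"] = len(failures)
    return {"replicates": reps, "summary": summary, "failed_reps": failures}
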