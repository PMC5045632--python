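"""Lexis expansion of follow-up and merging of expected deaths.

Piecewise exponential excess-mortality models are fitted on person-interval
data: each subject's follow-up since diagnosis is split on a grid of
interval boundaries, and every resulting row carries the observed deaths
``d``, the person-time at risk ``y``, and — after merging a life table —
the expected number of background deaths ``dstar = y * expected_rate``.
The excess mortality rate of a row is ``lambda_plus = (d - dstar) / y``.

Conventions
-----------
* Intervals are half-open ``[start, end)``; a death falling exactly on a
  boundary ends follow-up in the earlier interval (no zero-length rows).
* Attained age and calendar year for the life-table lookup are evaluated at
  interval entry by default (``convention="entry"``) and floored to whole
  years; a midpoint convention is also available.
* Calendar time is decimal years throughout; no date arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lifetable import LifeTable, validate_cohort

#: columns every split dataset carries besides the cohort covariates
SPLIT_COLUMNS = ("interval", "tstart", "tstop", "y", "d", "attained_age", "attained_year")


def split_followup(
    cohort: pd.DataFrame,
    boundaries,
    restriction: float | None = None,
    convention: str = "entry",
) -> pd.DataFrame:
    """Split each subject's follow-up on a grid of interval boundaries.

    Parameters
    ----------
    cohort
        One row per subject with columns ``id``, ``age``, ``sex``, ``dep``,
        ``year_dx``, ``time`` (exit, years since diagnosis), ``status``.
    boundaries
        Increasing interval boundaries starting at 0, e.g. ``range(8)`` for
        yearly intervals up to 7 years.
    restriction
        Maximum follow-up; exits beyond it are administratively censored at
        the restriction.  Must not exceed the last boundary.
    convention
        Where within an interval attained age/year are evaluated for the
        life-table lookup: ``"entry"`` (default) or ``"midpoint"`` of the
        person-time actually spent in the interval.  Values are floored to
        whole years.

    Returns
    -------
    DataFrame with one row per subject per overlapped interval, carrying
    ``interval`` (0-based index), ``tstart``, ``tstop``, person-time ``y``,
    death indicator ``d`` (1 only in the final interval of subjects dying
    within the restriction window) and ``attained_age``/``attained_year``.
    """
    b = np.asarray(list(boundaries), dtype=float)
    if b.ndim != 1 or len(b) < 2 or np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be strictly increasing with at least two values")
    if b[0] != 0:
        raise ValueError("boundaries must start at 0")
    if restriction is None:
        restriction = float(b[-1])
    if restriction > b[-1]:
        raise ValueError("restriction must not exceed the last boundary")
    if convention not in ("entry", "midpoint"):
        raise ValueError("convention must be 'entry' or 'midpoint'")
    validate_cohort(cohort)

    exit_time = np.minimum(cohort["time"].to_numpy(dtype=float), restriction)
    # a death exactly at the restriction still counts; beyond it is censored
    event = (cohort["status"].to_numpy() == 1) & (
        cohort["time"].to_numpy(dtype=float) <= restriction
    )

    n = len(cohort)
    k = len(b) - 1
    starts = np.broadcast_to(b[:-1], (n, k))
    stops = np.broadcast_to(b[1:], (n, k))
    overlap_stop = np.minimum(stops, exit_time[:, None])
    y = overlap_stop - starts
    keep = y > 0

    rows_i, rows_k = np.nonzero(keep)
    yk = y[keep]
    tstart = starts[keep]
    tstop = tstart + yk  # end of the person-time actually at risk
    # event belongs to the final retained row of each subject
    counts = keep.sum(axis=1)
    last_idx = np.cumsum(counts) - 1
    d = np.zeros(len(rows_i), dtype=int)
    d[last_idx[counts > 0]] = event[counts > 0].astype(int)

    age = cohort["age"].to_numpy(dtype=float)[rows_i]
    year = cohort["year_dx"].to_numpy(dtype=float)[rows_i]
    t_eval = tstart if convention == "entry" else (tstart + tstop) / 2.0
    attained_age = np.floor(age + t_eval).astype(int)
    attained_year = np.floor(year + t_eval).astype(int)

    out = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy()[rows_i],
            "interval": rows_k,
            "tstart": tstart,
            "tstop": tstop,
            "y": yk,
            "d": d,
            "attained_age": attained_age,
            "attained_year": attained_year,
        }
    )
    for col in cohort.columns:
        if col not in ("id", "time", "status", "age", "year_dx"):
            out[col] = cohort[col].to_numpy()[rows_i]
    out["age_dx"] = age
    return out


def merge_expected(split: pd.DataFrame, lifetable: LifeTable) -> pd.DataFrame:
    """Attach expected deaths ``dstar = y * expected_rate`` to a split dataset.

    The expected rate is looked up at the (floored) attained age and calendar
    year recorded for each row and treated as constant within the interval.
    Raises if any row's stratum is absent from the life table.
    """
    rate = lifetable.lookup(
        split["sex"], split["attained_age"], split["attained_year"], split["dep"]
    )
    out = split.copy()
    out["expected_rate"] = rate
    out["dstar"] = out["y"].to_numpy() * rate
    return out


def excess_rate(split: pd.DataFrame) -> np.ndarray:
    """Observed excess mortality rate per row: (d - dstar) / y."""
    return (split["d"].to_numpy() - split["dstar"].to_numpy()) / split["y"].to_numpy()


def collapse(split: pd.DataFrame, by, exact: bool = True) -> pd.DataFrame:
    """Sum d, dstar and y over cells of categorical covariates x interval.

    With ``exact=True`` (default) cells are additionally keyed on the
    expected background rate, so the Poisson likelihood of the collapsed
    data differs from the individual-level one only by a constant: within a
    cell every row shares ``dstar/y``, hence the cell mean
    ``dstar + y*exp(x'b)`` factorises exactly and collapsed and individual
    fits coincide.  With ``exact=False`` cells are the plain covariate x
    interval cross-classification with summed expected deaths — the
    aggregated layout registries typically model — which is a (very close)
    approximation whenever background rates vary within cells.

    Parameters
    ----------
    split
        A merged split dataset (must carry ``dstar``).
    by
        Categorical covariate columns defining the cells (the interval index
        is always included).
    """
    by = list(by)
    for col in by:
        if col not in split.columns:
            raise KeyError(f"unknown covariate {col!r}")
        if pd.api.types.is_float_dtype(split[col]):
            raise ValueError(f"covariate {col!r} is continuous; collapse needs categorical keys")
    if "dstar" not in split.columns:
        raise ValueError("collapse requires a merged dataset carrying 'dstar'")

    work = split.copy()
    keys = by + ["interval"]
    if exact:
        work["_rate_key"] = np.round(work["dstar"].to_numpy() / work["y"].to_numpy(), 12)
        keys = keys + ["_rate_key"]
    grouped = work.groupby(keys, observed=True, sort=True)
    agg = grouped.agg(
        d=("d", "sum"),
        dstar=("dstar", "sum"),
        y=("y", "sum"),
        tstart=("tstart", "min"),
        tstop=("tstop", "max"),
        attained_age=("attained_age", "first"),
        attained_year=("attained_year", "first"),
    ).reset_index()
    if exact:
        agg["expected_rate"] = agg.pop("_rate_key")
    else:
        agg["expected_rate"] = agg["dstar"] / agg["y"]
    return agg
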