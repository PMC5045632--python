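"""Population life tables: expected background mortality lookup.

In the relative-survival framework the mortality attributable to a disease
is estimated by contrasting the observed all-cause mortality of a patient
cohort with the mortality expected in the general population.  The expected
component comes from national life tables stratified by sex, single year of
age, calendar year and (here) deprivation quintile.  This module reads such
tables from delimited text and exposes a vectorised rate lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column names used internally
LIFETABLE_COLUMNS = ("sex", "age", "year", "dep", "rate")


class LifeTableError(ValueError):
    """Raised for malformed life tables or unresolvable strata."""


@dataclass
class LifeTable:
    """Expected all-cause mortality rates per person-year by stratum.

    Parameters
    ----------
    table
        DataFrame with columns ``sex`` (category/str), ``age`` (int, single
        years), ``year`` (int calendar year), ``dep`` (deprivation quintile
        1-5) and ``rate`` (expected mortality rate per person-year, > 0).
    """

    table: pd.DataFrame
    _index: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in LIFETABLE_COLUMNS if c not in df.columns]
        if missing:
            raise LifeTableError(f"life table lacks columns {missing}")
        rates = df["rate"].to_numpy(dtype=float)
        if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
            bad = df.loc[~np.isfinite(rates) | (rates <= 0)]
            raise LifeTableError(
                f"expected rates must be positive and finite; offending rows:\n{bad.head()}"
            )
        dep = df["dep"].to_numpy()
        if not np.isin(dep, [1, 2, 3, 4, 5]).all():
            raise LifeTableError("deprivation quintile must be in 1..5")
        keyed = df.assign(
            age=df["age"].astype(int),
            year=df["year"].astype(int),
            dep=df["dep"].astype(int),
            sex=df["sex"].astype(str),
        )
        if keyed.duplicated(subset=["sex", "age", "year", "dep"]).any():
            raise LifeTableError("duplicate strata in life table")
        self.table = keyed
        self._index = keyed.set_index(["sex", "age", "year", "dep"])["rate"]

    def lookup(self, sex, age, year, dep) -> np.ndarray:
        """Vectorised expected-rate lookup; raises on any missing stratum."""
        sex = np.asarray(sex, dtype=str)
        age = np.asarray(age, dtype=int)
        year = np.asarray(year, dtype=int)
        dep = np.asarray(dep, dtype=int)
        idx = pd.MultiIndex.from_arrays([sex, age, year, dep])
        rates = self._index.reindex(idx).to_numpy(dtype=float)
        if np.isnan(rates).any():
            bad = idx[np.isnan(rates)].unique()
            raise LifeTableError(
                f"life table misses {len(bad)} strata, e.g. "
                f"{list(bad[: min(5, len(bad))])}"
            )
        return rates


def probability_to_rate(q):
    """Convert an annual death probability q to a rate via rate = -ln(1 - q)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise LifeTableError("annual death probabilities must lie in (0, 1)")
    return -np.log1p(-q)


def rate_to_probability(rate):
    """Inverse of :func:`probability_to_rate`: q = 1 - exp(-rate)."""
    return -np.expm1(-np.asarray(rate, dtype=float))


def read_lifetable(
    path,
    columns: dict[str, str] | None = None,
    probabilities: bool = False,
    sep: str = ",",
) -> LifeTable:
    """Read a popmort-style life table from delimited text.

    Parameters
    ----------
    path
        Delimited text file, one row per stratum.
    columns
        Mapping from canonical names ``{"sex", "age", "year", "dep", "rate"}``
        to the column names used in the file.  Omitted keys default to the
        canonical name itself.
    probabilities
        If True the ``rate`` column holds annual death probabilities q and is
        converted to rates via ``-ln(1 - q)``.
    """
    colmap = {c: c for c in LIFETABLE_COLUMNS}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise LifeTableError(f"life table file lacks columns {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[list(LIFETABLE_COLUMNS)]
    if probabilities:
        df = df.assign(rate=probability_to_rate(df["rate"]))
    return LifeTable(df)


#: canonical cohort column names
COHORT_COLUMNS = ("id", "age", "sex", "dep", "year_dx", "time", "status")


def read_cohort(path, columns: dict[str, str] | None = None, sep: str = ",") -> pd.DataFrame:
    """Read an individual patient cohort from delimited text.

    Expected columns (configurable through ``columns``): ``id``, ``age``
    (age at diagnosis, years), ``sex``, ``dep`` (quintile 1-5), ``year_dx``
    (calendar time of diagnosis, decimal years), ``time`` (years from
    diagnosis to exit, > 0) and ``status`` (all-cause death indicator 0/1).
    """
    colmap = {c: c for c in COHORT_COLUMNS}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise LifeTableError(f"cohort file lacks columns {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    if (df["time"] <= 0).any():
        raise ValueError("exit times must be > 0")
    if not df["status"].isin([0, 1]).all():
        raise ValueError("status must be 0 or 1")
    if not df["dep"].isin([1, 2, 3, 4, 5]).all():
        raise ValueError("deprivation quintile must be in 1..5")
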