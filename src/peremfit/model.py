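"""Design-matrix specifications for excess-mortality models.

Two specifications are provided.  :class:`CategoricalSpec` builds the
classic piecewise model: an intercept, indicator columns for the follow-up
interval (the piecewise-constant baseline) and indicator columns for each
categorical covariate, with the first level as reference.
:class:`FlexibleSpec` (see :mod:`peremfit.splines`) replaces the interval
indicators by a restricted cubic spline of follow-up time and can interact
the spline with covariates to give time-dependent effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class DesignError(ValueError):
    pass


def _dummies(values: pd.Series, levels, term: str) -> tuple[np.ndarray, list[str]]:
    """Indicator columns for every non-reference level, reference = first."""
    arr = np.asarray(values)
    unseen = set(np.unique(arr)) - set(levels)
    if unseen:
        raise DesignError(f"unseen level(s) {sorted(unseen)} for term {term!r}")
    cols = [(arr == lev).astype(float) for lev in levels[1:]]
    names = [f"{term}[{lev}]" for lev in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(arr), 0))), names


@dataclass
class CategoricalSpec:
    """Piecewise-constant baseline + categorical covariate effects.

    Parameters
    ----------
    terms
        Covariate column names; each is treated as categorical with its
        first (sorted, or as given in ``levels``) level as reference.
    baseline
        Column holding the interval index, parameterised as a categorical
        variable; ``None`` for an intercept-only baseline.
    levels
        Optional mapping term -> ordered levels (first = reference).  Levels
        are inferred from the data at first use and frozen thereafter, so
        prediction on new data uses the fitted coding.
    """

    terms: Sequence[str] = ()
    baseline: str | None = "interval"
    levels: dict = field(default_factory=dict)

    def _freeze_levels(self, data: pd.DataFrame) -> None:
        cols = ([self.baseline] if self.baseline else []) + list(self.terms)
        for col in cols:
            if col not in data.columns:
                raise DesignError(f"column {col!r} not in data")
            if col not in self.levels:
                self.levels[col] = sorted(pd.unique(data[col]).tolist())

    def design(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        self._freeze_levels(data)
        blocks = [np.ones((len(data), 1))]
        names = ["(Intercept)"]
        for col in ([self.baseline] if self.baseline else []) + list(self.terms):
            X, nm = _dummies(data[col], self.levels[col], col)
            blocks.append(X)
            names.extend(nm)
        return np.column_stack(blocks), names

    def contrast(self, x1: dict, x2: dict) -> tuple[np.ndarray, list[str]]:
        """Design-row difference between two covariate settings.

        Unspecified terms must coincide (they cancel); the baseline cancels
        unless explicitly set.
        """
        row = {}
        _, names = _design_names(self)
        for col, levels in self.levels.items():
            v1, v2 = x1.get(col), x2.get(col)
            if v1 != v2:
                for lev in levels[1:]:
                    row[f"{col}[{lev}]"] = float(v1 == lev) - float(v2 == lev)
        delta = np.zeros(len(names))
        for key, val in row.items():
            delta[names.index(key)] = val
        return delta, names


def _design_names(spec: CategoricalSpec) -> tuple[None, list[str]]:
    names = ["(Intercept)"]
    for col in ([spec.baseline] if spec.baseline else []) + list(spec.terms):
        names.extend(f"{col}[{lev}]" for lev in spec.levels[col][1:])
    return None, names
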