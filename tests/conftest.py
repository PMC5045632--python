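import numpy as np
import pandas as pd
import pytest

from peremfit import LifeTable


@pytest.fixture
def flat_lifetable():
    """Constant-rate life table: 0.01/year everywhere, ages 20-110, 1995-2015."""
    ages = np.arange(20, 111)
    years = np.arange(1995, 2016)
    deps = np.arange(1, 6)
    grid = pd.MultiIndex.from_product([ages, years, deps], names=["age", "year", "dep"]).to_frame(
        index=False
    )
    return LifeTable(grid.assign(sex="F", rate=0.01)[["sex", "age", "year", "dep", "rate"]])


@pytest.fixture
def small_cohort():
    """Five hand-written patients exercising censoring, death and restriction."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5],
            "age": [60.0, 59.4, 45.0, 80.0, 70.0],
            "sex": "F",
            "dep": [1, 2, 3, 4, 5],
            "year_dx": [2000.0, 2000.0, 2001.0, 2002.0, 2003.0],
            "time": [2.5, 1.3, 7.8, 0.4, 7.0],
            "status": [0, 1, 1, 1, 0],
        }
    )


@pytest.fixture
def toy_rate_fit():
    """Intercept-only fit with observed excess rates (0.2, 0.4, 0.3) and
    fitted rate 0.3 on every row (equal y and dstar per row)."""
    from peremfit import CategoricalSpec, fit_perem

    df = pd.DataFrame(
        {"d": [3, 5, 4], "dstar": [1.0, 1.0, 1.0], "y": [10.0, 10.0, 10.0]}
    )
    return fit_perem(df, CategoricalSpec(terms=(), baseline=None))
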