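import numpy as np
import pandas as pd
import pytest

from epichannel import SimulationConfig, simulate_cohort
from epichannel.aggregate import monthly_imr


def make_series(city_id, imr_by_year, months=range(1, 13)):
    """Monthly IMR series from {year: value-or-dict-or-list}; NaN = undefined."""
    rows = []
    for year, val in imr_by_year.items():
        for m in months:
            if isinstance(val, dict):
                imr = val.get(m, np.nan)
            elif isinstance(val, (list, tuple)):
                imr = val[m - 1]
            else:
                imr = val
            rows.append({"city_id": city_id, "year": year, "month": m, "imr": imr})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Two cities per stratum over 11 years; shared read-only fixture."""
    cfg = SimulationConfig(
        cities_per_group=(2, 2, 2, 2, 2, 2), year_start=2009, year_end=2019, seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_series(small_cohort):
    return monthly_imr(small_cohort.records)
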