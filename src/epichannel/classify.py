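"""IBGE population-size groups, group summaries, and consistency labels.

Brazilian municipalities are conventionally stratified into six
population-size classes. The cross-city dispersion (SD) of the annual
infant mortality rate within a class is used as a proxy for how reliably a
Shewhart-type epidemic channel behaves for cities of that size: a small SD
means city-level monthly rates are stable enough for mean +/- 1.96*SD
limits to be meaningful, a large SD means a handful of births or deaths
swings the rate by tens of points and the chart alarms on noise.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .aggregate import compute_imr
from .errors import InvalidSpecError

#: Inclusive population bounds of the six IBGE size classes. The top class
#: is open-ended; ``None`` marks the missing upper bound.
GROUP_BOUNDS: list[tuple[int, int | None]] = [
    (1, 10_000),
    (10_001, 20_000),
    (20_001, 50_000),
    (50_001, 100_000),
    (100_001, 500_000),
    (500_001, None),
]

GROUP_NAMES: list[str] = [
    "10,000 or less",
    "10,001 to 20,000",
    "20,001 to 50,000",
    "50,001 to 100,000",
    "100,001 to 500,000",
    "500,000 or more",
]

#: Consistency labels ordered from most to least reliable.
CONSISTENCY_LABELS: list[str] = [
    "consistent",
    "consistent/interpretable",
    "interpretable",
    "interpretable/inconsistent",
    "inconsistent",
]

#: Default upper bin edges on the cross-city IMR SD for the five labels
#: above; an SD above the last edge (or an undefined SD) is inconsistent.
DEFAULT_SD_BINS: tuple[float, float, float, float] = (3.5, 5.5, 8.0, 12.0)

# searchsorted cut points: population p falls in group i iff
# p <= _UPPER[i], with the last group unbounded.
_UPPER = np.array([b[1] for b in GROUP_BOUNDS[:-1]], dtype=np.int64)


def assign_group(population) -> int | np.ndarray:
    """Map a population (scalar or array) to its 1-based IBGE group index.

    A population of exactly 500,000 belongs to group 5 ("100,001 to
    500,000"); the open-ended top class starts at 500,001.
    """
    pop = np.asarray(population)
    if np.any(pop < 1):
        raise InvalidSpecError("population must be >= 1")
    group = np.searchsorted(_UPPER, pop, side="left") + 1
    if np.isscalar(population) or pop.ndim == 0:
        return int(group)
    return group.astype(int)


def classify_consistency(
    imr_sd: float, bins: Sequence[float] = DEFAULT_SD_BINS
) -> str:
    """Label a group by its cross-city IMR standard deviation.

    ``bins`` are the four ordered upper edges separating the five labels.
    An undefined (NaN) SD is inconsistent by definition: with no dispersion
    estimate there is no basis for trusting the chart.
    """
    if len(bins) != len(CONSISTENCY_LABELS) - 1 or list(bins) != sorted(bins):
        raise InvalidSpecError("bins must be 4 ordered SD edges")
    if imr_sd is None or (isinstance(imr_sd, float) and math.isnan(imr_sd)):
        return CONSISTENCY_LABELS[-1]
    if imr_sd < 0:
        raise InvalidSpecError("imr_sd must be non-negative")
    for edge, label in zip(bins, CONSISTENCY_LABELS):
        if imr_sd <= edge:
            return label
    return CONSISTENCY_LABELS[-1]


def annual_city_imr(records: pd.DataFrame, year: int) -> pd.DataFrame:
    """Per-city annual totals and IMR for one calendar year.

    Returns one row per city: population, births, deaths, imr (NaN when the
    city recorded no births that year).
    """
    sub = records[records["year"] == year]
    agg = (
        sub.groupby("city_id", sort=True)
        .agg(
            population=("population", "first"),
            births=("births", "sum"),
            deaths=("deaths", "sum"),
        )
        .reset_index()
    )
    agg["imr"] = compute_imr(agg["deaths"].to_numpy(), agg["births"].to_numpy())
    return agg


def summarize_groups(
    records: pd.DataFrame,
    year: int,
    bins: Sequence[float] = DEFAULT_SD_BINS,
) -> pd.DataFrame:
    """Build the six-row group-profile table for one study year.

    Per group: total population, number of cities, total births and infant
    deaths, the pooled rate 1000*sum(deaths)/sum(births), the unweighted
    cross-city mean and SD of annual city IMR (cities with zero births are
    excluded from the mean/SD but still counted in ``n_cities``), and the
    consistency label derived from that SD. The cross-city statistics, not
    the pooled rate, drive the label: the pooled rate is dominated by the
    largest cities and hides exactly the small-denominator instability the
    label is meant to expose.
    """
    cities = annual_city_imr(records, year)
    cities["group"] = assign_group(cities["population"].to_numpy())

    rows = []
    for g in range(1, 7):
        sub = cities[cities["group"] == g]
        births = int(sub["births"].sum())
        deaths = int(sub["deaths"].sum())
        imrs = sub["imr"].dropna()
        imr_mean = float(imrs.mean()) if len(imrs) >= 1 else math.nan
        imr_sd = float(imrs.std(ddof=1)) if len(imrs) >= 2 else math.nan
        rows.append(
            {
                "group": g,
                "group_name": GROUP_NAMES[g - 1],
                "total_population": int(sub["population"].sum()),
                "n_cities": int(len(sub)),
                "total_births": births,
                "total_deaths": deaths,
                "pooled_imr": compute_imr(deaths, births),
                "imr_mean": imr_mean,
                "imr_sd": imr_sd,
                "classification": classify_consistency(imr_sd, bins),
            }
        )
    return pd.DataFrame(rows)
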