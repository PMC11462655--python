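"""Temporal aggregation and infant mortality rate computation.

Two aggregation paths coexist on purpose. Generic rate series are averaged
over fixed windows of m observations (block means: daily -> weekly with
m = 7, daily -> monthly with m = 30). Vital *counts*, in contrast, are
summed within calendar months and the IMR is then a ratio of sums,
1000 * deaths / births per city-month; a mean of finer-grained ratios is
undefined whenever a sub-period has zero births, which in small cities is
the rule rather than the exception.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, InvalidCountError, InvalidWindowError

logger = logging.getLogger(__name__)

#: Canonical long-format column order for city-month vital records.
DATASET_COLUMNS = ["city_id", "population", "year", "month", "births", "deaths"]


def aggregate_mean(x, m: int) -> np.ndarray:
    """Block means of a raw series: y_j = mean(x[m*(j-1)+1 .. m*j]).

    The series is cut into consecutive windows of ``m`` observations and
    each window is replaced by its mean. A trailing partial window is
    dropped (a mean over fewer observations is not comparable to the full
    blocks) with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    if m < 1:
        raise InvalidWindowError(f"window size must be >= 1, got {m}")
    if x.ndim != 1 or len(x) < m:
        raise InvalidWindowError(
            f"series of length {x.size} is shorter than window {m}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidWindowError("series contains non-finite values")
    n_blocks = len(x) // m
    remainder = len(x) - n_blocks * m
    if remainder:
        logger.warning(
            "aggregate_mean: dropping %d trailing observation(s) not filling a window of %d",
            remainder,
            m,
        )
    return x[: n_blocks * m].reshape(n_blocks, m).mean(axis=1)


def compute_imr(deaths, births):
    """Infant mortality rate: deaths per 1,000 live births.

    Returns 1000 * deaths / births where births > 0 and NaN where
    births == 0 — an undefined rate, deliberately distinct from a rate of
    zero. Accepts scalars or arrays; scalar in, scalar out.
    """
    d = np.asarray(deaths, dtype=float)
    b = np.asarray(births, dtype=float)
    if np.any(d < 0) or np.any(b < 0):
        raise InvalidCountError("birth and death counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        imr = np.where(b > 0, 1000.0 * d / np.where(b > 0, b, 1.0), np.nan)
    if np.isscalar(deaths) and np.isscalar(births):
        return float(imr)
    return imr


def monthly_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Sum births/deaths into unique (city, year, month) cells.

    Part-records sharing a key are summed. Months missing inside a city's
    observed year range are materialized as zero-count rows (logged), so a
    city contributes one row per calendar month from its first to its last
    observed year. A city whose rows disagree on the population scalar is a
    data-integrity error.
    """
    if records.empty:
        return records.reindex(columns=DATASET_COLUMNS)

    pop_conflicts = records.groupby("city_id")["population"].nunique()
    bad = pop_conflicts[pop_conflicts > 1]
    if len(bad):
        raise DataIntegrityError(
            f"conflicting population values for city id(s): {list(bad.index)}"
        )

    agg = (
        records.groupby(["city_id", "year", "month"], sort=True)
        .agg(population=("population", "first"), births=("births", "sum"), deaths=("deaths", "sum"))
        .reset_index()
    )

    # Materialize every calendar month inside each city's observed span.
    frames = []
    n_created = 0
    for city, sub in agg.groupby("city_id", sort=True):
        y0, y1 = int(sub["year"].min()), int(sub["year"].max())
        grid = pd.MultiIndex.from_product(
            [[city], range(y0, y1 + 1), range(1, 13)], names=["city_id", "year", "month"]
        )
        full = sub.set_index(["city_id", "year", "month"]).reindex(grid)
        n_created += int(full["births"].isna().sum())
        full["population"] = full["population"].ffill().bfill()
        full[["births", "deaths"]] = full[["births", "deaths"]].fillna(0)
        frames.append(full.reset_index())
    if n_created:
        logger.info("monthly_counts: materialized %d missing month(s) as zero counts", n_created)

    out = pd.concat(frames, ignore_index=True)
    out["population"] = out["population"].astype(int)
    out["births"] = out["births"].astype(int)
    out["deaths"] = out["deaths"].astype(int)
    return out[DATASET_COLUMNS]


def monthly_imr(records: pd.DataFrame) -> pd.DataFrame:
    """City-month IMR series from raw vital records.

    Output columns: city_id, population, year, month, births, deaths, imr.
    ``imr`` is NaN exactly in zero-birth months.
    """
    counts = monthly_counts(records)
    counts = counts.copy()
    counts["imr"] = compute_imr(counts["deaths"].to_numpy(), counts["births"].to_numpy())
    return counts
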