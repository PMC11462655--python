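"""Epidemic-channel (Shewhart-type) control charts for monthly IMR series.

For a chosen study year, the baseline is the ten preceding calendar years.
For each calendar month separately, the baseline mean (MD) and sample
standard deviation (SD, n-1 denominator) of the defined monthly IMR values
are computed; the channel is [MD - z*SD, MD + z*SD] with z = 1.96, the
central-95% multiplier of a normal distribution, and the lower limit is
clipped at zero since a rate cannot be negative. A study-year observation
strictly outside the channel raises an alert; equality with a limit does
not. Months whose baseline has fewer than ``min_years`` usable values give
undefined limits and an "unassessable" verdict rather than silently
narrowing the chart.

Known epidemic periods must be removed from the baseline before the limits
are computed, otherwise the channel is widened by the very anomalies it is
meant to flag; removal is caller-supplied (an exclusion set), with an
optional one-pass self-trim behind an explicit flag.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import InsufficientHistoryError

logger = logging.getLogger(__name__)

DEFAULT_Z = 1.96
DEFAULT_WINDOW_YEARS = 10
DEFAULT_MIN_YEARS = 3
#: status = insufficient_history when more than this many of the 12 months
#: have undefined baseline statistics.
DEFAULT_MAX_UNDEFINED_MONTHS = 3
#: status = degenerate when at least this many months have SD = 0 driven by
#: an all-zero death history (MD = 0 as well).
DEFAULT_MIN_DEGENERATE_MONTHS = 6

CHART_COLUMNS = [
    "city_id",
    "study_year",
    "calendar_month",
    "md",
    "sd",
    "n_years_used",
    "lcl",
    "ucl",
    "observed",
    "alert",
    "status",
]


def exclude_periods(series: pd.DataFrame, exclusions) -> pd.DataFrame:
    """Mark (city_id, year, month) cells as unusable for baselines.

    ``exclusions`` is an iterable of triples or a DataFrame with columns
    city_id, year, month. Matching rows get imr = NaN in the returned copy;
    triples not present in the series are ignored with a warning.
    """
    out = series.copy()
    if exclusions is None:
        return out
    if isinstance(exclusions, pd.DataFrame):
        triples = list(
            exclusions[["city_id", "year", "month"]].itertuples(index=False, name=None)
        )
    else:
        triples = [tuple(t) for t in exclusions]
    if not triples:
        return out
    wanted = pd.MultiIndex.from_tuples(triples, names=["city_id", "year", "month"])
    keys = pd.MultiIndex.from_frame(out[["city_id", "year", "month"]])
    unknown = wanted.difference(keys)
    if len(unknown):
        logger.warning("exclude_periods: %d exclusion(s) match no record", len(unknown))
    mask = keys.isin(wanted)
    out.loc[mask, "imr"] = np.nan
    logger.info("exclude_periods: removed %d cell(s) from baselines", int(mask.sum()))
    return out


def _baseline_groupby(baseline: pd.DataFrame, by: list[str], min_years: int) -> pd.DataFrame:
    g = baseline.groupby(by)["imr"]
    stats = g.agg(md="mean", sd=lambda v: v.std(ddof=1), n_years_used="count")
    stats["n_years_used"] = stats["n_years_used"].astype(int)
    thin = stats["n_years_used"] < min_years
    stats.loc[thin, ["md", "sd"]] = np.nan
    return stats.reset_index()


def baseline_table(
    series: pd.DataFrame,
    study_year: int,
    window_years: int = DEFAULT_WINDOW_YEARS,
    min_years: int = DEFAULT_MIN_YEARS,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-city, per-calendar-month baseline MD/SD over the window.

    The window is the ``window_years`` calendar years strictly before
    ``study_year``; study-year data never enters the baseline. Zero-birth
    months (imr NaN) are excluded from the statistics; a month with fewer
    than ``min_years`` usable values gets undefined (NaN) MD/SD.

    With ``pooled=True`` a single MD/SD over all baseline months of the
    city is broadcast to all 12 calendar months (n_years_used then counts
    usable months / 12, floored at the month level).
    """
    lo, hi = study_year - window_years, study_year - 1
    baseline = series[(series["year"] >= lo) & (series["year"] <= hi)]

    cities = sorted(series["city_id"].unique())
    grid = pd.MultiIndex.from_product(
        [cities, range(1, 13)], names=["city_id", "calendar_month"]
    ).to_frame(index=False)

    if baseline.empty:
        stats = grid.assign(md=np.nan, sd=np.nan, n_years_used=0)
        return stats

    if pooled:
        per_city = _baseline_groupby(baseline, ["city_id"], min_years)
        # a pooled count is in usable months; express per calendar month
        per_city["n_years_used"] = per_city["n_years_used"] // 12
        thin = per_city["n_years_used"] < min_years
        per_city.loc[thin, ["md", "sd"]] = np.nan
        stats = grid.merge(per_city, on="city_id", how="left")
    else:
        bl = baseline.rename(columns={"month": "calendar_month"})
        per_month = _baseline_groupby(bl, ["city_id", "calendar_month"], min_years)
        stats = grid.merge(per_month, on=["city_id", "calendar_month"], how="left")

    stats["n_years_used"] = stats["n_years_used"].fillna(0).astype(int)
    return stats


def build_baseline(
    history: pd.DataFrame,
    study_year: int,
    window_years: int = DEFAULT_WINDOW_YEARS,
    min_years: int = DEFAULT_MIN_YEARS,
    pooled: bool = False,
) -> pd.DataFrame:
    """Twelve BaselineStats rows for a single-city history.

    Raises InsufficientHistoryError when the history has no rows inside the
    baseline window at all.
    """
    if history["city_id"].nunique() > 1:
        raise ValueError("build_baseline expects a single city; use baseline_table")
    lo, hi = study_year - window_years, study_year - 1
    if history.empty or not ((history["year"] >= lo) & (history["year"] <= hi)).any():
        raise InsufficientHistoryError(
            f"no history in baseline window [{lo}, {hi}]"
        )
    return baseline_table(history, study_year, window_years, min_years, pooled)


def compute_limits(stats: pd.DataFrame, z: float = DEFAULT_Z) -> pd.DataFrame:
    """Attach lcl/ucl columns: ucl = md + z*sd, lcl = max(0, md - z*sd).

    Undefined (NaN) statistics propagate to undefined limits.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    out = stats.copy()
    out["lcl"] = np.maximum(0.0, out["md"] - z * out["sd"])
    out["ucl"] = out["md"] + z * out["sd"]
    return out


def detect_alerts(study_series: pd.DataFrame, limits: pd.DataFrame) -> pd.DataFrame:
    """Join study-year observations onto limits and assign alert verdicts.

    Verdicts: "above" iff observed > ucl, "below" iff observed < lcl,
    "unassessable" iff observed or the limits are undefined, else "none".
    Equality with a limit is not an alert.
    """
    obs = study_series.rename(columns={"month": "calendar_month", "imr": "observed"})
    key = ["city_id", "calendar_month"] if "city_id" in limits.columns else ["calendar_month"]
    merged = limits.merge(
        obs[[*key, "observed"]], on=key, how="left"
    )
    undefined = merged["observed"].isna() | merged["ucl"].isna()
    merged["alert"] = np.select(
        [
            undefined,
            merged["observed"] > merged["ucl"],
            merged["observed"] < merged["lcl"],
        ],
        ["unassessable", "above", "below"],
        default="none",
    )
    return merged


def chart_status(
    baseline: pd.DataFrame,
    max_undefined_months: int = DEFAULT_MAX_UNDEFINED_MONTHS,
    min_degenerate_months: int = DEFAULT_MIN_DEGENERATE_MONTHS,
) -> str:
    """Overall usability verdict of one city's 12-month baseline.

    insufficient_history: more than ``max_undefined_months`` months have
    undefined MD/SD (too few usable baseline years). degenerate: at least
    ``min_degenerate_months`` months have SD = 0 with MD = 0 — an all-zero
    death history collapses the channel to a single point at zero, so any
    death at all fires an alert. Otherwise ok.
    """
    n_undefined = int(baseline["md"].isna().sum())
    if n_undefined > max_undefined_months:
        return "insufficient_history"
    zero = (baseline["sd"] == 0) & (baseline["md"] == 0)
    if int(zero.sum()) >= min_degenerate_months:
        return "degenerate"
    return "ok"


def build_chart_table(
    series: pd.DataFrame,
    study_year: int,
    window_years: int = DEFAULT_WINDOW_YEARS,
    z: float = DEFAULT_Z,
    min_years: int = DEFAULT_MIN_YEARS,
    exclusions=None,
    pooled: bool = False,
    trim: bool = False,
    max_undefined_months: int = DEFAULT_MAX_UNDEFINED_MONTHS,
    min_degenerate_months: int = DEFAULT_MIN_DEGENERATE_MONTHS,
) -> pd.DataFrame:
    """Full chart pipeline over a (possibly multi-city) monthly IMR series.

    Returns one row per (city, calendar month) with baseline statistics,
    control limits, the study-year observation, the alert verdict and the
    per-city status. ``trim=True`` performs one pass of self-exclusion:
    baseline points outside a provisional z-channel are dropped and the
    statistics recomputed — a crude stand-in when epidemic periods are not
    known a priori.
    """
    working = exclude_periods(series, exclusions) if exclusions is not None else series

    stats = baseline_table(working, study_year, window_years, min_years, pooled)

    if trim:
        prov = compute_limits(stats, z)
        lo, hi = study_year - window_years, study_year - 1
        baseline = working[(working["year"] >= lo) & (working["year"] <= hi)].copy()
        key = baseline.rename(columns={"month": "calendar_month"}).merge(
            prov, on=["city_id", "calendar_month"], how="left"
        )
        outside = (key["imr"] > key["ucl"]) | (key["imr"] < key["lcl"])
        n_trim = int(outside.fillna(False).sum())
        if n_trim:
            logger.info("build_chart_table: trimming %d baseline point(s)", n_trim)
            baseline.loc[outside.to_numpy(), "imr"] = np.nan
            rest = working[(working["year"] < lo) | (working["year"] > hi)]
            working = pd.concat([rest, baseline], ignore_index=True)
            stats = baseline_table(working, study_year, window_years, min_years, pooled)

    limits = compute_limits(stats, z)
    study = working[working["year"] == study_year]
    result = detect_alerts(study, limits)

    status = (
        result.groupby("city_id")
        .apply(
            lambda g: chart_status(g, max_undefined_months, min_degenerate_months),
            include_groups=False,
        )
        .rename("status")
        .reset_index()
    )
    result = result.merge(status, on="city_id", how="left")
    result["study_year"] = study_year
    return result[CHART_COLUMNS].sort_values(["city_id", "calendar_month"]).reset_index(
        drop=True
    )
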