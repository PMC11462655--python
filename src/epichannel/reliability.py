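"""Monte-Carlo operating characteristics of the epidemic channel by
population stratum.

The chart's nominal behaviour — 5% of stable months outside mean +/- 1.96
SD — assumes normal data and *known* parameters. In practice both fail:
limits are estimated from ten baseline points per calendar month, and in
small cities the monthly IMR is a ratio of tiny counts whose distribution
is a spike at zero plus rare enormous values. These functions quantify the
consequences: the false-alert rate in stable cities, the fraction of cities
whose chart is degenerate or has no usable history, and the power to
detect injected mortality shocks — each stratified by the six IBGE
population groups, which is where the consistent-to-inconsistent gradient
appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aggregate import monthly_imr
from .chart import (
    DEFAULT_MIN_YEARS,
    DEFAULT_WINDOW_YEARS,
    DEFAULT_Z,
    build_chart_table,
)
from .classify import annual_city_imr, assign_group
from .errors import InvalidSpecError
from .simulate import EpidemicSpec, SimulationConfig, inject_epidemic, simulate_cohort

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "group",
    "n_cities",
    "false_alert_rate",
    "unassessable_fraction",
    "degenerate_fraction",
    "detection_power",
    "imr_sd",
    "imr_mean",
    "replications",
    "seed",
]


@dataclass
class ReliabilityReport:
    """Per-group operating characteristics plus the provenance needed to
    reproduce them (replication count, master seed, chart settings)."""

    per_group: pd.DataFrame
    replications: int
    seed: int
    settings: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.per_group.empty


def empirical_coverage(mu: float, sigma: float, z: float, n: int, seed) -> float:
    """Fraction of n normal(mu, sigma) draws inside mu +/- z*sigma.

    With known parameters this converges to the nominal normal coverage
    (0.95 at z = 1.96) — the idealized benchmark the estimated-limits chart
    is compared against.
    """
    if sigma <= 0:
        raise InvalidSpecError("sigma must be > 0")
    if n < 1:
        raise InvalidSpecError("n must be >= 1")
    draws = np.random.default_rng(seed).normal(mu, sigma, size=n)
    return float(np.mean(np.abs(draws - mu) <= z * sigma))


def _rep_seed(seed: int, rep: int) -> int:
    # distinct, stable per-replication master seeds below 2**31
    return (seed * 100_003 + rep) % (2**31 - 1)


def _chart_for_cohort(records, study_year, chart_kwargs):
    series = monthly_imr(records)
    return build_chart_table(series, study_year=study_year, **chart_kwargs)


def _group_of_cities(cohort) -> pd.DataFrame:
    pops = cohort.records.groupby("city_id")["population"].first()
    return pd.DataFrame(
        {"city_id": pops.index, "group": assign_group(pops.to_numpy())}
    )


def _alert_tallies(chart: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    df = chart.merge(groups, on="city_id")
    df["assessable"] = df["alert"] != "unassessable"
    df["flagged"] = df["alert"].isin(["above", "below"])
    per_city = df.groupby(["group", "city_id"]).agg(
        n_assessable=("assessable", "sum"),
        n_flagged=("flagged", "sum"),
        n_months=("alert", "size"),
        status=("status", "first"),
    )
    return per_city.reset_index()


def false_alert_rate(
    config: SimulationConfig,
    replications: int = 1,
    seed: int = 0,
    study_year: int | None = None,
    window_years: int = DEFAULT_WINDOW_YEARS,
    z: float = DEFAULT_Z,
    min_years: int = DEFAULT_MIN_YEARS,
    **chart_kwargs,
) -> ReliabilityReport:
    """False-alert rate of the chart in cities with stable mortality.

    Runs the full pipeline (simulate -> monthly IMR -> baseline -> limits
    -> alerts) ``replications`` times with no injected anomalies. Per
    group it reports the fraction of *assessable* study-year months flagged
    (above or below), with the unassessable fraction alongside — in small
    cities undefined months would otherwise dominate and mask the
    phenomenon — plus the fraction of cities whose chart status is not ok
    and the cross-city SD of annual study-year IMR.
    """
    if config.epidemics:
        raise InvalidSpecError("false_alert_rate expects a stable (no-epidemic) config")
    if replications < 1:
        logger.error("false_alert_rate: replications must be >= 1; returning empty report")
        return ReliabilityReport(
            per_group=pd.DataFrame(columns=REPORT_COLUMNS),
            replications=replications,
            seed=seed,
        )
    sy = study_year if study_year is not None else config.year_end
    ck = dict(window_years=window_years, z=z, min_years=min_years, **chart_kwargs)

    tallies, imrs = [], []
    for rep in range(replications):
        cfg = replace(config, seed=_rep_seed(seed, rep))
        cohort = simulate_cohort(cfg)
        groups = _group_of_cities(cohort)
        chart = _chart_for_cohort(cohort.records, sy, ck)
        tallies.append(_alert_tallies(chart, groups))
        annual = annual_city_imr(cohort.records, sy).merge(groups, on="city_id")
        imrs.append(annual)

    tally = pd.concat(tallies, ignore_index=True)
    annual = pd.concat(imrs, ignore_index=True)
    rows = []
    for g in range(1, 7):
        sub = tally[tally["group"] == g]
        if sub.empty:
            continue
        n_assessable = int(sub["n_assessable"].sum())
        vals = annual.loc[annual["group"] == g, "imr"].dropna()
        rows.append(
            {
                "group": g,
                "n_cities": int(sub["city_id"].nunique()),
                "false_alert_rate": (
                    float(sub["n_flagged"].sum() / n_assessable) if n_assessable else np.nan
                ),
                "unassessable_fraction": float(
                    1.0 - sub["n_assessable"].sum() / sub["n_months"].sum()
                ),
                "degenerate_fraction": float((sub["status"] != "ok").mean()),
                "detection_power": np.nan,
                "imr_sd": float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan,
                "imr_mean": float(vals.mean()) if len(vals) else np.nan,
                "replications": replications,
                "seed": seed,
            }
        )
    return ReliabilityReport(
        per_group=pd.DataFrame(rows, columns=REPORT_COLUMNS),
        replications=replications,
        seed=seed,
        settings={"study_year": sy, **ck},
    )


def detection_power(
    config: SimulationConfig,
    replications: int = 1,
    seed: int = 0,
    death_multiplier: float = 3.0,
    epidemic_months: tuple[int, ...] = (4, 5, 6),
    study_year: int | None = None,
    window_years: int = DEFAULT_WINDOW_YEARS,
    z: float = DEFAULT_Z,
    min_years: int = DEFAULT_MIN_YEARS,
    **chart_kwargs,
) -> ReliabilityReport:
    """Power to flag injected mortality shocks, by population group.

    Every city gets its per-birth death probability multiplied by
    ``death_multiplier`` in the study-year months ``epidemic_months``
    (study-year cells are disjoint from the baseline window by
    construction). Power is the fraction of injected city-months whose
    verdict is "above"; only upward alerts count, since the injected
    anomaly is an excess-mortality event. At multiplier 1 the injection is
    a plain re-draw and power estimates the (upward) false-alert rate.
    """
    if replications < 1:
        logger.error("detection_power: replications must be >= 1; returning empty report")
        return ReliabilityReport(
            per_group=pd.DataFrame(columns=REPORT_COLUMNS),
            replications=replications,
            seed=seed,
        )
    sy = study_year if study_year is not None else config.year_end
    lo = sy - window_years
    if any(cfg_epi for cfg_epi in config.epidemics):
        logger.warning("detection_power: config already carries epidemics; adding more")
    ck = dict(window_years=window_years, z=z, min_years=min_years, **chart_kwargs)

    rows_per_rep = []
    for rep in range(replications):
        cfg = replace(config, seed=_rep_seed(seed, rep))
        cohort = simulate_cohort(cfg)
        groups = _group_of_cities(cohort)
        epi = EpidemicSpec(
            city_ids=tuple(sorted(cohort.city_map)),
            periods=tuple((sy, m) for m in epidemic_months),
            death_multiplier=death_multiplier,
        )
        if any(lo <= y < sy for y, _ in epi.periods):
            logger.warning(
                "detection_power: epidemic period inside the baseline window; "
                "limits will be contaminated"
            )
        records = cohort.records
        if cohort.cities:
            records = inject_epidemic(
                records, cohort.city_map, epi, seed=[_rep_seed(seed, rep), 104729]
            )
        chart = _chart_for_cohort(records, sy, ck)
        injected = chart[chart["calendar_month"].isin(epidemic_months)]
        df = injected.merge(groups, on="city_id")
        df["hit"] = df["alert"] == "above"
        df["assessable"] = df["alert"] != "unassessable"
        per_group = df.groupby("group").agg(
            n_cells=("hit", "size"),
            n_hits=("hit", "sum"),
            n_assessable=("assessable", "sum"),
            n_cities=("city_id", "nunique"),
        )
        rows_per_rep.append(per_group.reset_index())

    agg = (
        pd.concat(rows_per_rep, ignore_index=True)
        .groupby("group")
        .sum(numeric_only=True)
        .reset_index()
    )
    rows = []
    for _, r in agg.iterrows():
        rows.append(
            {
                "group": int(r["group"]),
                "n_cities": int(r["n_cities"]) // max(replications, 1),
                "false_alert_rate": np.nan,
                "unassessable_fraction": float(1.0 - r["n_assessable"] / r["n_cells"]),
                "degenerate_fraction": np.nan,
                "detection_power": float(r["n_hits"] / r["n_cells"]),
                "imr_sd": np.nan,
                "imr_mean": np.nan,
                "replications": replications,
                "seed": seed,
            }
        )
    return ReliabilityReport(
        per_group=pd.DataFrame(rows, columns=REPORT_COLUMNS),
        replications=replications,
        seed=seed,
        settings={
            "study_year": sy,
            "death_multiplier": death_multiplier,
            "epidemic_months": list(epidemic_months),
            **ck,
        },
    )
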