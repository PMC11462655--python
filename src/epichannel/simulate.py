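"""Synthetic city-month vital statistics with the stratified structure of
Brazilian municipal data.

Each simulated city has a fixed population, an annual crude birth rate and
a true infant mortality risk. Monthly live births are Poisson with mean
population * rate / 12000; infant deaths are Binomial(births, p) with
p = (true_imr / 1000) * (1 + a * sin(2*pi*(month-1)/12)), so deaths can
never exceed births and a zero-birth month necessarily has zero deaths.
Deaths are attached to same-month births — real infant deaths lag their
birth cohort by up to a year, but the ratio-instability phenomenon the
charts are evaluated on does not depend on that lag.

Cities are drawn in the six IBGE population strata; per-city RNG streams
are keyed on (master seed, group index, city index) so enlarging one group
never perturbs the series of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import DATASET_COLUMNS
from .classify import GROUP_BOUNDS
from .errors import DataIntegrityError, InvalidSpecError

#: Sampling cap for the open-ended "500,000 or more" stratum (Brazilian
#: municipal populations top out in the low millions).
TOP_GROUP_POPULATION_CAP = 6_000_000

#: Smallest simulated municipality; sub-thousand populations exist but are
#: demographically atypical and add nothing to the instability mechanism.
MIN_SIMULATED_POPULATION = 1_500


@dataclass(frozen=True)
class CitySpec:
    """Generative parameters of one city.

    annual_birth_rate is live births per 1,000 population per year;
    true_imr is the expected number of infant deaths per 1,000 live births;
    seasonality_amplitude multiplies the per-birth death probability by
    1 + a*sin(2*pi*(month-1)/12), peaking in spring months.
    """

    city_id: str
    population: int
    annual_birth_rate: float
    true_imr: float
    seasonality_amplitude: float = 0.0

    def __post_init__(self):
        if self.population < 1:
            raise InvalidSpecError(f"{self.city_id}: population must be >= 1")
        if self.annual_birth_rate <= 0:
            raise InvalidSpecError(f"{self.city_id}: annual_birth_rate must be > 0")
        if not 0 <= self.true_imr < 1000:
            raise InvalidSpecError(f"{self.city_id}: true_imr must be in [0, 1000)")
        if not 0 <= self.seasonality_amplitude < 1:
            raise InvalidSpecError(
                f"{self.city_id}: seasonality_amplitude must be in [0, 1)"
            )

    def mean_monthly_births(self) -> float:
        return self.population * self.annual_birth_rate / 12000.0

    def death_probability(self, month) -> np.ndarray | float:
        """Per-birth infant death probability in a calendar month."""
        m = np.asarray(month, dtype=float)
        season = 1.0 + self.seasonality_amplitude * np.sin(2 * np.pi * (m - 1) / 12.0)
        p = np.clip(self.true_imr / 1000.0 * season, 0.0, 1.0)
        return float(p) if np.isscalar(month) else p


@dataclass(frozen=True)
class EpidemicSpec:
    """Ground-truth anomaly: multiply the death probability in chosen
    (city, year, month) cells. Supports power studies of alert detection."""

    city_ids: tuple[str, ...]
    periods: tuple[tuple[int, int], ...]  # (year, month) pairs
    death_multiplier: float

    def __post_init__(self):
        if self.death_multiplier < 1:
            raise InvalidSpecError("death_multiplier must be >= 1")
        for _, m in self.periods:
            if not 1 <= m <= 12:
                raise InvalidSpecError(f"invalid month {m} in epidemic periods")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level configuration.

    cities_per_group gives counts for the six IBGE strata smallest-first.
    Per-city birth rates and true IMRs are drawn from truncated normal
    distributions around the group means; defaults echo national magnitudes
    (birth rate ~13.5/1,000/yr, IMR ~11.6/1,000 live births).
    """

    cities_per_group: tuple[int, int, int, int, int, int] = (5, 5, 5, 5, 5, 5)
    year_start: int = 2009
    year_end: int = 2020
    seed: int = 0
    birth_rate_mean: float = 13.5
    birth_rate_sd: float = 1.5
    imr_mean: float = 11.6
    imr_sd: float = 2.0
    seasonality_amplitude: float = 0.1
    epidemics: tuple[EpidemicSpec, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.cities_per_group) != 6 or any(c < 0 for c in self.cities_per_group):
            raise InvalidSpecError("cities_per_group must be six non-negative counts")
        if self.year_end < self.year_start:
            raise InvalidSpecError("year_end must be >= year_start")
        if self.birth_rate_mean <= 0 or not 0 <= self.imr_mean < 1000:
            raise InvalidSpecError("birth_rate_mean/imr_mean out of range")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


@dataclass
class Cohort:
    """A simulated dataset plus the specs that generated it."""

    records: pd.DataFrame
    cities: list[CitySpec]

    @property
    def city_map(self) -> dict[str, CitySpec]:
        return {c.city_id: c for c in self.cities}


def simulate_city(spec: CitySpec, years, seed) -> pd.DataFrame:
    """One row per calendar month for one city.

    ``years`` is an iterable of calendar years; ``seed`` any value accepted
    by numpy's SeedSequence. Identical (spec, years, seed) give identical
    output.
    """
    years = list(years)
    if not years:
        raise InvalidSpecError("year range must be non-empty")
    rng = np.random.default_rng(seed)
    yy = np.repeat(years, 12)
    mm = np.tile(np.arange(1, 13), len(years))
    births = rng.poisson(spec.mean_monthly_births(), size=len(yy))
    deaths = rng.binomial(births, spec.death_probability(mm))
    return pd.DataFrame(
        {
            "city_id": spec.city_id,
            "population": spec.population,
            "year": yy,
            "month": mm,
            "births": births,
            "deaths": deaths,
        }
    )[DATASET_COLUMNS]


def _sample_population(rng: np.random.Generator, group_index: int) -> int:
    """Log-uniform population inside the group's bounds (1-based index)."""
    lo, hi = GROUP_BOUNDS[group_index - 1]
    lo = max(lo, MIN_SIMULATED_POPULATION)
    hi = hi if hi is not None else TOP_GROUP_POPULATION_CAP
    pop = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    return min(max(pop, lo), hi)


def _city_spec(config: SimulationConfig, group_index: int, city_index: int) -> CitySpec:
    """Deterministic per-city attributes keyed off (seed, group, city)."""
    rng = np.random.default_rng([config.seed, group_index, city_index, 0])
    population = _sample_population(rng, group_index)
    rate = max(5.0, rng.normal(config.birth_rate_mean, config.birth_rate_sd))
    imr = min(max(1.0, rng.normal(config.imr_mean, config.imr_sd)), 999.0)
    return CitySpec(
        city_id=f"g{group_index}c{city_index:04d}",
        population=population,
        annual_birth_rate=rate,
        true_imr=imr,
        seasonality_amplitude=config.seasonality_amplitude,
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate all cities of all six strata; apply configured epidemics.

    Deterministic under a fixed config (including seed); each city's stream
    is independent of the others.
    """
    specs: list[CitySpec] = []
    frames: list[pd.DataFrame] = []
    for g, n_cities in enumerate(config.cities_per_group, start=1):
        lo, hi = GROUP_BOUNDS[g - 1]
        hi = hi if hi is not None else TOP_GROUP_POPULATION_CAP
        for i in range(n_cities):
            spec = _city_spec(config, g, i)
            if not lo <= spec.population <= hi:
                raise DataIntegrityError(
                    f"{spec.city_id}: population {spec.population} outside group {g} bounds"
                )
            specs.append(spec)
            frames.append(
                simulate_city(spec, config.years, seed=[config.seed, g, i, 1])
            )
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=DATASET_COLUMNS)
    cohort = Cohort(records=records, cities=specs)
    for k, epi in enumerate(config.epidemics):
        cohort = Cohort(
            records=inject_epidemic(
                cohort.records, cohort.city_map, epi, seed=[config.seed, 7919, k]
            ),
            cities=cohort.cities,
        )
    return cohort


def inject_epidemic(
    records: pd.DataFrame,
    city_map: dict[str, CitySpec],
    spec: EpidemicSpec,
    seed,
) -> pd.DataFrame:
    """Re-draw deaths in the targeted cells with a multiplied probability.

    All non-targeted cells are returned unchanged; deaths <= births is
    preserved because the re-draw is Binomial(births, min(1, mult*p)).
    """
    for city_id in spec.city_ids:
        if city_id not in city_map:
            raise LookupError(f"unknown city id {city_id!r}")
    out = records.copy()
    rng = np.random.default_rng(seed)
    targets = pd.MultiIndex.from_tuples(
        [(c, y, m) for c in spec.city_ids for (y, m) in spec.periods],
        names=["city_id", "year", "month"],
    )
    keys = pd.MultiIndex.from_frame(out[["city_id", "year", "month"]])
    missing = targets.difference(keys)
    if len(missing):
        raise LookupError(f"no record for cell(s): {list(missing)[:5]}")
    mask = keys.isin(targets)
    rows = out.loc[mask]
    p = np.array(
        [
            min(1.0, city_map[c].death_probability(m) * spec.death_multiplier)
            for c, m in zip(rows["city_id"], rows["month"])
        ]
    )
    out.loc[mask, "deaths"] = rng.binomial(rows["births"].to_numpy(), p)
    return out
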