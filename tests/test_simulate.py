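"""Generative model of the synthetic vital-statistics simulator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epichannel import (
    CitySpec,
    EpidemicSpec,
    SimulationConfig,
    inject_epidemic,
    simulate_city,
    simulate_cohort,
)
from epichannel.classify import GROUP_BOUNDS
from epichannel.errors import InvalidSpecError


def test_invalid_specs_rejected():
    with pytest.raises(InvalidSpecError):
        CitySpec("x", population=0, annual_birth_rate=13.5, true_imr=10)
    with pytest.raises(InvalidSpecError):
        CitySpec("x", population=100, annual_birth_rate=0, true_imr=10)
    with pytest.raises(InvalidSpecError):
        CitySpec("x", population=100, annual_birth_rate=13.5, true_imr=1000)
    with pytest.raises(InvalidSpecError):
        CitySpec("x", 100, 13.5, 10, seasonality_amplitude=1.0)


def test_zero_imr_means_zero_deaths():
    spec = CitySpec("z", population=50_000, annual_birth_rate=13.5, true_imr=0.0)
    rec = simulate_city(spec, range(2009, 2019), seed=1)
    assert (rec["deaths"] == 0).all()
    assert len(rec) == 120


def test_simulation_is_deterministic():
    spec = CitySpec("d", population=8_000, annual_birth_rate=12.0, true_imr=15.0)
    a = simulate_city(spec, range(2009, 2012), seed=42)
    b = simulate_city(spec, range(2009, 2012), seed=42)
    pd.testing.assert_frame_equal(a, b)


def test_zero_birth_month_frequency_matches_poisson_mass():
    # mean monthly births 0.5 -> P(births = 0) = exp(-0.5) ~ 0.6065
    spec = CitySpec("p", population=3_000, annual_birth_rate=2.0, true_imr=11.6)
    assert spec.mean_monthly_births() == pytest.approx(0.5)
    rec = simulate_city(spec, range(0, 850), seed=5)  # 10,200 months
    frac = (rec["births"] == 0).mean()
    n = len(rec)
    p = math.exp(-0.5)
    assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)


def test_large_city_aggregate_imr_converges_to_truth():
    spec = CitySpec(
        "big", population=1_000_000, annual_birth_rate=13.5, true_imr=12.0,
        seasonality_amplitude=0.0,
    )
    rec = simulate_city(spec, range(2010, 2020), seed=9)  # 120 months
    births, deaths = rec["births"].sum(), rec["deaths"].sum()
    imr = 1000 * deaths / births
    se = 1000 * math.sqrt(0.012 * (1 - 0.012) / births)
    assert abs(imr - 12.0) < 3 * se


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    population=st.integers(1_500, 200_000),
    imr=st.floats(0, 60),
    amplitude=st.floats(0, 0.5),
    seed=st.integers(0, 2**16),
)
def test_deaths_never_exceed_births(population, imr, amplitude, seed):
    spec = CitySpec("h", population, 13.5, imr, seasonality_amplitude=amplitude)
    rec = simulate_city(spec, range(2015, 2018), seed=seed)
    assert (rec["deaths"] <= rec["births"]).all()
    assert (rec[["births", "deaths"]] >= 0).all().all()


def test_cohort_respects_group_bounds_and_determinism():
    cfg = SimulationConfig(cities_per_group=(3, 3, 3, 3, 3, 3), year_start=2010,
                           year_end=2012, seed=2)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    assert a.records.to_csv(index=False) == b.records.to_csv(index=False)
    for spec in a.cities:
        g = int(spec.city_id[1])
        lo, hi = GROUP_BOUNDS[g - 1]
        assert spec.population >= lo
        assert hi is None or spec.population <= hi


def test_cohort_single_small_city_and_empty():
    cfg = SimulationConfig(cities_per_group=(1, 0, 0, 0, 0, 0), year_start=2010,
                           year_end=2011, seed=4)
    cohort = simulate_cohort(cfg)
    assert len(cohort.cities) == 1
    assert cohort.cities[0].population <= 10_000
    empty = simulate_cohort(
        SimulationConfig(cities_per_group=(0,) * 6, year_start=2010, year_end=2011, seed=4)
    )
    assert empty.records.empty


def test_adding_cities_does_not_perturb_existing_streams():
    small = SimulationConfig(cities_per_group=(2, 0, 0, 0, 0, 0), year_start=2010,
                             year_end=2012, seed=8)
    big = SimulationConfig(cities_per_group=(2, 0, 0, 0, 0, 5), year_start=2010,
                           year_end=2012, seed=8)
    a = simulate_cohort(small).records
    b = simulate_cohort(big).records
    b_sub = b[b["city_id"].isin(a["city_id"].unique())].reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b_sub)


class TestInjectEpidemic:
    def _city_and_records(self, imr=2.0, seed=3):
        spec = CitySpec("e", 1_000_000, 13.5, imr, seasonality_amplitude=0.0)
        rec = simulate_city(spec, range(2018, 2021), seed=seed)
        return spec, rec

    def test_unknown_city_raises(self):
        spec, rec = self._city_and_records()
        epi = EpidemicSpec(("nope",), ((2019, 1),), 2.0)
        with pytest.raises(LookupError):
            inject_epidemic(rec, {"e": spec}, epi, seed=0)

    def test_clamped_probability_gives_deaths_equal_births(self):
        spec, rec = self._city_and_records(imr=500.0)
        epi = EpidemicSpec(("e",), ((2019, 3),), 1e6)
        out = inject_epidemic(rec, {"e": spec}, epi, seed=0)
        cell = out[(out["year"] == 2019) & (out["month"] == 3)]
        assert (cell["deaths"] == cell["births"]).all()

    def test_untargeted_cells_unchanged_and_deterministic(self):
        spec, rec = self._city_and_records()
        epi = EpidemicSpec(("e",), ((2019, 3), (2019, 4)), 1.0)
        out1 = inject_epidemic(rec, {"e": spec}, epi, seed=77)
        out2 = inject_epidemic(rec, {"e": spec}, epi, seed=77)
        pd.testing.assert_frame_equal(out1, out2)
        untouched = ~((out1["year"] == 2019) & (out1["month"].isin([3, 4])))
        pd.testing.assert_frame_equal(
            out1[untouched].reset_index(drop=True), rec[untouched].reset_index(drop=True)
        )

    def test_multiplier_scales_expected_deaths(self):
        # 24 injected months at 5x: total deaths within 4 SD of the analytic mean
        spec, rec = self._city_and_records(imr=2.0)
        periods = tuple((y, m) for y in (2019, 2020) for m in range(1, 13))
        epi = EpidemicSpec(("e",), periods, 5.0)
        out = inject_epidemic(rec, {"e": spec}, epi, seed=123)
        mask = out["year"].isin([2019, 2020])
        births = out.loc[mask, "births"].sum()
        p = 5 * 2.0 / 1000
        expected = births * p
        sd = math.sqrt(births * p * (1 - p))
        assert abs(out.loc[mask, "deaths"].sum() - expected) < 4 * sd
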