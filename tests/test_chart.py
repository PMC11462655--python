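"""Baseline statistics, control limits, alerts, and chart status."""

import math

import numpy as np
import pandas as pd
import pytest

from epichannel import (
    build_baseline,
    build_chart_table,
    chart_status,
    compute_limits,
    detect_alerts,
    exclude_periods,
)
from epichannel.errors import InsufficientHistoryError
from tests.conftest import make_series


def constant_series(value=12.0, years=range(2010, 2021)):
    return make_series("c", {y: value for y in years})


class TestBuildBaseline:
    def test_constant_history_gives_zero_sd(self):
        bl = build_baseline(constant_series(), study_year=2020)
        assert (bl["md"] == 12.0).all()
        assert (bl["sd"] == 0.0).all()
        assert (bl["n_years_used"] == 10).all()

    def test_two_point_sample_sd(self):
        vals = {2018: 10.0, 2019: 14.0}
        series = make_series("c", vals)
        bl = build_baseline(series, study_year=2020, min_years=2)
        assert bl["md"].iloc[0] == pytest.approx(12.0)
        assert bl["sd"].iloc[0] == pytest.approx(math.sqrt(8), abs=1e-4)
        assert (bl["n_years_used"] == 2).all()

    def test_min_years_gate_blanks_thin_months(self):
        series = make_series("c", {2018: 10.0, 2019: 14.0})
        bl = build_baseline(series, study_year=2020, min_years=3)
        assert bl["md"].isna().all()
        assert (bl["n_years_used"] == 2).all()

    def test_study_year_never_enters_baseline(self):
        series = make_series("c", {**{y: 12.0 for y in range(2010, 2020)}, 2020: 99.0})
        bl = build_baseline(series, study_year=2020)
        assert (bl["md"] == 12.0).all()

    def test_empty_window_raises(self):
        series = make_series("c", {1990: 12.0})
        with pytest.raises(InsufficientHistoryError):
            build_baseline(series, study_year=2020)

    def test_all_undefined_history_propagates(self):
        series = make_series("c", {y: np.nan for y in range(2010, 2020)})
        bl = build_baseline(series, study_year=2020)
        assert bl["md"].isna().all()
        assert chart_status(bl) == "insufficient_history"

    def test_pooled_mode_single_band(self):
        rng = np.random.default_rng(0)
        series = make_series(
            "c", {y: list(rng.normal(12, 2, size=12)) for y in range(2010, 2020)}
        )
        bl = build_baseline(series, study_year=2020, pooled=True)
        assert bl["md"].nunique() == 1
        assert bl["sd"].nunique() == 1


class TestExcludePeriods:
    def test_empty_exclusions_noop(self):
        series = constant_series()
        pd.testing.assert_frame_equal(exclude_periods(series, []), series)

    def test_excluding_all_januaries_zeroes_that_month(self):
        series = constant_series()
        excl = [("c", y, 1) for y in range(2010, 2020)]
        bl = build_baseline(exclude_periods(series, excl), study_year=2020)
        jan = bl[bl["calendar_month"] == 1].iloc[0]
        assert jan["n_years_used"] == 0
        assert math.isnan(jan["md"])

    def test_excluding_one_year_decrements_every_month(self):
        series = constant_series()
        excl = [("c", 2015, m) for m in range(1, 13)]
        bl = build_baseline(exclude_periods(series, excl), study_year=2020)
        assert (bl["n_years_used"] == 9).all()

    def test_unknown_triples_ignored(self, caplog):
        series = constant_series()
        out = exclude_periods(series, [("ghost", 2015, 1)])
        pd.testing.assert_frame_equal(out, series)


class TestComputeLimits:
    def _stats(self, md, sd):
        return pd.DataFrame({"calendar_month": [1], "md": [md], "sd": [sd], "n_years_used": [10]})

    def test_basic_arithmetic(self):
        lim = compute_limits(self._stats(12.0, 2.0), z=1.96)
        assert lim["lcl"].iloc[0] == pytest.approx(8.08)
        assert lim["ucl"].iloc[0] == pytest.approx(15.92)

    def test_lcl_clipped_at_zero(self):
        lim = compute_limits(self._stats(1.0, 2.0), z=1.96)
        assert lim["lcl"].iloc[0] == 0.0
        assert lim["ucl"].iloc[0] == pytest.approx(4.92)

    def test_zero_sd_collapses_band(self):
        lim = compute_limits(self._stats(7.0, 0.0))
        assert lim["lcl"].iloc[0] == lim["ucl"].iloc[0] == 7.0

    def test_undefined_stats_propagate(self):
        lim = compute_limits(self._stats(np.nan, np.nan))
        assert lim[["lcl", "ucl"]].isna().all().all()


class TestDetectAlerts:
    def _limits(self, md=12.0, sd=2.0):
        stats = pd.DataFrame(
            {
                "city_id": "c",
                "calendar_month": range(1, 13),
                "md": md,
                "sd": sd,
                "n_years_used": 10,
            }
        )
        return compute_limits(stats, z=1.96)

    def _study(self, values):
        return make_series("c", {2020: values})

    def test_strictly_above_fires(self):
        res = detect_alerts(self._study([16.0] + [12.0] * 11), self._limits())
        assert res["alert"].iloc[0] == "above"
        assert (res["alert"].iloc[1:] == "none").all()

    def test_boundary_equality_is_not_an_alert(self):
        res = detect_alerts(self._study([15.92] + [8.08] * 11), self._limits())
        assert (res["alert"] == "none").all()

    def test_undefined_observation_is_unassessable(self):
        vals = [np.nan] + [12.0] * 11
        res = detect_alerts(self._study(vals), self._limits())
        assert res["alert"].iloc[0] == "unassessable"

    def test_below_lcl(self):
        res = detect_alerts(self._study([7.0] + [12.0] * 11), self._limits())
        assert res["alert"].iloc[0] == "below"


class TestChartStatus:
    def _baseline(self, md, sd):
        return pd.DataFrame(
            {"calendar_month": range(1, 13), "md": md, "sd": sd, "n_years_used": 10}
        )

    def test_healthy_chart_ok(self):
        assert chart_status(self._baseline([12.0] * 12, [2.0] * 12)) == "ok"

    def test_zero_death_history_is_degenerate(self):
        assert chart_status(self._baseline([0.0] * 12, [0.0] * 12)) == "degenerate"

    def test_sparse_history_is_insufficient(self):
        md = [12.0] * 6 + [np.nan] * 6
        assert chart_status(self._baseline(md, [1.0] * 12)) == "insufficient_history"

    def test_nonzero_constant_months_are_not_degenerate(self):
        # sd = 0 with md > 0 is a constant history, not an absent one
        assert chart_status(self._baseline([12.0] * 12, [0.0] * 12)) == "ok"


class TestChartTable:
    def test_alert_set_monotone_in_z(self, small_series):
        loose = build_chart_table(small_series, study_year=2019, z=1.5)
        strict = build_chart_table(small_series, study_year=2019, z=2.5)
        key = ["city_id", "calendar_month"]
        fired_loose = set(map(tuple, loose.loc[loose["alert"].isin(["above", "below"]), key].to_numpy()))
        fired_strict = set(map(tuple, strict.loc[strict["alert"].isin(["above", "below"]), key].to_numpy()))
        assert fired_strict <= fired_loose

    def test_limit_ordering_invariants(self, small_series):
        table = build_chart_table(small_series, study_year=2019)
        ok = table.dropna(subset=["md"])
        assert (ok["lcl"] <= ok["md"] + 1e-12).all()
        assert (ok["md"] <= ok["ucl"] + 1e-12).all()
        assert (ok["lcl"] >= 0).all()

    def test_alert_verdicts_consistent_with_limits(self, small_series):
        table = build_chart_table(small_series, study_year=2019)
        above = table[table["alert"] == "above"]
        assert (above["observed"] > above["ucl"]).all()
        unass = table[table["alert"] == "unassessable"]
        assert (unass["observed"].isna() | unass["ucl"].isna()).all()

    def test_trim_narrows_or_keeps_band(self):
        vals = {y: 12.0 for y in range(2010, 2020)}
        vals[2015] = {**dict.fromkeys(range(1, 13), 12.0), 6: 90.0}  # one outbreak month
        series = make_series("c", vals)
        plain = build_chart_table(series, study_year=2020)
        trimmed = build_chart_table(series, study_year=2020, trim=True)
        june_plain = plain[plain["calendar_month"] == 6].iloc[0]
        june_trim = trimmed[trimmed["calendar_month"] == 6].iloc[0]
        assert june_trim["ucl"] <= june_plain["ucl"]
        assert june_trim["n_years_used"] == 9
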