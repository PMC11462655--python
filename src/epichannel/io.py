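"""Canonical file formats, run configuration, and the run manifest.

All interchange is comma-delimited UTF-8 with a required header. Undefined
numeric values (zero-birth IMRs, thin-baseline statistics) are serialized
as the sentinel ``NA``, never as an empty string, and rates are written at
4 decimal places; readers restore them as NaN, so writer -> reader
round-trips at that precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .aggregate import DATASET_COLUMNS
from .chart import CHART_COLUMNS
from .errors import ConfigError, DataIntegrityError, ValidationError
from .reliability import REPORT_COLUMNS, ReliabilityReport
from .simulate import EpidemicSpec, SimulationConfig

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"
RATE_FORMAT = "%.4f"

SUMMARY_COLUMNS = [
    "group",
    "group_name",
    "total_population",
    "n_cities",
    "total_births",
    "total_deaths",
    "pooled_imr",
    "imr_mean",
    "imr_sd",
    "classification",
]


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format vital-records CSV.

    Hard failures (missing file, wrong header, non-integer counts, month
    outside 1-12, negative counts, duplicate keys) raise ValidationError /
    DataIntegrityError with a code and, where known, the 1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}", code="missing-file")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != DATASET_COLUMNS:
        raise ValidationError(
            f"malformed header {list(df.columns)!r}; expected {DATASET_COLUMNS!r}",
            code="bad-header",
        )
    out = df.copy()
    for col in ["population", "year", "month", "births", "deaths"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted % 1 != 0)
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValidationError(
                f"non-integer value in column {col!r} at data row {row}",
                code="bad-integer",
                row=row,
            )
        out[col] = converted.astype(int)
    bad_month = ~out["month"].between(1, 12)
    if bad_month.any():
        row = int(bad_month.idxmax()) + 1
        raise ValidationError(
            f"month out of range 1-12 at data row {row}", code="bad-month", row=row
        )
    negative = (out[["population", "births", "deaths"]] < 0).any(axis=1)
    if negative.any():
        row = int(negative.idxmax()) + 1
        raise ValidationError(
            f"negative count at data row {row}", code="negative-count", row=row
        )
    dup = out.duplicated(subset=["city_id", "year", "month"])
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise DataIntegrityError(
            f"duplicate (city_id, year, month) key at data row {row}"
        )
    return out


def write_dataset(records: pd.DataFrame, path) -> None:
    records[DATASET_COLUMNS].to_csv(path, index=False)


def write_chart(chart: pd.DataFrame, path) -> None:
    chart[CHART_COLUMNS].to_csv(
        path, index=False, na_rep=NA_TOKEN, float_format=RATE_FORMAT
    )


def read_chart(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)


def write_summary(summary: pd.DataFrame, path) -> None:
    summary[SUMMARY_COLUMNS].to_csv(
        path, index=False, na_rep=NA_TOKEN, float_format=RATE_FORMAT
    )


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)


def write_report(report: ReliabilityReport | pd.DataFrame, path) -> None:
    table = report.per_group if isinstance(report, ReliabilityReport) else report
    table[REPORT_COLUMNS].to_csv(
        path, index=False, na_rep=NA_TOKEN, float_format=RATE_FORMAT
    )


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)


def read_exclusions(path) -> pd.DataFrame:
    """Exclusion list CSV with header city_id,year,month."""
    df = pd.read_csv(path, dtype={"city_id": str})
    missing = {"city_id", "year", "month"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"exclusion file missing column(s): {sorted(missing)}", code="bad-header"
        )
    return df


# ---------------------------------------------------------------------------
# run configuration


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    try:
        epidemics = tuple(
            EpidemicSpec(
                city_ids=tuple(e["city_ids"]),
                periods=tuple((int(y), int(m)) for y, m in e["periods"]),
                death_multiplier=float(e["death_multiplier"]),
            )
            for e in d.get("epidemics", [])
        )
        return SimulationConfig(
            cities_per_group=tuple(d.get("cities_per_group", (5, 5, 5, 5, 5, 5))),
            year_start=int(d.get("year_start", 2009)),
            year_end=int(d.get("year_end", 2020)),
            seed=int(d.get("seed", 0)),
            birth_rate_mean=float(d.get("birth_rate_mean", 13.5)),
            birth_rate_sd=float(d.get("birth_rate_sd", 1.5)),
            imr_mean=float(d.get("imr_mean", 11.6)),
            imr_sd=float(d.get("imr_sd", 2.0)),
            seasonality_amplitude=float(d.get("seasonality_amplitude", 0.1)),
            epidemics=epidemics,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation section: {exc}") from exc


def load_config(path) -> dict:
    """Load and validate the structured (YAML) run configuration.

    Returns a dict with a parsed ``simulation`` SimulationConfig plus the
    chart / classification / evaluation sections with defaults applied.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = {
        "simulation": simulation_config_from_dict(raw.get("simulation", {})),
        "chart": {
            "study_year": raw.get("chart", {}).get("study_year"),
            "window_years": int(raw.get("chart", {}).get("window_years", 10)),
            "z": float(raw.get("chart", {}).get("z", 1.96)),
            "min_years": int(raw.get("chart", {}).get("min_years", 3)),
            "pooled": bool(raw.get("chart", {}).get("pooled", False)),
            "trim": bool(raw.get("chart", {}).get("trim", False)),
        },
        "classification": {
            "sd_bins": tuple(
                raw.get("classification", {}).get("sd_bins", (3.5, 5.5, 8.0, 12.0))
            ),
        },
        "evaluate": {
            "replications": int(raw.get("evaluate", {}).get("replications", 1)),
            "death_multiplier": float(
                raw.get("evaluate", {}).get("death_multiplier", 3.0)
            ),
            "epidemic_months": tuple(
                raw.get("evaluate", {}).get("epidemic_months", (4, 5, 6))
            ),
        },
        "seed": int(raw.get("seed", 0)),
        "log_level": str(raw.get("log_level", "INFO")),
    }
    if cfg["chart"]["z"] < 0 or cfg["chart"]["window_years"] < 1:
        raise ConfigError("chart.z must be >= 0 and chart.window_years >= 1")
    return cfg


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, *, seed, params: dict, inputs: dict[str, str] | None = None):
    """Machine-readable record of a run: seed, parameters, input hashes."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {
            name: file_sha256(p) for name, p in (inputs or {}).items() if Path(p).exists()
        },
    }
    out = Path(out_dir) / "run_manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out
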