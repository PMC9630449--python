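"""Readers and writers for the four tabular inputs and the result tables.

All inputs are delimited text (CSV). Readers validate strictly and never
silently drop rows: every rejected or recoded value is logged. Missing PM10
is an explicit NaN, never 0 or a sentinel passthrough; the sentinels −999
and −9999 common in monitor exports are mapped to missing with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGE_GROUPS

logger = logging.getLogger(__name__)

#: Sentinel values some monitor networks use for missing concentrations.
MISSING_SENTINELS = (-999.0, -9999.0)

#: Column dialect of FIRMS fire-hotspot archive CSVs.
FIRMS_COLUMNS = {"latitude": "lat", "longitude": "lon", "acq_date": "date"}

HOURLY_COLUMNS = ["station_id", "province", "timestamp", "pm10"]
HOTSPOT_COLUMNS = ["date", "lat", "lon", "confidence"]
POPULATION_COLUMNS = ["district_id", "province", "population"]
VISIT_COLUMNS = ["province", "date", "age_group", "count"]


class SchemaError(ValueError):
    """An input file violates the expected schema or a value contract."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _first_bad_line(mask: pd.Series) -> int:
    # +2: header line plus 1-based numbering
    return int(mask.idxmax()) + 2


def read_hourly_pm10(path: str | Path) -> pd.DataFrame:
    """Read hourly PM10 monitor records.

    Returns a frame with columns ``station_id, province, timestamp, pm10``
    (plus ``lat, lon`` when present), sorted by station then time. Negative
    concentrations and sentinel values become NaN with a logged warning.

    Raises
    ------
    SchemaError
        On a missing column, an unparseable timestamp or concentration
        (the error names the offending line), or duplicate
        (station, timestamp) pairs.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"station_id": str, "province": str})
    _require_columns(df, HOURLY_COLUMNS, path)

    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        raise SchemaError(
            f"{path}: unparseable timestamp at line "
            f"{_first_bad_line(ts.isna())}"
        )
    df["timestamp"] = ts

    raw = df["pm10"]
    pm10 = pd.to_numeric(raw, errors="coerce")
    unparseable = pm10.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if unparseable.any():
        raise SchemaError(
            f"{path}: unparseable pm10 value at line "
            f"{_first_bad_line(unparseable)}"
        )
    sentinel = pm10.isin(MISSING_SENTINELS)
    if sentinel.any():
        logger.warning(
            "%s: %d sentinel pm10 value(s) mapped to missing", path, sentinel.sum()
        )
        pm10 = pm10.mask(sentinel)
    negative = pm10 < 0
    if negative.any():
        logger.warning(
            "%s: %d negative pm10 value(s) converted to missing", path, negative.sum()
        )
        pm10 = pm10.mask(negative)
    df["pm10"] = pm10

    dup = df.duplicated(subset=["station_id", "timestamp"], keep=False)
    if dup.any():
        raise SchemaError(
            f"{path}: duplicate (station, timestamp) at line "
            f"{_first_bad_line(df.duplicated(subset=['station_id', 'timestamp']))}"
        )

    keep = HOURLY_COLUMNS + [c for c in ("lat", "lon") if c in df.columns]
    return (
        df[keep]
        .sort_values(["station_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )


def read_hotspots(path: str | Path) -> pd.DataFrame:
    """Read daily satellite fire-hotspot point records.

    Accepts either native column names (``date, lat, lon, confidence``) or
    the FIRMS archive dialect (``acq_date, latitude, longitude,
    confidence``). All rows are retained; confidence filtering is a
    separate exposure-stage operation.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df = df.rename(columns=FIRMS_COLUMNS)
    _require_columns(df, HOTSPOT_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"], errors="raise").dt.normalize()
    conf = pd.to_numeric(df["confidence"], errors="raise")
    bad = (conf < 0) | (conf > 100)
    if bad.any():
        raise SchemaError(
            f"{path}: confidence outside [0, 100] at line {_first_bad_line(bad)}"
        )
    df["confidence"] = conf.astype(float)
    return df[HOTSPOT_COLUMNS].reset_index(drop=True)


def read_population(path: str | Path) -> pd.DataFrame:
    """Read the district-level population table.

    Optional ``lat, lon`` columns carry district centroids used to map
    districts to their nearest monitor.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"district_id": str, "province": str})
    _require_columns(df, POPULATION_COLUMNS, path)
    pop = pd.to_numeric(df["population"], errors="raise")
    if (pop < 0).any():
        raise SchemaError(
            f"{path}: negative population at line {_first_bad_line(pop < 0)}"
        )
    df["population"] = pop.astype(float)
    if df["district_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate district_id")
    keep = POPULATION_COLUMNS + [c for c in ("lat", "lon") if c in df.columns]
    return df[keep].reset_index(drop=True)


def read_visits(path: str | Path) -> pd.DataFrame:
    """Read daily hospital-visit counts by province and age group."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"province": str, "age_group": str})
    _require_columns(df, VISIT_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"], errors="raise").dt.normalize()
    bad_group = ~df["age_group"].isin(AGE_GROUPS)
    if bad_group.any():
        raise SchemaError(
            f"{path}: unknown age_group at line {_first_bad_line(bad_group)}"
        )
    count = pd.to_numeric(df["count"], errors="raise")
    if (count < 0).any() or (count % 1 != 0).any():
        raise SchemaError(f"{path}: count must be a non-negative integer")
    df["count"] = count.astype(int)
    if df.duplicated(subset=["province", "date", "age_group"]).any():
        raise SchemaError(f"{path}: duplicate (province, date, age_group) row")
    return df[VISIT_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# result tables

BURDEN_SORT = ["province", "period", "age_group"]


def write_burden_tables(
    annual: pd.DataFrame,
    summaries: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write burden-estimate tables as CSV with deterministic row order.

    ``annual`` holds one row per (province, period, age_group); ``summaries``
    holds period-level aggregates (study period, before/after ban). A
    write→read round trip reproduces values bit-exactly (floats are written
    with full shortest-repr precision).
    """
    if annual is None or len(annual) == 0:
        raise ValueError("no burden estimates to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ordered = annual.sort_values(BURDEN_SORT, kind="mergesort").reset_index(drop=True)
    paths["burden_by_province_year"] = out_dir / "burden_by_province_year.csv"
    ordered.to_csv(paths["burden_by_province_year"], index=False)

    if summaries is not None and len(summaries):
        cols = [c for c in BURDEN_SORT if c in summaries.columns]
        ordered_s = summaries.sort_values(cols, kind="mergesort").reset_index(drop=True)
        paths["burden_period_summaries"] = out_dir / "burden_period_summaries.csv"
        ordered_s.to_csv(paths["burden_period_summaries"], index=False)
    return paths


def read_burden_table(path: str | Path) -> pd.DataFrame:
    """Read back a burden table written by :func:`write_burden_tables`."""
    return pd.read_csv(
        path,
        dtype={"province": str, "period": str, "age_group": str},
        float_precision="round_trip",
    )
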