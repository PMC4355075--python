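"""CSV reading and writing for gauge series.

Series files carry a (lake_id, date, level) header with ISO-8601 dates.
Monthly files use the first of the month; a skipped calendar month inside
the span becomes a missing month.  Malformed rows are reported with their
line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series import DailyGauge, MonthlySeries

__all__ = ["read_series_csv", "read_monthly_csv", "read_daily_csv", "write_monthly_csv"]


class SeriesParseError(ValueError):
    pass


def _parse(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"lake_id": str})
    required = {"lake_id", "date", "level"}
    if not required.issubset(df.columns):
        raise SeriesParseError(f"{path}: expected columns {sorted(required)}")
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = np.flatnonzero(dates.isna().to_numpy() & df["date"].notna().to_numpy())
    if len(bad):
        # +2: header line and 1-based numbering
        raise SeriesParseError(f"{path}: unparseable date on line {bad[0] + 2}")
    levels = pd.to_numeric(df["level"], errors="coerce")
    bad = np.flatnonzero(levels.isna().to_numpy() & df["level"].notna().to_numpy() & (df["level"].astype(str).str.strip() != ""))
    if len(bad):
        raise SeriesParseError(f"{path}: non-numeric level on line {bad[0] + 2}")
    df = df.assign(date=dates, level=levels)
    if not df["date"].is_monotonic_increasing:
        raise SeriesParseError(f"{path}: dates are not increasing")
    return df


def read_daily_csv(path: str | Path) -> DailyGauge:
    df = _parse(path)
    df = df.dropna(subset=["level"])
    return DailyGauge(
        lake_id=str(df["lake_id"].iloc[0]),
        dates=pd.DatetimeIndex(df["date"]),
        levels=df["level"].to_numpy(),
    )


def read_monthly_csv(path: str | Path) -> MonthlySeries:
    df = _parse(path)
    months = df["date"].dt.to_period("M")
    if months.duplicated().any():
        raise SeriesParseError(f"{path}: duplicate calendar month")
    full = pd.period_range(months.iloc[0], months.iloc[-1], freq="M")
    values = np.full(len(full), np.nan)
    observed = np.zeros(len(full), dtype=bool)
    pos = {p: i for i, p in enumerate(full)}
    for month, level in zip(months, df["level"]):
        i = pos[month]
        if pd.notna(level):
            values[i] = level
            observed[i] = True
    return MonthlySeries(
        lake_id=str(df["lake_id"].iloc[0]),
        start=full[0],
        values=values,
        observed=observed,
    )


def read_series_csv(path: str | Path) -> MonthlySeries | DailyGauge:
    """Read a series file, inferring resolution from the dates.

    A file whose dates all fall on the first of the month is read as a
    monthly series; anything else as a daily gauge record.
    """
    df = _parse(path)
    if (df["date"].dt.day == 1).all():
        return read_monthly_csv(path)
    return read_daily_csv(path)


def write_monthly_csv(series: MonthlySeries, path: str | Path) -> None:
    """Write a monthly series; missing months get an empty level field."""
    series.to_frame().to_csv(path, index=False)
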