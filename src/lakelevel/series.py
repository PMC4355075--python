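"""Containers for gauge series at daily and monthly resolution."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DailyGauge:
    """Relative mean daily water levels at a gauge station; gaps allowed.

    ``dates`` must be strictly increasing calendar days and ``levels``
    finite wherever present.
    """

    lake_id: str
    dates: pd.DatetimeIndex
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.levels = np.asarray(self.levels, dtype=float)
        if len(self.dates) != len(self.levels):
            raise ValueError("dates and levels differ in length")
        if len(self.dates) == 0:
            raise ValueError("empty daily gauge record")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("daily dates must be strictly increasing")
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("daily levels must be finite where present")


@dataclass
class MonthlySeries:
    """One lake's monthly mean level series with an observed/missing mask.

    ``values`` holds the monthly mean level (m) where observed and NaN
    where missing; ``observed`` is the boolean mask.  ``hidden_truth``
    optionally retains the pre-masking values of months that were removed
    synthetically, so imputation can be scored against the truth; it is
    never visible to fitting code.
    """

    lake_id: str
    start: pd.Period
    values: np.ndarray
    observed: np.ndarray
    hidden_truth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.start = pd.Period(self.start, freq="M")
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed mask differ in shape")
        obs = self.values[self.observed]
        if np.any(~np.isfinite(obs)) or np.any(obs <= 0):
            raise ValueError("observed monthly levels must be finite and > 0")

    @property
    def n_months(self) -> int:
        return len(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(1.0 - self.observed.mean())

    @property
    def month_index(self) -> np.ndarray:
        """1-based month index t used by the harmonic regression."""
        return np.arange(1, self.n_months + 1)

    @property
    def periods(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=self.n_months, freq="M")

    def to_frame(self) -> pd.DataFrame:
        dates = self.periods.to_timestamp(how="start")
        return pd.DataFrame(
            {
                "lake_id": self.lake_id,
                "date": dates.strftime("%Y-%m-%d"),
                "level": [("" if not o else v) for v, o in zip(self.values, self.observed)],
            }
        )
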