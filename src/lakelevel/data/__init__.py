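"""Packaged summary tables for the 28-lake Irish gauge cohort.

``lake_metadata.csv`` lists the studied lakes with coordinates, series
spans, missing-value percentages and current (2008-2009) annual
abstraction volumes (hm^3/yr).  ``fitted_trends.csv`` holds the published
best-model summaries per lake: DIC, DIC difference to the no-harmonic
null, the trend coefficient beta1 (x 1e-4 per month) with its 95%
credible interval, and the fitted period means/intervals for up to three
harmonics.  The raw gauge series themselves were never deposited; these
tables are what the cross-lake statistics consume.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_lake_metadata", "load_fitted_trends", "study_cohort_records"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_lake_metadata() -> pd.DataFrame:
    """Per-lake metadata: coordinates, span, missingness, abstraction."""
    return _read("lake_metadata.csv")


def load_fitted_trends() -> pd.DataFrame:
    """Published best-model summaries: DIC, beta1 and CI, period posteriors."""
    return _read("fitted_trends.csv")


def study_cohort_records() -> list:
    """Join the two tables into LakeRecords for the cohort statistics.

    beta1 columns are stored in units of 1e-4 per month and are rescaled
    to per-month here.  The chosen harmonic count is inferred from which
    period columns are populated.
    """
    from ..trends import LakeRecord

    meta = load_lake_metadata().set_index("lake")
    fits = load_fitted_trends()
    records = []
    for _, row in fits.iterrows():
        m = meta.loc[row["lake"]]
        k = int(pd.notna(row["p1_mean"])) + int(pd.notna(row["p2_mean"])) + int(
            pd.notna(row["p3_mean"])
        )
        records.append(
            LakeRecord(
                lake_id=row["lake"],
                latitude=float(m["latitude"]),
                longitude=float(m["longitude"]),
                abstraction=float(m["abstraction_hm3_yr"]),
                beta1_mean=float(row["beta1_e4_mean"]) * 1e-4,
                beta1_lo=float(row["beta1_e4_lo"]) * 1e-4,
                beta1_hi=float(row["beta1_e4_hi"]) * 1e-4,
                chosen_k=k,
            )
        )
    return records
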