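"""Foley's drought index (FDI) from monthly rainfall series.

FDI standardizes the multi-year rainfall deficit by the long-term mean
annual precipitation (MAP).  For each month m,

    FDI(m) = (sum of rainfall over the 36 months ending at m - 3 * MAP) / MAP

where MAP is computed over a fixed baseline period (1901-2003 by default).
Values are dimensionless; more negative means deeper drought, and a series
running exactly at climatology scores 0 everywhere.  The first 35 months of
a series, and any month whose trailing window contains gaps, are undefined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WINDOW_MONTHS = 36
BASELINE = (1901, 2003)


def _month_index(df: pd.DataFrame) -> pd.PeriodIndex:
    return pd.PeriodIndex.from_fields(
        year=df["year"].astype(int), month=df["month"].astype(int), freq="M"
    )


def mean_annual_precipitation(
    series: pd.DataFrame, baseline: tuple[int, int] = BASELINE
) -> float:
    """Baseline mean annual precipitation (mm/yr) = 12 x mean monthly rainfall."""
    years = series["year"].astype(int)
    base = series[(years >= baseline[0]) & (years <= baseline[1])]
    if len(base) == 0:
        raise ValueError(f"no rainfall inside baseline {baseline}")
    return float(12.0 * base["rain_mm"].mean())


def monthly_fdi(
    series: pd.DataFrame,
    baseline: tuple[int, int] = BASELINE,
    window_months: int = WINDOW_MONTHS,
) -> pd.DataFrame:
    """FDI per month for one or many locations.

    ``series`` has columns ``location_id, year, month, rain_mm`` (the
    location column is optional for a single series).  Returns the same
    keying columns plus ``fdi``; months whose trailing window is incomplete
    hold NaN.
    """
    df = series.copy()
    if "location_id" not in df.columns:
        df["location_id"] = "_single"
    if (df["rain_mm"] < 0).any():
        raise ValueError("rainfall totals must be >= 0")

    pieces = []
    for loc, grp in df.groupby("location_id", observed=True, sort=True):
        grp = grp.set_index(_month_index(grp)).sort_index()
        if grp.index.has_duplicates:
            raise ValueError(f"duplicate months for location {loc!r}")
        # re-index over the full span so internal gaps become NaN and
        # poison every window that touches them
        full = pd.period_range(grp.index[0], grp.index[-1], freq="M")
        rain = grp["rain_mm"].reindex(full)
        map_mm = mean_annual_precipitation(grp.reset_index(drop=True), baseline)
        rolling = rain.rolling(window_months, min_periods=window_months).sum()
        fdi = (rolling - 3.0 * map_mm) / map_mm
        pieces.append(
            pd.DataFrame(
                {
                    "location_id": loc,
                    "year": full.year,
                    "month": full.month,
                    "fdi": fdi.to_numpy(),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def species_mean_fdi(
    records: pd.DataFrame, fdi_by_location: pd.DataFrame
) -> pd.Series:
    """Average FDI per species over the record x month pool.

    Every record contributes its location's full monthly FDI series, so a
    location sampled twice counts twice; undefined months are ignored.
    Species with no mappable records are absent from the result.
    """
    merged = records[["species", "location_id"]].merge(
        fdi_by_location[["location_id", "fdi"]], on="location_id", how="inner"
    )
    out = merged.groupby("species", observed=True)["fdi"].mean()
    out.name = "mean_fdi"
    return out
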