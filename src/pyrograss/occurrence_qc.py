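"""Quality control of species occurrence records.

Occurrence tables carry one row per georeferenced, dated record with columns
``species, lon, lat, date, hii, protected``.  The filters below remove
records that cannot support fine-scale fire-regime attribution: bad or
imprecise coordinates, records from heavily human-transformed landscapes
(unless inside a protected area), pre-satellite-era records, and species
sampled at too few distinct points.  Each filter is idempotent and the
cleaning pipeline reports per-step attrition.

When an occurrence CSV is read with :func:`read_occurrences`, the textual
longitude/latitude columns are preserved (``lon_str``/``lat_str``) so that
stated coordinate precision can be judged on the source representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "lon", "lat", "date")


@dataclass
class CleaningReport:
    """Ordered per-step attrition of a cleaning run."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, n_species: int) -> None:
        if n_out > n_in:
            raise ValueError(f"step {name!r}: records out ({n_out}) > in ({n_in})")
        self.steps.append((name, n_in, n_out, n_species))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "records_in", "records_out", "species_remaining"]
        )


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV, keeping raw coordinate strings for precision checks."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    df["lon_str"] = df["lon"]
    df["lat_str"] = df["lat"]
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    if "hii" in df.columns:
        df["hii"] = pd.to_numeric(df["hii"], errors="coerce")
    else:
        df["hii"] = np.nan
    if "protected" in df.columns:
        df["protected"] = (
            df["protected"].astype(str).str.strip().str.lower().isin(["true", "1", "yes", "t"])
        )
    else:
        df["protected"] = False
    return df


def filter_coordinates(records: pd.DataFrame, land_mask=None) -> pd.DataFrame:
    """Drop invalid coordinates, (0, 0) placeholders and exact duplicates.

    ``land_mask`` is an optional callable ``(lon, lat) -> bool array``; the
    terrestriality check only runs when one is supplied.
    """
    if len(records) == 0:
        warnings.warn("filter_coordinates: empty input", stacklevel=2)
        return records.copy()
    out = records.copy()
    lon = pd.to_numeric(out["lon"], errors="coerce")
    lat = pd.to_numeric(out["lat"], errors="coerce")
    ok = lon.notna() & lat.notna()
    ok &= lon.between(-180.0, 180.0) & lat.between(-90.0, 90.0)
    ok &= ~((lon == 0.0) & (lat == 0.0))
    out = out[ok]
    if land_mask is not None:
        on_land = np.asarray(land_mask(out["lon"].to_numpy(), out["lat"].to_numpy()), dtype=bool)
        out = out[on_land]
    dedupe_cols = [c for c in ("species", "lon", "lat", "date") if c in out.columns]
    out = out.drop_duplicates(subset=dedupe_cols, keep="first")
    return out


def _string_decimals(text: str) -> int:
    text = str(text).strip()
    if "e" in text.lower():  # scientific notation: fall back to numeric test
        return -1
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1].rstrip())


def _has_min_decimals(values: pd.Series, strings: pd.Series | None, min_decimals: int) -> pd.Series:
    if min_decimals <= 0:
        return pd.Series(True, index=values.index)
    if strings is not None:
        dec = strings.map(_string_decimals)
    else:
        dec = pd.Series(-1, index=values.index)
    # numeric fallback: value keeps information beyond (d-1) decimals
    numeric_ok = (values - values.round(min_decimals - 1)).abs() > 1e-12
    return (dec >= min_decimals) | ((dec < 0) & numeric_ok)


def filter_precision(records: pd.DataFrame, min_decimals: int = 3) -> pd.DataFrame:
    """Keep records whose lon and lat are stated to >= ``min_decimals`` decimals."""
    if min_decimals < 0:
        raise ValueError("min_decimals must be >= 0")
    if min_decimals == 0 or len(records) == 0:
        return records.copy()
    lon_str = records["lon_str"] if "lon_str" in records.columns else None
    lat_str = records["lat_str"] if "lat_str" in records.columns else None
    ok = _has_min_decimals(records["lon"], lon_str, min_decimals) & _has_min_decimals(
        records["lat"], lat_str, min_decimals
    )
    return records[ok].copy()


def filter_human_influence(records: pd.DataFrame, hii_max: float = 30) -> pd.DataFrame:
    """Drop records from transformed landscapes (HII > ``hii_max``) unless protected.

    Records with missing HII that are not in a protected area are also
    dropped: the analysis keeps only records whose fire regime can be
    presumed unaltered.
    """
    if len(records) == 0:
        return records.copy()
    hii = pd.to_numeric(records.get("hii"), errors="coerce")
    protected = records.get("protected", pd.Series(False, index=records.index)).astype(bool)
    keep = protected | (hii.notna() & (hii <= hii_max))
    return records[keep].copy()


def filter_date(records: pd.DataFrame, min_year: int = 1980) -> pd.DataFrame:
    """Drop records collected before ``min_year``; unparseable dates are dropped too."""
    if len(records) == 0:
        return records.copy()
    years = pd.to_datetime(records["date"], errors="coerce", format="mixed").dt.year
    n_bad = int(years.isna().sum())
    if n_bad:
        logger.info("filter_date: dropping %d unparseable dates", n_bad)
    return records[years >= min_year].copy()


def filter_min_sampling(records: pd.DataFrame, min_unique: int = 50) -> pd.DataFrame:
    """Drop all records of species with fewer than ``min_unique`` distinct coordinates."""
    if len(records) == 0:
        return records.copy()
    uniq = (
        records.drop_duplicates(subset=["species", "lon", "lat"])
        .groupby("species", observed=True)
        .size()
    )
    keep_species = uniq[uniq >= min_unique].index
    return records[records["species"].isin(keep_species)].copy()


# local equirectangular scale, km per degree
_KM_PER_DEG_LAT = 110.574
_KM_PER_DEG_LON_EQ = 111.320


def spatial_thin(
    records: pd.DataFrame,
    cell_area_km2: float = 10.0,
    max_per_cell: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Subsample to at most ``max_per_cell`` records per species per grid cell.

    Cells are squares of area ``cell_area_km2`` on a local equal-area
    approximation (longitude scaled by cos latitude).  Used for the
    spatial-bias sensitivity check, not the main pipeline.
    """
    if len(records) == 0:
        return records.copy()
    edge_km = float(np.sqrt(cell_area_km2))
    lat = records["lat"].to_numpy(float)
    lon = records["lon"].to_numpy(float)
    x_km = lon * _KM_PER_DEG_LON_EQ * np.cos(np.radians(lat))
    y_km = lat * _KM_PER_DEG_LAT
    cell = pd.Series(
        list(zip(np.floor(x_km / edge_km).astype(int), np.floor(y_km / edge_km).astype(int))),
        index=records.index,
    )
    rng = np.random.default_rng(seed)
    keep_idx = []
    for _, grp in records.groupby([records["species"], cell], observed=True, sort=True):
        idx = grp.index.to_numpy()
        if len(idx) > max_per_cell:
            idx = rng.choice(np.sort(idx), size=max_per_cell, replace=False)
        keep_idx.extend(idx.tolist())
    return records.loc[sorted(keep_idx)].copy()


def clean_occurrences(
    records: pd.DataFrame,
    min_decimals: int = 3,
    hii_max: float = 30,
    min_year: int = 1980,
    min_unique: int = 50,
    thin: bool = False,
    cell_area_km2: float = 10.0,
    max_per_cell: int = 3,
    seed: int = 0,
    land_mask=None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full cleaning pipeline and return (cleaned records, report)."""
    report = CleaningReport()

    def _step(name, func, df):
        out = func(df)
        report.add(name, len(df), len(out), out["species"].nunique() if len(out) else 0)
        return out

    df = _step("coordinates", lambda d: filter_coordinates(d, land_mask=land_mask), records)
    df = _step("precision", lambda d: filter_precision(d, min_decimals), df)
    df = _step("human_influence", lambda d: filter_human_influence(d, hii_max), df)
    df = _step("date", lambda d: filter_date(d, min_year), df)
    df = _step("min_sampling", lambda d: filter_min_sampling(d, min_unique), df)
    if thin:
        df = _step(
            "spatial_thin",
            lambda d: spatial_thin(d, cell_area_km2, max_per_cell, seed),
            df,
        )
    return df, report
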