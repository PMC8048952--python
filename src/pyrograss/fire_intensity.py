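"""Per-species fire-intensity summaries from fire-radiative-power detections.

Fire radiative power (FRP, MW per 1-km pixel) is a proxy for fire-line
intensity.  Detections below a confidence floor are discarded and each
species is summarized by an upper quantile (default the 95th) of the FRP
values at its record locations, which indicates the intensity a headfire can
attain there while damping the low-value bias from night-time and partial
detections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def filter_confidence(detections: pd.DataFrame, min_conf: float = 50.0) -> pd.DataFrame:
    """Drop detections with confidence below ``min_conf`` percent (strict <)."""
    conf = pd.to_numeric(detections["confidence"], errors="coerce")
    return detections[conf >= min_conf].copy()


def species_frp_quantile(
    detections_by_species: pd.DataFrame, q: float = 0.95, value_col: str = "frp_mw"
) -> pd.Series:
    """Per-species FRP quantile (linear interpolation between order statistics).

    ``detections_by_species`` needs columns ``species`` and ``value_col``.
    Species with no surviving detections are simply absent from the result.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    out = detections_by_species.groupby("species", observed=True)[value_col].quantile(
        q, interpolation="linear"
    )
    out.name = f"frp_q{int(round(q * 100))}"
    return out


def attach_frp_to_records(
    records: pd.DataFrame, detections: pd.DataFrame
) -> pd.DataFrame:
    """Join detections to species via shared ``location_id`` (same-cell matching)."""
    return records[["species", "location_id"]].merge(
        detections[["location_id", "frp_mw"]], on="location_id", how="inner"
    )


def frp_summary_diagnostics(profiles: pd.DataFrame) -> dict:
    """r-squared of the species q95 against mean and median FRP, for reporting.

    ``profiles`` needs columns ``frp_q95``, ``frp_mean``, ``frp_median``.
    A constant q95 column leaves r-squared undefined (NaN, flagged).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 species")
    q95 = profiles["frp_q95"].to_numpy(float)
    out = {"degenerate": False}
    if np.ptp(q95) == 0:
        return {"degenerate": True, "r2_mean": np.nan, "r2_median": np.nan}
    for key, col in (("r2_mean", "frp_mean"), ("r2_median", "frp_median")):
        other = profiles[col].to_numpy(float)
        if np.ptp(other) == 0:
            out[key] = np.nan
            out["degenerate"] = True
        else:
            r, _ = stats.pearsonr(q95, other)
            out[key] = float(r * r)
    return out
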