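"""End-to-end orchestration: QC -> FRI/FRP/FDI -> fire-prone filter ->
comparative models.

:func:`run_pipeline` takes the raw input tables (occurrences, burn dates,
FRP detections, rainfall, phylogeny, traits), derives a per-species fire
profile (proportion burned, median fire return interval from the censored
Weibull fit, FRP 95th quantile, mean drought index), restricts frequency
analyses to fire-prone species with resolvable FRIs, and fits the
phylogenetic logistic models (strategy ~ log FRI + FDI and
strategy ~ log FRP + FDI), optional trait-association models, and the PGLS
diagnostics between fire and drought variables.  Fire frequency and
intensity enter the models natural-log-transformed; nothing else is
transformed.  Every number in the result is reproducible from the inputs,
the configuration and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import occurrence_qc as qc
from .drought_index import BASELINE, monthly_fdi, species_mean_fdi
from .fire_frequency import (
    CensoredWeibull,
    FireHistory,
    classify_fire_prone,
    date_to_year_fraction,
    filter_fri_bounds,
    fit_breakpoint,
    pool_species_intervals,
    proportion_burned,
    species_count_curve,
)
from .fire_intensity import filter_confidence, species_frp_quantile
from .phylo_models import PGLS, PhyloLogisticRegression, load_tree

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (2000.25, 2020.08)


@dataclass
class PipelineConfig:
    """All stage parameters, at the defaults of the source analysis."""

    window: tuple[float, float] = DEFAULT_WINDOW
    min_decimals: int = 3
    hii_max: float = 30.0
    min_year: int = 1980
    min_unique: int = 50
    conf_min: float = 50.0
    frp_q: float = 0.95
    fri_lo: float = 1.0
    fri_hi: float = 100.0
    breakpoint_bin: float = 0.02
    # None -> estimate the threshold by break-point regression on the
    # species-count curve; a float fixes it (0.26 is the published estimate)
    fire_prone_threshold: float | None = 0.26
    baseline: tuple[int, int] = BASELINE
    n_boot: int = 0
    seed: int = 0
    test_interaction: bool = True
    fit_trait_models: bool = False
    fit_pgls: bool = True
    trait_columns: tuple[str, ...] = ("pathway", "bud_position", "life_history")


def load_bundle(directory) -> dict:
    """Read a benchmark-bundle directory written by ``make_benchmark_bundle``."""
    d = Path(directory)
    bundle = {
        "occurrences": qc.read_occurrences(d / "occurrences.csv"),
        "burns": pd.read_csv(d / "burn_histories.csv"),
        "frp": pd.read_csv(d / "frp_detections.csv"),
        "rainfall": pd.read_csv(d / "rainfall.csv"),
        "traits": pd.read_csv(d / "traits.csv"),
        "tree": load_tree(d / "tree.nwk"),
    }
    return bundle


def _burn_dates_to_years(burns: pd.DataFrame) -> pd.Series:
    vals = burns["burn_date"]
    if vals.dtype.kind in "fi":
        return vals.astype(float)
    return pd.Series(date_to_year_fraction(vals), index=burns.index)


def build_histories(burns: pd.DataFrame, window) -> dict[str, FireHistory]:
    """Fire histories per location from a long (location_id, burn_date) table."""
    years = _burn_dates_to_years(burns)
    out = {}
    for loc, grp in years.groupby(burns["location_id"], observed=True):
        out[str(loc)] = FireHistory(str(loc), window[0], window[1], grp.to_numpy())
    return out


def _fit_glm(tree, df, predictors, response, cfg, label):
    """Fit strategy ~ predictors (+ pairwise interaction when significant)."""
    X = df[predictors].copy()
    y = df[response].to_numpy(float)
    model = PhyloLogisticRegression(n_boot=0, random_state=cfg.seed).fit(
        X, y, tree=tree, species=list(df.index)
    )
    interaction_kept = False
    if cfg.test_interaction and len(predictors) == 2:
        Xi = X.copy()
        # centred product keeps the interaction near-orthogonal to the
        # main effects, so retaining it does not distort their estimates
        a = Xi[predictors[0]] - Xi[predictors[0]].mean()
        b = Xi[predictors[1]] - Xi[predictors[1]].mean()
        Xi["interaction"] = a * b
        try:
            mi = PhyloLogisticRegression(n_boot=0, random_state=cfg.seed).fit(
                Xi, y, tree=tree, species=list(df.index)
            )
            if mi.converged_ and mi.pvalues_[-1] < 0.05:
                model, interaction_kept = mi, True
        except (ValueError, np.linalg.LinAlgError):
            pass
    if cfg.n_boot:
        model.bootstrap_ci(cfg.n_boot, seed=cfg.seed)
    fit = model.summary()
    table = pd.DataFrame(
        {
            "term": fit.names,
            "estimate": fit.coef,
            "ci_lower": fit.ci_lower if fit.ci_lower is not None else np.nan,
            "ci_upper": fit.ci_upper if fit.ci_upper is not None else np.nan,
            "z": fit.zvalues,
            "p": fit.pvalues,
        }
    )
    return {
        "label": label,
        "model": model,
        "table": table,
        "n": fit.n,
        "alpha": fit.alpha,
        "interaction_kept": interaction_kept,
        "converged": fit.converged,
    }


def run_pipeline(bundle: dict, config: PipelineConfig | None = None) -> dict:
    """Run every stage on in-memory tables; returns profiles, fits and a report."""
    cfg = config or PipelineConfig()
    report: dict = {"seed": cfg.seed}

    # ---- stage 1: occurrence QC ----------------------------------------
    occ = bundle["occurrences"]
    if "lon_str" not in occ.columns:
        occ = occ.copy()
        occ["lon_str"] = occ["lon"].astype(str)
        occ["lat_str"] = occ["lat"].astype(str)
    cleaned, cleaning_report = qc.clean_occurrences(
        occ,
        min_decimals=cfg.min_decimals,
        hii_max=cfg.hii_max,
        min_year=cfg.min_year,
        min_unique=cfg.min_unique,
        seed=cfg.seed,
    )
    if len(cleaned) == 0:
        raise RuntimeError("stage occurrence_qc: no records survived cleaning")
    report["attrition"] = cleaning_report.to_frame()

    # ---- stage 2: fire histories and per-species profiles ---------------
    histories = build_histories(bundle["burns"], cfg.window)
    burn_lookup = {loc: h.n_fires > 0 for loc, h in histories.items()}
    for loc in cleaned["location_id"].unique():
        burn_lookup.setdefault(str(loc), False)

    rows = []
    species_locations = {}
    for sp, grp in cleaned.groupby("species", observed=True, sort=True):
        locs = sorted(grp["location_id"].astype(str).unique())
        species_locations[sp] = locs
        rows.append(
            {
                "species": sp,
                "n_records": len(grp),
                "proportion_burned": proportion_burned(grp, burn_lookup),
            }
        )
    profiles = pd.DataFrame(rows).set_index("species")

    # ---- stage 3: fire-prone threshold ----------------------------------
    if cfg.fire_prone_threshold is None:
        centers, counts = species_count_curve(
            profiles["proportion_burned"].to_numpy(), cfg.breakpoint_bin
        )
        bp = fit_breakpoint(centers, counts)
        threshold = bp.breakpoint
        report["breakpoint"] = bp
    else:
        threshold = float(cfg.fire_prone_threshold)
    report["fire_prone_threshold"] = threshold
    profiles = classify_fire_prone(profiles.reset_index(), threshold).set_index("species")

    # ---- stage 4: censored Weibull FRI per fire-prone species ------------
    fit_cols = {
        "b": np.nan,
        "c": np.nan,
        "median_fri": np.nan,
        "n_complete": 0,
        "n_censored": 0,
        "fri_converged": False,
    }
    for col, default in fit_cols.items():
        profiles[col] = default
    n_nonconverged = 0
    for sp in profiles.index[profiles["fire_prone"]]:
        intervals = pool_species_intervals(histories, species_locations[sp])
        est = CensoredWeibull().fit(intervals)
        profiles.loc[sp, ["b", "c", "median_fri"]] = (
            est.scale_,
            est.shape_,
            est.median_fri_,
        )
        profiles.loc[sp, ["n_complete", "n_censored"]] = (
            est.n_complete_,
            est.n_censored_,
        )
        profiles.loc[sp, "fri_converged"] = est.converged_
        n_nonconverged += not est.converged_
    report["fri_nonconverged"] = n_nonconverged
    profiles = filter_fri_bounds(profiles, cfg.fri_lo, cfg.fri_hi)

    # ---- stage 5: fire intensity ----------------------------------------
    frp = filter_confidence(bundle["frp"], cfg.conf_min)
    frp_by_species = cleaned[["species", "location_id"]].merge(
        frp[["location_id", "frp_mw"]], on="location_id", how="inner"
    )
    q = species_frp_quantile(frp_by_species, cfg.frp_q)
    profiles["frp_q95"] = q.reindex(profiles.index)
    grp = frp_by_species.groupby("species", observed=True)["frp_mw"]
    profiles["frp_mean"] = grp.mean().reindex(profiles.index)
    profiles["frp_median"] = grp.median().reindex(profiles.index)

    # ---- stage 6: drought ------------------------------------------------
    fdi = monthly_fdi(bundle["rainfall"], baseline=cfg.baseline)
    start, end = cfg.window
    fdi_window = fdi[(fdi["year"] >= int(start)) & (fdi["year"] <= int(np.ceil(end)))]
    loc_col = "climate_cell" if "climate_cell" in cleaned.columns else "location_id"
    rec = cleaned[["species", loc_col]].rename(columns={loc_col: "location_id"})
    profiles["mean_fdi"] = species_mean_fdi(rec, fdi_window).reindex(profiles.index)

    # ---- stage 7: comparative models -------------------------------------
    traits = bundle["traits"].set_index("species")
    profiles["strategy"] = traits["strategy"].reindex(profiles.index)
    tree = bundle["tree"]

    profiles["log_fri"] = np.log(profiles["median_fri"])
    profiles["log_frp"] = np.log(profiles["frp_q95"])

    fits = {}
    freq_df = profiles[profiles["fire_prone"]].dropna(
        subset=["log_fri", "mean_fdi", "strategy"]
    )
    if len(freq_df) >= 10:
        fits["frequency"] = _fit_glm(
            tree, freq_df, ["log_fri", "mean_fdi"], "strategy", cfg, "strategy ~ log FRI + FDI"
        )
    inten_df = profiles.dropna(subset=["log_frp", "mean_fdi", "strategy"])
    if len(inten_df) >= 10:
        fits["intensity"] = _fit_glm(
            tree, inten_df, ["log_frp", "mean_fdi"], "strategy", cfg, "strategy ~ log FRP + FDI"
        )

    if cfg.fit_trait_models:
        merged = traits.join(profiles[["fire_prone"]], how="left")
        for col in cfg.trait_columns:
            if col not in merged.columns:
                continue
            sub = merged.dropna(subset=[col, "strategy"])
            codes = pd.get_dummies(sub[col], drop_first=True).astype(float)
            if codes.shape[1] != 1:
                continue
            df = pd.DataFrame(
                {col: codes.iloc[:, 0], "strategy": sub["strategy"].astype(float)},
                index=sub.index,
            )
            try:
                fits[f"trait_{col}"] = _fit_glm(
                    tree, df, [col], "strategy", cfg, f"strategy ~ {col}"
                )
            except (ValueError, np.linalg.LinAlgError) as err:
                logger.warning("trait model %s skipped: %s", col, err)

    pgls_results = {}
    if cfg.fit_pgls:
        pairs = [
            ("log_fri", "log_frp"),
            ("mean_fdi", "frp_q95"),
            ("mean_fdi", "median_fri"),
        ]
        for xcol, ycol in pairs:
            sub = profiles.dropna(subset=[xcol, ycol])
            if len(sub) < 5:
                continue
            est = PGLS().fit(
                sub[[xcol]], sub[ycol].to_numpy(), tree=tree, species=list(sub.index)
            )
            pgls_results[f"{ycol}~{xcol}"] = {
                "slope": float(est.coef_[0]),
                "intercept": est.intercept_,
                "F": float(est.fstat_),
                "r2": float(est.rsquared_),
                "p": float(est.pvalue_),
                "n": est.n_,
            }

    report["n_species"] = len(profiles)
    report["n_fire_prone"] = int(profiles["fire_prone"].sum())
    report["n_with_fri"] = int(profiles["median_fri"].notna().sum())
    return {"profiles": profiles, "fits": fits, "pgls": pgls_results, "report": report}


def summarize_distributions(
    profiles: pd.DataFrame,
    value_cols: tuple[str, ...] = ("median_fri", "frp_q95"),
    strategy_col: str = "strategy",
    min_n_mode: int = 5,
) -> pd.DataFrame:
    """Median, SD and KDE mode per strategy for the given profile columns.

    The mode is the argmax of a Gaussian kernel density with Silverman
    bandwidth, evaluated on a fine grid over the sample range; it is omitted
    (NaN) for groups below ``min_n_mode``.
    """
    rows = []
    for col in value_cols:
        for strat, grp in profiles.dropna(subset=[col, strategy_col]).groupby(
            strategy_col
        ):
            vals = grp[col].to_numpy(float)
            row = {
                "variable": col,
                "strategy": strat,
                "n": len(vals),
                "median": float(np.median(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "mode": np.nan,
            }
            if len(vals) >= min_n_mode and np.ptp(vals) > 0:
                kde = stats.gaussian_kde(vals, bw_method="silverman")
                grid = np.linspace(vals.min(), vals.max(), 2048)
                row["mode"] = float(grid[np.argmax(kde(grid))])
            elif np.ptp(vals) == 0:
                row["mode"] = float(vals[0])
            rows.append(row)
    return pd.DataFrame(rows)
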