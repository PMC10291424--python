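"""Period-level joins, rank-association tests, and the full pipeline.

The headline question is directional: are periods of high wealth
inequality (house-size Gini) also periods of persistent settlement and of
a small unoccupied dry-farming niche? With a dozen-odd archaeological
periods and unknown marginals, the test is deliberately modest: Spearman
rank correlation across period rows with a permutation p-value.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import demodynamics, inequality, io, mobility, niche, synthetic
from .errors import AlignmentError, InsufficientDataError
from .periods import PeriodTable, default_period_grid

logger = logging.getLogger("copial")

ASSOCIATION_COLUMNS = [
    "period",
    "gini",
    "mean_persistence_yr",
    "mean_room_to_walk",
    "mean_unoccupied_niche_frac",
    "churn",
    "n_houses",
]

#: Column pairs whose rank association the pipeline reports by default.
DEFAULT_PAIRS = [
    ("gini", "mean_persistence_yr"),
    ("gini", "mean_unoccupied_niche_frac"),
    ("gini", "mean_room_to_walk"),
    ("gini", "churn"),
]


@dataclass(frozen=True)
class AssociationResult:
    pair: tuple[str, str]
    rho: float
    n_periods: int
    sign: str  # "+", "-", or "0"
    p_perm: float


def build_period_table(
    gini_series: pd.DataFrame,
    niche_series: pd.DataFrame,
    persistence: pd.DataFrame,
    churn_series: pd.DataFrame,
    periods: PeriodTable,
) -> pd.DataFrame:
    """Join all period-level covariates: exactly one row per period.

    Year-level niche statistics are aggregated to period means over the
    years inside each period. Missing cells stay NaN (they are never
    silently dropped). Raises AlignmentError when an input's period labels
    do not live on the supplied grid.
    """
    names = periods.names
    for df, col, label in [
        (gini_series, "period", "gini series"),
        (persistence, "period", "persistence table"),
        (churn_series, "period", "churn table"),
    ]:
        stray = set(df[col].dropna()) - set(names)
        if stray:
            raise AlignmentError(f"{label} has periods off the grid: {sorted(stray)}")

    out = pd.DataFrame({"period": names})
    out = out.merge(
        gini_series.rename(columns={"n": "n_houses"})[["period", "gini", "n_houses"]],
        on="period",
        how="left",
    )
    pers = persistence
    if "size_class" in pers.columns:  # village class is the persistence covariate
        pers = pers[pers["size_class"] == "village"]
    out = out.merge(
        pers.rename(columns={"mean_span_yr": "mean_persistence_yr"})[
            ["period", "mean_persistence_yr"]
        ],
        on="period",
        how="left",
    )

    year_period = {}
    for p in periods:
        for y in range(p.start_year, p.end_year + 1):
            year_period[y] = p.name
    ns = niche_series.copy()
    ns["period"] = ns["year"].map(year_period)
    agg = (
        ns.dropna(subset=["period"])
        .groupby("period")
        .agg(
            mean_room_to_walk=("room_to_walk", "mean"),
            mean_unoccupied_niche_frac=("unoccupied_niche_frac", "mean"),
        )
        .reset_index()
    )
    out = out.merge(agg, on="period", how="left")
    out = out.merge(churn_series[["period", "churn"]], on="period", how="left")
    out["n_houses"] = out["n_houses"].fillna(0).astype(int)
    return out[ASSOCIATION_COLUMNS]


def rank_association(
    table: pd.DataFrame,
    x: str,
    y: str,
    n_perm: int = 999,
    seed: int | np.random.SeedSequence = 0,
) -> AssociationResult:
    """Spearman rho between two period-level columns, permutation p-value.

    Rows where either column is undefined are excluded; at least 4 complete
    periods are required. The p-value is two-sided,
    (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1), from label shuffles of
    y; deterministic under seed.
    """
    sub = table[[x, y]].dropna()
    n = len(sub)
    if n < 4:
        raise InsufficientDataError(
            f"rank association needs >= 4 complete periods, got {n}"
        )
    xs = sub[x].to_numpy(dtype=float)
    ys = sub[y].to_numpy(dtype=float)
    rho = float(stats.spearmanr(xs, ys).statistic)
    rng = np.random.default_rng(seed)
    xr = stats.rankdata(xs)
    yr = stats.rankdata(ys)
    hits = 0
    for _ in range(n_perm):
        perm_rho = np.corrcoef(xr, rng.permutation(yr))[0, 1]
        if abs(perm_rho) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    sign = "0" if rho == 0 or math.isnan(rho) else ("+" if rho > 0 else "-")
    return AssociationResult((x, y), rho, n, sign, p)


# ---------------------------------------------------------------------------
# Pipeline orchestration


@dataclass
class PipelineConfig:
    """Everything run_all needs: generation, analysis and stage toggles."""

    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    niche: niche.NicheParams = field(default_factory=niche.NicheParams)
    periods: PeriodTable = field(default_factory=default_period_grid)
    gini_corrected: bool = False
    gini_bootstrap_B: int = 500
    gini_min_n: int = 5
    churn_threshold: float = mobility.CHURN_THRESHOLD_DEFAULT
    n_perm: int = 999
    run_demodynamics: bool = True
    demog_years: int = 1500

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            if "years" in syn:
                syn["years"] = tuple(syn["years"])
            if "migration_pulses" in syn:
                syn["migration_pulses"] = {
                    tuple(k.split("|")): v for k, v in syn["migration_pulses"].items()
                }
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        if "niche" in raw:
            cfg.niche = niche.NicheParams(**raw["niche"])
        if "periods" in raw:
            cfg.periods = PeriodTable(
                tuple(
                    mobility.Period(p["name"], p["start_year"], p["end_year"])
                    for p in raw["periods"]
                )
            )
        for key in (
            "gini_corrected",
            "gini_bootstrap_B",
            "gini_min_n",
            "churn_threshold",
            "n_perm",
            "run_demodynamics",
            "demog_years",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


def run_all(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Execute the full pipeline and write every stage CSV plus a manifest.

    Stages: synthetic generation -> niche series -> Gini series ->
    churn + persistence -> (optional) demographic reference run ->
    period-level join -> rank associations. ``seed`` overrides the
    synthetic config's seed, and also seeds the bootstrap and permutation
    streams. Identical (config, seed) reproduces every output byte for
    byte. Returns the report bundle as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    if seed is not None:
        cfg.synthetic.seed = int(seed)
    seed_eff = int(cfg.synthetic.seed)
    periods = cfg.periods

    logger.info("stage synthetic: generating landscape, occupation, houses, populations")
    cells = synthetic.gen_landscape(cfg.synthetic, periods)
    ledger = synthetic.gen_occupation(cells, cfg.synthetic, periods, cfg.niche)
    houses = synthetic.gen_houses(cfg.synthetic, periods, ledger)
    pops = synthetic.gen_subregion_pops(cfg.synthetic, periods)
    io.write_csv(cells, out / "cells.csv")
    io.write_csv(ledger, out / "occupations.csv")
    io.write_csv(houses, out / "houses.csv")
    io.write_csv(pops, out / "populations.csv")
    io.write_periods(periods, out / "periods.csv")

    logger.info("stage niche: annual niche/occupancy series")
    ns = niche.niche_series(cells, ledger, cfg.niche)
    io.write_csv(ns, out / "niche_series.csv")

    logger.info("stage inequality: Gini by period (B=%d)", cfg.gini_bootstrap_B)
    estimates = inequality.gini_by_period(
        houses,
        periods,
        corrected=cfg.gini_corrected,
        B=cfg.gini_bootstrap_B,
        seed=seed_eff,
        min_n=cfg.gini_min_n,
    )
    gs = inequality.gini_series_frame(estimates)
    io.write_csv(gs, out / "gini_series.csv")

    logger.info("stage mobility: churn and persistence")
    churn_results = mobility.churn(pops, periods, cfg.churn_threshold)
    cf = mobility.churn_frame(churn_results)
    io.write_csv(cf, out / "churn.csv")
    pers = mobility.persistence_by_period(ledger, periods)
    io.write_csv(pers, out / "persistence.csv")

    phase_report = None
    if cfg.run_demodynamics:
        logger.info("stage demodynamics: reference run (%d years)", cfg.demog_years)
        params = demodynamics.default_params()
        traj = demodynamics.run(params, years=cfg.demog_years)
        io.write_csv(traj.frame(), out / "trajectory.csv")
        phases = demodynamics.detect_phases(traj)
        phase_report = {
            "copial_end_year": phases.copial_end_year,
            "malthusian_start_year": phases.malthusian_start_year,
            "copial_duration": phases.copial_duration,
            "mti_duration": phases.mti_duration,
            "status": phases.status,
        }
        io.write_csv(pd.DataFrame([phase_report]), out / "phase_report.csv")

    logger.info("stage association: period join and rank tests")
    table = build_period_table(gs, ns, pers, cf, periods)
    io.write_csv(table, out / "association_table.csv")
    results = []
    ss = np.random.SeedSequence(seed_eff).spawn(len(DEFAULT_PAIRS))
    for (x, y), sub_ss in zip(DEFAULT_PAIRS, ss):
        try:
            r = rank_association(table, x, y, n_perm=cfg.n_perm, seed=sub_ss)
        except InsufficientDataError as exc:
            logger.warning("association %s~%s skipped: %s", x, y, exc)
            continue
        results.append(
            {"x": r.pair[0], "y": r.pair[1], "rho": r.rho, "n_periods": r.n_periods,
             "sign": r.sign, "p_perm": r.p_perm}
        )
    io.write_csv(pd.DataFrame(results), out / "associations.csv")

    manifest = {
        "seed": seed_eff,
        "synthetic": cfg.synthetic.manifest(),
        "niche": {
            "precip_threshold_cm": cfg.niche.precip_threshold_cm,
            "fgdd_threshold": cfg.niche.fgdd_threshold,
            "occupancy_lookback_yr": cfg.niche.occupancy_lookback_yr,
            "smoothing_window_yr": cfg.niche.smoothing_window_yr,
            "inclusive_thresholds": cfg.niche.inclusive_thresholds,
            "window_includes_current": cfg.niche.window_includes_current,
        },
        "analysis": {
            "gini_corrected": cfg.gini_corrected,
            "gini_bootstrap_B": cfg.gini_bootstrap_B,
            "gini_min_n": cfg.gini_min_n,
            "churn_threshold": cfg.churn_threshold,
            "n_perm": cfg.n_perm,
            "run_demodynamics": cfg.run_demodynamics,
            "demog_years": cfg.demog_years,
        },
        "periods": cfg.periods.to_frame().to_dict(orient="records"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    bundle = {
        "association_table": table,
        "associations": results,
        "phase_report": phase_report,
        "manifest": manifest,
    }
    return bundle
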