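"""End-to-end orchestration: levels -> decomposition -> association.

Regional rate grids are population-weighted means of member-country rates
(weights are the age-specific population counts), built before life-table
construction.  All stages run within (region, sex) strata; the analysis
year pair defaults to (1990, 2019).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import WeightedScatter, region_trajectory, weighted_loess
from .decomposition import F_from_rates, decompose_F_change
from .gbd_io import AgeScheme, CauseScheme, MortalityPanel, PanelSlice, logger, write_results_tables
from .lifetable import build_life_table, life_disparity
from .uncertainty import envelope, significant_difference


@dataclass
class RunConfig:
    """Run-level knobs; mirrors the YAML config and CLI flags."""

    year_pair: tuple[int, int] = (1990, 2019)
    n_draws: int = 1000
    seed: int = 0
    n_steps: int = 20
    loess_span: float = 0.75
    loess_degree: int = 1
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.year_pair[0] == self.year_pair[1]:
            raise ValueError("analysis years must be distinct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "year_pair" in raw:
            raw["year_pair"] = tuple(raw["year_pair"])
        return cls(**raw)


def aggregate_region_slice(
    panel: MortalityPanel, region: str, sex: str, year: int
) -> PanelSlice:
    """Population-weighted mean of country rate grids within a region."""
    df = panel.data
    members = df.loc[df["region"] == region, "location"].unique()
    if len(members) == 0:
        raise KeyError(f"no locations in region {region!r}")
    num_r = num_lo = num_hi = 0.0
    den = 0.0
    pop_total = 0.0
    for loc in members:
        s = panel.get_slice(loc, sex, year)
        w = s.population[:, None]
        num_r = num_r + w * s.rates
        num_lo = num_lo + w * s.lower
        num_hi = num_hi + w * s.upper
        den = den + w
        pop_total = pop_total + s.population
    den = np.where(den > 0, den, 1.0)
    return PanelSlice(rates=num_r / den, lower=num_lo / den, upper=num_hi / den,
                      population=pop_total, location=region, region=region,
                      sex=sex, year=year)


def _slice_summaries(rates: np.ndarray, age_scheme: AgeScheme) -> tuple[float, float, float]:
    m = rates.sum(axis=1)
    lt = build_life_table(m, age_scheme)
    return F_from_rates(rates, age_scheme), lt.e0, life_disparity(lt)


def run_levels(cfg: RunConfig, panel: MortalityPanel) -> pd.DataFrame:
    """Regional F with 95% envelopes for both analysis years, the 1990-2019
    change, its significance, and the male-female gap per year."""
    ages = panel.age_scheme
    y1, y2 = cfg.year_pair
    regions = panel.data["region"].unique()
    sexes = panel.data["sex"].unique()
    stat = lambda rates: F_from_rates(rates, ages)
    rows = []
    for region in regions:
        for sex in sexes:
            s1 = aggregate_region_slice(panel, region, sex, y1)
            s2 = aggregate_region_slice(panel, region, sex, y2)
            env1 = envelope(stat, s1, cfg.n_draws, cfg.seed)
            env2 = envelope(stat, s2, cfg.n_draws, cfg.seed + 1)
            sig, diff_env = significant_difference(stat, s1, s2, cfg.n_draws, cfg.seed)
            for year, env in ((y1, env1), (y2, env2)):
                rows.append({
                    "region": region, "sex": sex, "year": year,
                    "F": env.point, "lower": env.lower, "upper": env.upper,
                    "diff": diff_env.point, "significant": sig,
                })
            logger.info("levels %s/%s: F(%d)=%.3f F(%d)=%.3f diff=%+.3f sig=%s",
                        region, sex, y1, env1.point, y2, env2.point,
                        diff_env.point, sig)
    levels = pd.DataFrame(rows)
    # male - female gap per region-year
    if {"male", "female"} <= set(sexes):
        wide = levels.pivot_table(index=["region", "year"], columns="sex", values="F")
        gaps = (wide["male"] - wide["female"]).rename("sex_gap").reset_index()
        levels = levels.merge(gaps, on=["region", "year"], how="left")
    return levels


def run_decomposition(cfg: RunConfig, panel: MortalityPanel) -> pd.DataFrame:
    """Cause x age contributions to the F change per (region, sex)."""
    ages, scheme = panel.age_scheme, panel.cause_scheme
    y1, y2 = cfg.year_pair
    labels = ages.labels()
    rows = []
    for region in panel.data["region"].unique():
        for sex in panel.data["sex"].unique():
            s1 = aggregate_region_slice(panel, region, sex, y1)
            s2 = aggregate_region_slice(panel, region, sex, y2)
            dm = decompose_F_change(s1.rates, s2.rates, ages, scheme, cfg.n_steps)
            logger.info("decompose %s/%s: total=%+.4f residual=%.2e",
                        region, sex, dm.total, dm.residual)
            for ai in range(ages.n):
                for j, cause in enumerate(scheme.causes):
                    rows.append({
                        "region": region, "sex": sex, "cause": cause,
                        "level1": scheme.level1_of[cause],
                        "age": labels[ai],
                        "age_lower": ages.lower_bounds[ai],
                        "contribution": dm.contribution[ai, j],
                        "total": dm.total,
                    })
    return pd.DataFrame(rows)


def run_association(cfg: RunConfig, panel: MortalityPanel) -> dict[str, pd.DataFrame]:
    """Country-level F/e0/e-dagger table, per-year weighted LOESS curves for
    both predictors, and regional year-by-year trajectories."""
    ages = panel.age_scheme
    df = panel.data
    y1, y2 = cfg.year_pair
    all_years = sorted(df["year"].unique())
    sexes = df["sex"].unique()

    # country-level points for the fit years
    pts = []
    for (loc, sex, year), grp in df.groupby(["location", "sex", "year"], sort=False):
        if year not in (y1, y2):
            continue
        s = panel.get_slice(loc, sex, year)
        F, e0, ed = _slice_summaries(s.rates, ages)
        pts.append({"location": loc, "region": s.region, "sex": sex, "year": year,
                    "F": F, "e0": e0, "e_dagger": ed,
                    "population": float(s.population.sum())})
    points = pd.DataFrame(pts)

    curves = []
    for sex in sexes:
        for year in (y1, y2):
            sub = points[(points["sex"] == sex) & (points["year"] == year)]
            for predictor in ("e0", "e_dagger"):
                sc = WeightedScatter(x=sub[predictor].to_numpy(),
                                     y=sub["F"].to_numpy(),
                                     w=sub["population"].to_numpy())
                curve = weighted_loess(sc, span=cfg.loess_span,
                                       degree=cfg.loess_degree, n_grid=50)
                curves.append(pd.DataFrame({
                    "sex": sex, "year": year, "predictor": predictor,
                    "x": curve.grid, "fitted": curve.fitted,
                    "span": curve.span, "degree": curve.degree,
                }))
    curves_df = pd.concat(curves, ignore_index=True)

    # regional trajectories over every year
    traj_rows = []
    for region in df["region"].unique():
        for sex in sexes:
            for year in all_years:
                s = aggregate_region_slice(panel, region, sex, year)
                F, e0, ed = _slice_summaries(s.rates, ages)
                traj_rows.append({"region": region, "sex": sex, "year": year,
                                  "F": F, "e0": e0, "e_dagger": ed})
    traj_df = pd.DataFrame(traj_rows)
    region_trajectory(traj_df)  # validates contiguity
    return {"points": points, "loess_curves": curves_df, "trajectories": traj_df}


def run_all(cfg: RunConfig, panel: MortalityPanel) -> dict[str, pd.DataFrame]:
    """Full pipeline; writes every output table under ``cfg.out_dir``."""
    results: dict[str, pd.DataFrame] = {"levels": run_levels(cfg, panel)}
    results["decomposition"] = run_decomposition(cfg, panel)
    results.update(run_association(cfg, panel))
    write_results_tables(results, cfg.out_dir)
    return results
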