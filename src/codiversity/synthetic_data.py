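"""Synthetic GBD-like mortality panels with known ground truth.

The generator emulates the structure of a GBD results extract — 21 level-2
causes in 3 level-1 groups, GBD age groups, regions x countries x sexes x
years with asymmetric uncertainty bounds and population counts — driven by
a stylized epidemiological transition:

* communicable/maternal/neonatal/nutritional causes follow a young-age-
  concentrated hazard whose level declines exponentially over time;
* non-communicable causes follow Gompertz hazards, with a cardiovascular
  share that rises and then falls over the transition;
* injuries have an age-flat hazard (with a young-adult hump) and a male
  excess multiplier.

Regions are staggered along the transition clock, so a cross-section of
regions spans early- to late-transition mortality profiles.  Because the
exact cause-age rates are parametric, every slice's true F, e0 and
e-dagger are computable noise-free, giving exact oracles for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .gbd_io import (
    DEFAULT_REGIONS,
    AgeScheme,
    CauseScheme,
    MortalityPanel,
)
from .decomposition import F_from_rates
from .lifetable import build_life_table, life_disparity

SEXES = ("female", "male")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the stylized epidemiological-transition scenario.

    Hazard units are deaths per person-year.  ``comm_level`` is the
    communicable hazard scale at transition time zero and declines at
    ``comm_decline_rate`` per year; ``ncd_level`` is the all-NCD Gompertz
    hazard at age 80 with slope ``gompertz_slope`` per year of age;
    ``cvd_amp``/``cvd_peak``/``cvd_width`` shape the rise-and-fall of the
    cardiovascular share over the transition clock.  Regions are offset
    along that clock by ``region_offsets`` (years).
    """

    n_regions: int = 7
    countries_per_region: int = 3
    years: tuple[int, int] = (1990, 2019)
    seed: int = 20190
    mode: str = "transition"  # or "uniform": equal rates across all causes

    # hazard templates
    comm_level: float = 0.06
    comm_decline_rate: float = 0.045
    comm_age_scale: float = 10.0
    comm_background: float = 0.015
    ncd_level: float = 0.05
    gompertz_slope: float = 0.10
    cvd_amp: float = 1.3
    cvd_peak: float = 45.0
    cvd_width: float = 18.0
    inj_level: float = 4e-4
    inj_sex_multiplier: float = 2.5
    female_ncd_multiplier: float = 0.9
    country_jitter_sd: float = 0.08
    country_clock_jitter: float = 3.0

    # observation model
    uncertainty_width: float = 0.05
    population_range: tuple[float, float] = (1e6, 1e8)

    region_offsets: tuple[float, ...] | None = None

    # cause-group share vectors (normalized within group)
    cmnn_weights: tuple[float, ...] = (0.28, 0.22, 0.16, 0.12, 0.10, 0.07, 0.05)
    ncd_weights: tuple[float, ...] = (0.34, 0.22, 0.09, 0.08, 0.06, 0.06, 0.04, 0.04, 0.03, 0.02, 0.02)
    inj_weights: tuple[float, ...] = (0.40, 0.35, 0.25)

    cause_scheme: CauseScheme = field(default_factory=CauseScheme.default)
    age_scheme: AgeScheme = field(default_factory=AgeScheme.gbd_default)

    def offsets(self) -> np.ndarray:
        if self.region_offsets is not None:
            return np.asarray(self.region_offsets, dtype=float)
        return np.linspace(0.0, 60.0, self.n_regions)

    def region_names(self) -> list[str]:
        if self.n_regions == len(DEFAULT_REGIONS):
            return list(DEFAULT_REGIONS)
        return [f"R{i + 1}" for i in range(self.n_regions)]


@dataclass
class GroundTruth:
    """Exact generator rates and summary statistics per (location, sex, year)."""

    rates: dict[tuple[str, str, int], np.ndarray]
    population: dict[str, np.ndarray]  # location -> per-age persons
    region_of: dict[str, str]
    age_scheme: AgeScheme
    cause_scheme: CauseScheme

    def F(self, location: str, sex: str, year: int) -> float:
        return F_from_rates(self.rates[(location, sex, year)], self.age_scheme)

    def e0(self, location: str, sex: str, year: int) -> float:
        m = self.rates[(location, sex, year)].sum(axis=1)
        return build_life_table(m, self.age_scheme).e0

    def e_dagger(self, location: str, sex: str, year: int) -> float:
        m = self.rates[(location, sex, year)].sum(axis=1)
        return life_disparity(build_life_table(m, self.age_scheme))

    def region_rates(self, region: str, sex: str, year: int) -> np.ndarray:
        """Population-weighted mean of member-country true rates."""
        members = [c for c, r in self.region_of.items() if r == region]
        num = 0.0
        den = 0.0
        for c in members:
            w = self.population[c][:, None]
            num = num + w * self.rates[(c, sex, year)]
            den = den + w
        return num / den

    def region_F(self, region: str, sex: str, year: int) -> float:
        return F_from_rates(self.region_rates(region, sex, year), self.age_scheme)


def _age_midpoints(scheme: AgeScheme) -> np.ndarray:
    lb = np.asarray(scheme.lower_bounds, dtype=float)
    w = scheme.widths
    mid = lb + w / 2.0
    mid[w == 1.0] = lb[w == 1.0] + 0.3  # infant deaths concentrate early
    mid[-1] = lb[-1] + 5.0
    return mid


def _group_columns(scheme: CauseScheme) -> dict[str, list[int]]:
    cols: dict[str, list[int]] = {}
    for j, c in enumerate(scheme.causes):
        cols.setdefault(scheme.level1_of[c], []).append(j)
    return cols


def true_rates(cfg: ScenarioConfig, tau: float, sex: str,
               cause_jitter: np.ndarray | None = None) -> np.ndarray:
    """Exact cause-age rate grid at transition time ``tau`` (years)."""
    scheme = cfg.cause_scheme
    A, k = cfg.age_scheme.n, scheme.k
    x = _age_midpoints(cfg.age_scheme)
    m = np.zeros((A, k))

    if cfg.mode == "uniform":
        # identical hazard for every cause: cause fractions are 1/k at all
        # ages, so F is exactly (k-1)/k whatever the age pattern
        total = 0.01 + 0.05 * np.exp(cfg.gompertz_slope * (x - 80.0))
        m[:] = total[:, None] / k
        return m

    groups = _group_columns(scheme)
    shape_cmnn = np.exp(-x / cfg.comm_age_scale) + cfg.comm_background
    shape_ncd = np.exp(cfg.gompertz_slope * (x - 80.0))
    shape_inj = 1.0 + 0.5 * np.exp(-(((x - 22.0) / 8.0) ** 2))

    C = cfg.comm_level * np.exp(-cfg.comm_decline_rate * tau)
    w_cmnn = np.asarray(cfg.cmnn_weights)
    w_cmnn = w_cmnn / w_cmnn.sum()
    w_ncd = np.asarray(cfg.ncd_weights)
    w_ncd = w_ncd / w_ncd.sum()
    w_ncd = w_ncd.copy()
    w_ncd[0] *= 1.0 + cfg.cvd_amp * np.exp(-(((tau - cfg.cvd_peak) / cfg.cvd_width) ** 2))
    w_inj = np.asarray(cfg.inj_weights)
    w_inj = w_inj / w_inj.sum()

    ncd_mult = cfg.female_ncd_multiplier if sex == "female" else 1.0
    inj_mult = cfg.inj_sex_multiplier if sex == "male" else 1.0

    from .gbd_io import CMNN, NCD, INJ

    m[:, groups[CMNN]] = C * shape_cmnn[:, None] * w_cmnn[None, :]
    m[:, groups[NCD]] = cfg.ncd_level * ncd_mult * shape_ncd[:, None] * w_ncd[None, :]
    m[:, groups[INJ]] = cfg.inj_level * inj_mult * shape_inj[:, None] * w_inj[None, :]
    if cause_jitter is not None:
        m = m * cause_jitter[None, :]
    return m


def _assemble_panel(
    cfg: ScenarioConfig,
    truth: GroundTruth,
    values: Mapping[tuple[str, str, int], np.ndarray],
) -> MortalityPanel:
    scheme, ages = cfg.cause_scheme, cfg.age_scheme
    A, k = ages.n, scheme.k
    age_idx = np.repeat(np.arange(A), k)
    causes = np.tile(np.array(scheme.causes, dtype=object), A)
    frames = []
    wfrac = cfg.uncertainty_width
    for (loc, sex, year), val in values.items():
        flat = val.ravel()
        frames.append(pd.DataFrame({
            "location": loc,
            "region": truth.region_of[loc],
            "sex": sex,
            "year": year,
            "age_index": age_idx,
            "cause": causes,
            "rate": flat,
            "lower": flat * (1.0 - wfrac),
            "upper": flat * (1.0 + wfrac),
            "population": np.repeat(truth.population[loc], k),
        }))
    panel = MortalityPanel(pd.concat(frames, ignore_index=True), scheme, ages)
    panel.validate()
    return panel


def generate_panel(cfg: ScenarioConfig) -> tuple[MortalityPanel, GroundTruth]:
    """Generate a noise-free panel (point estimates equal the exact rates).

    Uncertainty bounds are point x (1 -/+ uncertainty_width).  Country
    heterogeneity (per-cause level jitter, a small offset on the transition
    clock, log-uniform population sizes) is drawn deterministically from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    regions = cfg.region_names()
    offsets = cfg.offsets()
    y0, y1 = cfg.years
    years = range(y0, y1 + 1)
    x = _age_midpoints(cfg.age_scheme)

    rates: dict[tuple[str, str, int], np.ndarray] = {}
    population: dict[str, np.ndarray] = {}
    region_of: dict[str, str] = {}
    lo_pop, hi_pop = cfg.population_range
    age_shares = np.exp(-0.02 * x)
    age_shares = age_shares / age_shares.sum()

    for r, region in enumerate(regions):
        for c in range(cfg.countries_per_region):
            loc = f"{region}-{c + 1:02d}"
            region_of[loc] = region
            jitter = np.exp(rng.normal(0.0, cfg.country_jitter_sd, size=cfg.cause_scheme.k))
            clock = rng.uniform(-cfg.country_clock_jitter, cfg.country_clock_jitter)
            total_pop = np.exp(rng.uniform(np.log(lo_pop), np.log(hi_pop)))
            population[loc] = total_pop * age_shares
            for sex in SEXES:
                for year in years:
                    tau = (year - y0) + offsets[r] + clock
                    rates[(loc, sex, year)] = true_rates(cfg, tau, sex, jitter)

    truth = GroundTruth(rates=rates, population=population, region_of=region_of,
                        age_scheme=cfg.age_scheme, cause_scheme=cfg.cause_scheme)
    panel = _assemble_panel(cfg, truth, rates)
    return panel, truth


def perturb_observations(
    cfg: ScenarioConfig, truth: GroundTruth, seed: int
) -> MortalityPanel:
    """An observed panel: truth times independent relative normal noise.

    The noise sd matches the stated interval half-width, width/1.96 in
    relative terms, so the reported bounds are calibrated 95% intervals
    for the truth.
    """
    rng = np.random.default_rng(seed)
    sd = cfg.uncertainty_width / 1.959963984540054
    values = {
        key: np.clip(m * (1.0 + rng.normal(0.0, sd, size=m.shape)), 0.0, None)
        for key, m in truth.rates.items()
    }
    return _assemble_panel(cfg, truth, values)


def generate_null_pair(
    cfg: ScenarioConfig, seed: int
) -> tuple[MortalityPanel, MortalityPanel, GroundTruth]:
    """Two observed panels sharing the same ground truth, independent noise.

    With uncertainty_width 0 both panels equal the truth exactly; the true
    difference of any statistic between them is zero by construction.
    """
    _, truth = generate_panel(cfg)
    ss = np.random.SeedSequence(seed).spawn(2)
    a = perturb_observations(cfg, truth, ss[0].generate_state(1)[0] % (2**31))
    b = perturb_observations(cfg, truth, ss[1].generate_state(1)[0] % (2**31))
    return a, b, truth


def transition_scenario(**overrides) -> ScenarioConfig:
    """The default stylized epidemiological-transition scenario."""
    return replace(ScenarioConfig(), **overrides) if overrides else ScenarioConfig()


def uniform_scenario(**overrides) -> ScenarioConfig:
    """Every cause equally hazardous at every age: F = (k-1)/k everywhere."""
    return replace(ScenarioConfig(mode="uniform"), **overrides)
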