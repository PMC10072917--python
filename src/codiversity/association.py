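"""Population-weighted LOESS and region trajectories.

Relates cause-of-death diversity (F) to life expectancy at birth (e0) and
life disparity (e-dagger) across country-sex-year observations.  The
smoother is classical LOESS — a local polynomial weighted least-squares
fit with tricube kernel weights — with the kernel weight of each point
additionally multiplied by its population, so populous countries pull the
curve more.  Trajectories are raw (unsmoothed) year-ordered paths per
region and sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WeightedScatter:
    """Observations (x, y) with population weights and context labels."""

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if not (len(x) == len(y) == len(w)):
            raise ValueError("x, y, w must have equal lengths")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        for name, arr in (("x", x), ("y", y), ("w", w)):
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class SmoothCurve:
    grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    inside = np.abs(u) < 1
    out[inside] = (1 - np.abs(u[inside]) ** 3) ** 3
    return out


def weighted_loess(
    scatter: WeightedScatter,
    span: float = 0.75,
    degree: int = 1,
    grid: Sequence[float] | None = None,
    n_grid: int = 100,
) -> SmoothCurve:
    """LOESS with tricube kernel weights multiplied by population weights.

    At each grid point g the bandwidth is the distance to the
    ceil(span * n)-th nearest positively weighted observation; the fit is a
    degree-``degree`` polynomial weighted least squares on the windowed
    points, evaluated at g.  The default grid is 100 equispaced points on
    [min x, max x] (no extrapolation).  The curve is invariant to a common
    rescaling of the population weights.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    keep = scatter.w > 0  # zero-weight points carry no information
    x, y, w = scatter.x[keep], scatter.y[keep], scatter.w[keep]
    n = len(x)
    if n < degree + 2:
        raise ValueError("need at least degree + 2 positively weighted points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < x.min() - 1e-12 or grid.max() > x.max() + 1e-12:
        raise ValueError("grid must lie within the data range (no extrapolation)")

    q = max(int(np.ceil(span * n)), degree + 1)
    fitted = np.empty_like(grid)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.partition(d, q - 1)[q - 1]
        if h == 0:
            h = max(d.max(), 1e-12)  # all nearest points at g itself
        wt = _tricube(d / h) * w
        use = wt > 0
        if use.sum() < degree + 1 or len(np.unique(x[use])) < degree + 1:
            raise ValueError(f"singular local fit at grid point {g!r}")
        X = np.vander(x[use] - g, degree + 1, increasing=True)
        sw = np.sqrt(wt[use])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[use] * sw, rcond=None)
        fitted[i] = beta[0]
    return SmoothCurve(grid=grid, fitted=fitted, span=float(span), degree=int(degree))


def region_trajectory(results: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    """Year-ordered (e0, e_dagger, F) paths per (region, sex), unsmoothed.

    ``results`` needs columns region, sex, year, F and any predictor
    columns (e0, e_dagger).  Years must be contiguous within each
    region-sex; gaps raise an error listing the missing years.
    """
    required = {"region", "sex", "year", "F"}
    if not required <= set(results.columns):
        raise ValueError(f"results missing columns: {sorted(required - set(results.columns))}")
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for (region, sex), grp in results.groupby(["region", "sex"], sort=False):
        grp = grp.sort_values("year").reset_index(drop=True)
        years = grp["year"].to_numpy()
        expected = np.arange(years.min(), years.max() + 1)
        missing = sorted(set(expected) - set(years))
        if missing:
            raise ValueError(f"({region}, {sex}) missing years: {missing}")
        out[(str(region), str(sex))] = grp
    return out
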