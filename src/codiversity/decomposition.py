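"""Horiuchi (line-integral / stepwise-replacement) decomposition.

Attributes the change in a scalar functional of a covariate array between
two time points to each covariate, by integrating the functional's partial
sensitivities along a proportional-change path from the first covariate
array to the second.  Specialized here to decompose the change in the
fractionalization index F between two years into cause x age
contributions, with cause-age-specific mortality rates m(x, c) as the
covariates (the all-cause rate is their sum, so the life table responds to
every covariate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gbd_io import AgeScheme, CauseScheme
from .diversity import cause_proportions_from_lifetable, fractionalization
from .lifetable import build_life_table, partition_deaths_by_cause


@dataclass(frozen=True)
class DecompositionMatrix:
    """Cause x age contributions to a change in a scalar functional.

    ``contribution`` sums exactly to ``total`` (the raw numerical residual
    of the midpoint rule, recorded in ``residual``, has been redistributed
    proportionally to absolute contributions).
    """

    contribution: np.ndarray
    total: float
    residual: float
    n_steps: int

    def cause_marginals(self) -> np.ndarray:
        """Per-cause totals (sums over age groups)."""
        return self.contribution.sum(axis=0)

    def age_marginals(self) -> np.ndarray:
        return self.contribution.sum(axis=1)

    def level1_by_age(self, scheme: CauseScheme) -> dict[str, np.ndarray]:
        """Age profiles of contributions aggregated to level-1 groups."""
        out: dict[str, np.ndarray] = {}
        for g in scheme.level1_groups:
            cols = [j for j, c in enumerate(scheme.causes) if scheme.level1_of[c] == g]
            out[g] = self.contribution[:, cols].sum(axis=1)
        return out


def _path_values(c1: np.ndarray, c2: np.ndarray, t: float) -> np.ndarray:
    """Proportional (log-linear) path; linear where an endpoint is zero."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_path = c1 * np.exp(t * np.log(np.where(c1 > 0, c2 / np.where(c1 > 0, c1, 1.0), 1.0)))
    linear = c1 + t * (c2 - c1)
    both_pos = (c1 > 0) & (c2 > 0)
    return np.where(both_pos, log_path, linear)


def horiuchi_decompose(
    f,
    c1,
    c2,
    n_steps: int = 20,
    *,
    distribute_residual: bool = True,
) -> DecompositionMatrix:
    """Decompose f(c2) - f(c1) into per-covariate contributions.

    The path from c1 to c2 is split into ``n_steps`` equal segments; within
    each segment every covariate in turn is moved across the segment while
    the others are held at the segment midpoint (a midpoint central
    difference).  Contributions approximate the line integral of the
    partial derivatives; the small residual of the midpoint rule is
    redistributed proportionally to absolute contributions so that the
    contributions add up to f(c2) - f(c1) exactly.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("covariate arrays must share a grid")
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    shape = c1.shape
    flat1, flat2 = c1.ravel(), c2.ravel()
    J = flat1.size
    moving = np.nonzero(flat1 != flat2)[0]  # fixed cells contribute exactly 0

    contrib = np.zeros(J)
    for s in range(1, n_steps + 1):
        t0 = (s - 1) / n_steps
        t1 = s / n_steps
        tm = 0.5 * (t0 + t1)
        base = _path_values(flat1, flat2, tm)
        y0 = _path_values(flat1, flat2, t0)
        y1 = _path_values(flat1, flat2, t1)
        x = base.copy()
        xs = x.reshape(shape)
        for j in moving:
            x[j] = y1[j]
            f_hi = f(xs)
            x[j] = y0[j]
            f_lo = f(xs)
            x[j] = base[j]
            if not (np.isfinite(f_hi) and np.isfinite(f_lo)):
                raise FloatingPointError(
                    f"functional non-finite at step {s}/{n_steps}, covariate {j}"
                )
            contrib[j] += f_hi - f_lo

    total = float(f(c2) - f(c1))
    residual = total - contrib.sum()
    if distribute_residual:
        weights = np.abs(contrib)
        wsum = weights.sum()
        if wsum > 0:
            contrib += residual * weights / wsum
        elif moving.size:
            contrib[moving] += residual / moving.size
    return DecompositionMatrix(
        contribution=contrib.reshape(shape), total=total,
        residual=float(residual), n_steps=n_steps,
    )


def F_from_rates(m_xc: np.ndarray, age_scheme: AgeScheme) -> float:
    """Fractionalization of life-table deaths implied by rates m(x, c).

    The all-cause rate is the row sum; within each age group life-table
    deaths are split across causes proportionally to the cause-specific
    rates (the standard multi-decrement assumption).
    """
    m_xc = np.asarray(m_xc, dtype=float)
    m_x = m_xc.sum(axis=1)
    lt = build_life_table(m_x, age_scheme)
    with np.errstate(divide="ignore", invalid="ignore"):
        fractions = np.where(m_x[:, None] > 0, m_xc / np.where(m_x[:, None] > 0, m_x[:, None], 1.0), 0.0)
    cdm = partition_deaths_by_cause(lt, fractions)
    return fractionalization(cause_proportions_from_lifetable(cdm))


def decompose_F_change(
    m1_xc: np.ndarray,
    m2_xc: np.ndarray,
    age_scheme: AgeScheme,
    cause_scheme: CauseScheme,
    n_steps: int = 20,
) -> DecompositionMatrix:
    """Cause x age decomposition of the change in F between two rate grids."""
    m1_xc = np.asarray(m1_xc, dtype=float)
    m2_xc = np.asarray(m2_xc, dtype=float)
    expected = (age_scheme.n, cause_scheme.k)
    if m1_xc.shape != expected or m2_xc.shape != expected:
        raise ValueError(f"rate grids must have shape {expected}")
    return horiuchi_decompose(lambda m: F_from_rates(m, age_scheme), m1_xc, m2_xc, n_steps)
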