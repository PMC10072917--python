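"""Period life-table construction, life disparity (e-dagger) and
cause-partitioned life-table deaths.

The table is built from all-cause age-specific mortality rates m(x) on an
abridged age grid with an open terminal interval, radix 1.0, so that the
life-table deaths d(x) are directly the death-distribution proportions.
Two scalar summaries matter downstream: life expectancy at birth e0 and
life disparity e† (the average remaining life expectancy at the ages when
people die, a measure of lifespan inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gbd_io import AgeScheme


@dataclass(frozen=True)
class LifeTable:
    """Abridged period life table with radix 1.0.

    Arrays are indexed by age group: ``m`` (rate /person-year), ``q``
    (death probability), ``a`` (average person-years lived in the interval
    by those dying in it), ``l`` (survivors), ``d`` (life-table deaths,
    summing to 1), ``L`` (person-years), ``T`` (person-years above the
    interval start) and ``e`` (remaining expectancy in years).
    """

    age_lower: np.ndarray
    width: np.ndarray  # last entry inf (open interval)
    m: np.ndarray
    q: np.ndarray
    a: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray

    @property
    def e0(self) -> float:
        """Life expectancy at birth (years)."""
        return float(self.T[0])

    @property
    def e_dagger(self) -> float:
        """Life disparity e† (years); see :func:`life_disparity`."""
        return life_disparity(self)


def _nax(m: np.ndarray, widths: np.ndarray, lower: np.ndarray) -> np.ndarray:
    """Average years lived in the interval by decedents.

    Mid-interval (n/2) for closed intervals, except the infant interval
    <1 where a0 = 0.07 + 1.7*m0 (capped to [0.01, 0.35]) separates the
    early concentration of infant deaths.  The open interval's entry is
    unused (exponential closure).
    """
    a = widths / 2.0
    if lower[0] == 0.0 and widths[0] == 1.0:
        a[0] = float(np.clip(0.07 + 1.7 * m[0], 0.01, 0.35))
    a[-1] = np.nan
    return a


def build_life_table(m, age_scheme: AgeScheme) -> LifeTable:
    """Build a period life table from all-cause rates on the age scheme.

    Closed intervals use q = n*m / (1 + (n - a)*m) capped at 1; the open
    terminal interval has q = 1 and L = l/m (exponential closure), which
    requires m > 0 there.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (age_scheme.n,):
        raise ValueError(f"m has shape {m.shape}, expected ({age_scheme.n},)")
    if not np.all(np.isfinite(m)) or np.any(m < 0):
        raise ValueError("rates must be finite and non-negative")
    if m[-1] <= 0:
        raise ValueError("open-interval rate must be positive (closure is l/m)")

    lower = np.asarray(age_scheme.lower_bounds, dtype=float)
    n = age_scheme.widths
    a = _nax(m, n.copy(), lower)

    q = np.empty_like(m)
    nc, ac, mc = n[:-1], a[:-1], m[:-1]
    q[:-1] = np.minimum(nc * mc / (1.0 + (nc - ac) * mc), 1.0)
    q[-1] = 1.0

    l = np.empty_like(m)
    l[0] = 1.0
    np.cumprod(1.0 - q[:-1], out=l[1:])
    d = l * q

    L = np.empty_like(m)
    L[:-1] = nc * l[1:] + ac * d[:-1]  # survivors n years each, decedents a years
    L[-1] = l[-1] / m[-1]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    return LifeTable(age_lower=lower, width=n, m=m, q=q, a=a, l=l, d=d, L=L, T=T, e=e)


def life_disparity(lt: LifeTable) -> float:
    """Life disparity e†: the d(x)-weighted mean remaining expectancy at death.

    For each closed interval the remaining expectancy is evaluated at the
    mean age at death x + a(x), with l and T linearly interpolated between
    the tabulated interval boundaries; deaths in the open interval carry
    its own expectancy e(omega) (exact under the exponential closure).
    This discretization converges to the continuous integral
    ``int d(x) e(x) dx`` under grid refinement.
    """
    d, l, T, a, n = lt.d, lt.l, lt.T, lt.a, lt.width
    frac = a[:-1] / n[:-1]
    l_mid = l[:-1] + frac * (l[1:] - l[:-1])
    T_mid = T[:-1] + frac * (T[1:] - T[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        e_mid = np.where(l_mid > 0, T_mid / l_mid, 0.0)
    return float(np.sum(d[:-1] * e_mid) + d[-1] * lt.e[-1])


@dataclass(frozen=True)
class CauseDeathMatrix:
    """Life-table deaths d(x, c) split by age group x and cause c."""

    d_xc: np.ndarray  # (n_ages, k)

    @property
    def d_x(self) -> np.ndarray:
        return self.d_xc.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.d_xc.sum())


def partition_deaths_by_cause(
    lt: LifeTable,
    cause_fractions: np.ndarray,
    *,
    renormalize: bool = False,
    tol: float = 1e-9,
) -> CauseDeathMatrix:
    """Split life-table deaths by cause: d(x, c) = d(x) * f(x, c).

    ``cause_fractions`` rows are per-age proportions over causes and must
    sum to 1 within ``tol`` (a row of zeros is accepted where the age group
    has no life-table deaths).  With ``renormalize`` nonzero rows are
    rescaled instead of rejected.
    """
    f = np.asarray(cause_fractions, dtype=float)
    if f.ndim != 2 or f.shape[0] != lt.d.shape[0]:
        raise ValueError("cause_fractions must be (n_ages, k)")
    if np.any(f < 0):
        raise ValueError("cause fractions must be non-negative")
    rs = f.sum(axis=1)
    if renormalize:
        nz = rs > 0
        f = f.copy()
        f[nz] /= rs[nz, None]
        rs = f.sum(axis=1)
    bad = np.abs(rs - 1.0) > tol
    empty_ok = (rs == 0) & (lt.d == 0)
    if np.any(bad & ~empty_ok):
        rows = np.nonzero(bad & ~empty_ok)[0]
        raise ValueError(f"cause fractions rows do not sum to 1 at age indices {rows[:5].tolist()}")
    return CauseDeathMatrix(d_xc=lt.d[:, None] * f)
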