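"""Life-table construction, e0, life disparity and cause partitioning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codiversity import (
    AgeScheme,
    build_life_table,
    life_disparity,
    partition_deaths_by_cause,
)


def test_constant_hazard_exponential_closed_form(fine_ages):
    """Constant hazard mu: e0 = 1/mu and e-dagger = e0 (memorylessness)."""
    mu = 0.05
    lt = build_life_table(np.full(fine_ages.n, mu), fine_ages)
    assert lt.e0 == pytest.approx(1 / mu, rel=0.01)
    assert life_disparity(lt) == pytest.approx(lt.e0, rel=0.02)


def test_degenerate_survival_to_open_interval(ages):
    """No mortality before 95, then constant 0.5: e0 = 95 + 1/0.5."""
    m = np.zeros(ages.n)
    m[-1] = 0.5
    lt = build_life_table(m, ages)
    assert lt.e0 == pytest.approx(97.0, rel=1e-6)
    assert lt.l[-1] == 1.0


def test_immediate_death_limit(ages):
    """m0 -> infinity concentrates all deaths in infancy: e0 -> a0."""
    m = np.full(ages.n, 1e-9)
    m[0] = 1e6
    m[-1] = 0.5
    lt = build_life_table(m, ages)
    assert lt.q[0] == 1.0
    assert lt.e0 == pytest.approx(lt.a[0], rel=1e-6)


def test_invalid_rates_rejected(ages):
    with pytest.raises(ValueError):
        build_life_table(np.full(ages.n, -0.01), ages)
    m = np.full(ages.n, np.nan)
    with pytest.raises(ValueError):
        build_life_table(m, ages)
    m = np.full(ages.n, 0.01)
    m[-1] = 0.0  # open interval needs m > 0 for the l/m closure
    with pytest.raises(ValueError):
        build_life_table(m, ages)


@given(st.integers(0, 2**32 - 1))
def test_table_invariants_on_random_rates(ages, seed):
    """l non-increasing from 1, deaths sum to 1, T non-increasing, e0 = T0."""
    rng = np.random.default_rng(seed)
    m = rng.lognormal(mean=-5, sigma=1.5, size=ages.n)
    lt = build_life_table(m, ages)
    assert lt.l[0] == 1.0
    assert np.all(np.diff(lt.l) <= 1e-15)
    assert lt.d.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all((lt.q >= 0) & (lt.q <= 1)) and lt.q[-1] == 1.0
    assert np.all(np.diff(lt.T) <= 1e-12)
    assert lt.e0 == pytest.approx(lt.T[0] / lt.l[0])
    assert life_disparity(lt) >= 0


@given(st.integers(0, 2**32 - 1), st.integers(0, 20))
def test_raising_one_rate_weakly_lowers_e0(ages, seed, idx):
    rng = np.random.default_rng(seed)
    m = rng.lognormal(mean=-5, sigma=1.0, size=ages.n)
    bumped = m.copy()
    bumped[idx] *= 1.5
    assert build_life_table(bumped, ages).e0 <= build_life_table(m, ages).e0 + 1e-12


def test_life_disparity_matches_quadrature_oracle():
    """e-dagger equals dense numerical integration of d(x) e(x).

    On a fine grid the within-interval evaluation point is immaterial, and
    e-dagger must agree with a brute-force integral over the table's
    piecewise-linear survival and person-year functions.
    """
    scheme = AgeScheme(tuple(np.arange(0, 110.05, 0.05)))
    x = np.asarray(scheme.lower_bounds)
    mu = 0.002 + 1e-5 * np.exp(0.09 * x)  # Gompertz-Makeham
    lt = build_life_table(mu, scheme)

    # oracle: sub-sample each closed interval, integrate f(y) e(y) dy with
    # l and T linearly interpolated between the tabulated boundary values
    sub = np.linspace(0.0, 1.0, 9)[None, :]
    n = lt.width[:-1, None]
    l0, l1 = lt.l[:-1, None], lt.l[1:, None]
    T0, T1 = lt.T[:-1, None], lt.T[1:, None]
    l_y = l0 + sub * (l1 - l0)
    T_y = T0 + sub * (T1 - T0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_y = np.where(l_y > 0, T_y / l_y, 0.0)
    inner = np.trapezoid(e_y, dx=1.0 / 8.0, axis=1)  # mean of e over interval
    oracle = float(np.sum(lt.d[:-1] * inner) + lt.d[-1] * lt.e[-1])
    assert life_disparity(lt) == pytest.approx(oracle, rel=1e-6)


def test_single_interval_deaths_have_subyear_disparity(fine_ages):
    """All deaths inside one 1-year interval: e-dagger below 1 year."""
    m = np.full(fine_ages.n, 1e-10)
    m[50] = 1e6
    m[-1] = 0.5
    lt = build_life_table(m, fine_ages)
    assert lt.d[50] == pytest.approx(1.0, abs=1e-3)
    assert life_disparity(lt) < 1.0


class TestPartition:
    def test_single_cause_column_equals_dx(self, ages):
        m = np.full(ages.n, 0.02)
        lt = build_life_table(m, ages)
        f = np.zeros((ages.n, 4))
        f[:, 2] = 1.0
        cdm = partition_deaths_by_cause(lt, f)
        np.testing.assert_allclose(cdm.d_xc[:, 2], lt.d)
        assert cdm.d_xc[:, [0, 1, 3]].sum() == 0

    def test_uniform_fractions(self, ages):
        lt = build_life_table(np.full(ages.n, 0.02), ages)
        cdm = partition_deaths_by_cause(lt, np.full((ages.n, 21), 1 / 21))
        np.testing.assert_allclose(cdm.d_xc, np.tile(lt.d[:, None] / 21, (1, 21)))

    @given(st.integers(0, 2**32 - 1))
    def test_conservation_for_random_fractions(self, ages, seed):
        rng = np.random.default_rng(seed)
        lt = build_life_table(rng.lognormal(-5, 1, size=ages.n), ages)
        f = rng.dirichlet(np.ones(6), size=ages.n)
        cdm = partition_deaths_by_cause(lt, f)
        assert cdm.total == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(cdm.d_x, lt.d, atol=1e-15)

    def test_bad_row_sum_rejected_unless_renormalized(self, ages):
        lt = build_life_table(np.full(ages.n, 0.02), ages)
        f = np.full((ages.n, 3), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            partition_deaths_by_cause(lt, f)
        cdm = partition_deaths_by_cause(lt, f, renormalize=True)
        assert cdm.total == pytest.approx(1.0, abs=1e-9)
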