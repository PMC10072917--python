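"""Fractionalization index: values, bounds and structural properties."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codiversity import (
    CauseProportions,
    build_life_table,
    cause_proportions_from_lifetable,
    fractionalization,
    fractionalization_observed,
    partition_deaths_by_cause,
    regroup,
    sex_gap,
)


def random_simplex(seed, k=None):
    rng = np.random.default_rng(seed)
    k = k or rng.integers(2, 30)
    return rng.dirichlet(np.full(k, rng.uniform(0.2, 5.0)))


@pytest.mark.parametrize("p, expected", [
    (np.full(21, 1 / 21), 20 / 21),          # uniform maximum
    (np.eye(21)[0], 0.0),                     # single cause
    (np.array([0.5, 0.5]), 0.5),
])
def test_fractionalization_reference_values(p, expected):
    assert fractionalization(p) == pytest.approx(expected, abs=1e-12)


def test_bad_proportions_rejected():
    with pytest.raises(ValueError):
        fractionalization(np.array([0.5, 0.4]))
    with pytest.raises(ValueError):
        fractionalization(np.array([1.2, -0.2]))
    assert fractionalization(np.array([2.0, 2.0]), renormalize=True) == 0.5


@given(st.integers(0, 2**32 - 1))
def test_bounds_and_uniform_maximum(seed):
    """0 <= F <= (k-1)/k, with the maximum only at the uniform vector."""
    p = random_simplex(seed)
    k = len(p)
    F = fractionalization(p)
    assert -1e-12 <= F <= (k - 1) / k + 1e-12
    assert fractionalization(np.full(k, 1 / k)) == pytest.approx((k - 1) / k)


@given(st.integers(0, 2**32 - 1))
def test_zero_padding_invariance(seed):
    p = random_simplex(seed)
    padded = np.concatenate([p, np.zeros(5)])
    assert fractionalization(padded) == pytest.approx(fractionalization(p), abs=1e-12)


@given(st.integers(0, 2**32 - 1))
def test_merge_monotonicity(causes, seed):
    """Any regrouping of causes weakly decreases F."""
    rng = np.random.default_rng(seed)
    p = CauseProportions(rng.dirichlet(np.ones(causes.k)), scheme=causes)
    n_groups = rng.integers(1, causes.k + 1)
    mapping = {c: f"g{rng.integers(n_groups)}" for c in causes.causes}
    merged, _ = regroup(p, mapping)
    assert merged.sum() == pytest.approx(1.0, abs=1e-9)
    assert fractionalization(merged) <= fractionalization(p.p) + 1e-12


@given(st.integers(0, 2**32 - 1))
def test_schur_concavity_spot_check(seed):
    """Moving mass from a smaller share to a larger share decreases F."""
    p = random_simplex(seed)
    if len(np.unique(p)) < len(p):
        return
    i, j = int(np.argmax(p)), int(np.argmin(p))
    eps = p[j] / 2
    q = p.copy()
    q[i] += eps
    q[j] -= eps
    assert fractionalization(q) < fractionalization(p)


def test_level1_regroup_of_uniform(causes):
    """Uniform level-2 shares merge to the 3 level-1 group sizes /21."""
    p = CauseProportions(np.full(causes.k, 1 / causes.k), scheme=causes)
    merged, labels = regroup(p)
    assert len(labels) == 3
    sizes = sorted(merged * causes.k)
    np.testing.assert_allclose(sizes, [3, 7, 11])
    assert fractionalization(merged) < 20 / 21


def test_regroup_requires_total_mapping(causes):
    p = CauseProportions(np.full(causes.k, 1 / causes.k), scheme=causes)
    mapping = dict.fromkeys(causes.causes[:-1], "g")
    with pytest.raises(ValueError, match="missing"):
        regroup(p, mapping)


def test_identity_regroup_and_pair_merge(causes):
    p = CauseProportions(np.full(causes.k, 1 / causes.k), scheme=causes)
    same, labels = regroup(p, {c: c for c in causes.causes})
    np.testing.assert_allclose(same, p.p)
    pair = CauseProportions(np.array([0.5, 0.5]),
                            scheme=type(causes)(("a", "b"), {"a": "x", "b": "x"}))
    merged, _ = regroup(pair)
    assert fractionalization(merged) == 0.0


class TestObservedVariant:
    def test_counts(self):
        assert fractionalization_observed([10, 10]) == pytest.approx(0.5)
        assert fractionalization_observed([0, 42, 0]) == 0.0

    @given(st.integers(0, 2**32 - 1))
    def test_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 1000, size=8)
        if counts.sum() == 0:
            counts[0] = 1
        assert fractionalization_observed(counts) == pytest.approx(
            fractionalization_observed(10 * counts), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fractionalization_observed([0, 0, 0])


class TestLifetableProportions:
    def test_random_matrix_matches_column_sums(self, ages):
        rng = np.random.default_rng(5)
        lt = build_life_table(rng.lognormal(-5, 1, size=ages.n), ages)
        f = rng.dirichlet(np.ones(7), size=ages.n)
        cdm = partition_deaths_by_cause(lt, f)
        p = cause_proportions_from_lifetable(cdm)
        oracle = cdm.d_xc.sum(axis=0) / cdm.d_xc.sum()
        np.testing.assert_allclose(p.p, oracle, atol=1e-12)
        assert p.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_age_uniform_fractions_pass_through(self, ages):
        lt = build_life_table(np.full(ages.n, 0.03), ages)
        f_c = np.array([0.6, 0.3, 0.1])
        cdm = partition_deaths_by_cause(lt, np.tile(f_c, (ages.n, 1)))
        np.testing.assert_allclose(cause_proportions_from_lifetable(cdm).p, f_c,
                                   atol=1e-12)


def test_sex_gap_is_signed_difference():
    assert sex_gap(0.7, 0.7) == 0.0
    assert sex_gap(0.748, 0.712) == pytest.approx(0.036)
    assert sex_gap(0.6, 0.8) == -sex_gap(0.8, 0.6)
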