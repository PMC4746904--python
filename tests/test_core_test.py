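"""Unit and property tests for the score statistic and its combinations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointgt import (
    CovariateSet,
    DegenerateResponseError,
    ResponseVector,
    fit_null,
    joint_statistic,
    moments_q,
    q_statistic,
    standardize_columns,
    standardized_t,
)

from conftest import random_instance


def naive_q(y, x):
    """Element-wise evaluation of the ratio quadratic form (oracle)."""
    r = y - y.mean()
    a = x @ x.T
    num = sum(r[i] * a[i, j] * r[j] for i in range(len(r)) for j in range(len(r)))
    return num / (r @ r)


class TestFitNull:
    def test_intercept_only_mean(self):
        null = fit_null(ResponseVector(np.array([1.0, 2, 3, 4])))
        assert np.allclose(null.fitted, 2.5)
        assert np.allclose(null.residuals, [-1.5, -0.5, 0.5, 1.5])
        assert null.df_resid == 3
        assert null.design_rank == 1

    def test_constant_response_is_degenerate(self):
        with pytest.raises(DegenerateResponseError):
            fit_null(ResponseVector(np.array([5.0, 5, 5, 5])))

    def test_confounder_residuals_match_normal_equations(self):
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        c = np.array([0.5, -1.0, 2.0, 0.0, 1.5])
        d = np.column_stack([np.ones(5), c])
        # independent oracle: solve (D'D) b = D'y directly
        b = np.linalg.solve(d.T @ d, d.T @ y)
        null = fit_null(ResponseVector(y, confounders=c[:, None]))
        assert np.allclose(null.fitted, d @ b)
        assert abs(null.residuals @ c) < 1e-10
        assert abs(null.residuals.sum()) < 1e-10
        assert null.df_resid == 3

    def test_confounders_explaining_y_exactly_are_degenerate(self):
        c = np.array([1.0, 2, 3, 4, 5])
        with pytest.raises(DegenerateResponseError):
            fit_null(ResponseVector(2 * c + 1, confounders=c[:, None]))

    def test_residuals_sum_to_zero_with_intercept(self, rng):
        _, null, _ = random_instance(rng, 30, 3, confounders=2)
        assert abs(null.residuals.sum()) < 1e-8 * 30 * null.residuals.std()


class TestQStatistic:
    def test_zero_covariates_give_zero(self, toy_null):
        assert q_statistic(toy_null, CovariateSet("x", np.zeros((4, 3)))) == 0.0

    def test_matches_elementwise_quadratic_form_oracle(self, toy_null, toy_sets):
        xset, _ = toy_sets
        y = np.array([1.0, 2, 3, 4])
        assert q_statistic(toy_null, xset) == pytest.approx(
            naive_q(y, xset.values), rel=1e-12
        )

    def test_location_invariance(self, rng, toy_sets):
        xset, _ = toy_sets
        y = np.array([1.0, 2, 3, 4])
        q0 = q_statistic(fit_null(ResponseVector(y)), xset)
        q1 = q_statistic(fit_null(ResponseVector(y + 17.3)), xset)
        assert q1 == pytest.approx(q0, rel=1e-12)

    def test_quadratic_scale_behaviour(self, toy_null, toy_sets):
        xset, _ = toy_sets
        q = q_statistic(toy_null, xset)
        q9 = q_statistic(toy_null, CovariateSet("x", 3.0 * xset.values))
        assert q9 == pytest.approx(9 * q, rel=1e-12)

    def test_dimension_mismatch_errors(self, toy_null):
        with pytest.raises(ValueError, match="rows"):
            q_statistic(toy_null, CovariateSet("x", np.ones((5, 2))))


class TestMomentsQ:
    def test_unit_vector_rank_one_expectation(self):
        null = fit_null(ResponseVector(np.array([1.0, 2, 3, 4])))
        # unit column orthogonal to the intercept: A has eigenvalues (1, 0, 0)
        x = np.array([[1.0], [-1.0], [0.0], [0.0]]) / np.sqrt(2)
        e, v = moments_q(null, CovariateSet("x", x))
        assert e == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert v > 0

    def test_matches_spherical_monte_carlo(self, rng):
        _, null, xset = random_instance(rng, 10, 5)
        e, v = moments_q(null, xset)
        # oracle: fresh gaussian responses through an independent residual path
        draws = rng.standard_normal((50_000, 10))
        r = draws - draws.mean(axis=1, keepdims=True)
        q = ((r @ xset.values) ** 2).sum(axis=1) / (r * r).sum(axis=1)
        se_mean = q.std(ddof=1) / np.sqrt(q.size)
        qc = (q - q.mean()) ** 2
        se_var = np.sqrt((np.mean(qc**2) - np.var(q) ** 2) / q.size)
        assert abs(q.mean() - e) < 3 * se_mean
        assert abs(q.var(ddof=1) - v) < 3 * se_var

    def test_permutation_enumeration_mean_close_to_spherical(self, toy_null, toy_sets):
        xset, _ = toy_sets
        y = np.array([1.0, 2, 3, 4])
        qs = [naive_q(y[list(p)], xset.values) for p in itertools.permutations(range(4))]
        enum_mean = np.mean(qs)
        # independent re-enumeration through the tested path must agree exactly
        qs2 = [
            q_statistic(fit_null(ResponseVector(y[list(p)])), xset)
            for p in itertools.permutations(range(4))
        ]
        assert enum_mean == pytest.approx(np.mean(qs2), rel=1e-12)
        e, _ = moments_q(toy_null, xset)
        # permutation and spherical nulls differ; document the discrepancy bound
        assert abs(enum_mean - e) / e < 0.25


class TestStandardizedT:
    def test_zero_at_the_mean(self):
        assert standardized_t(1.0, 1.0, 4.0) == 0.0

    def test_arithmetic_identity(self):
        assert standardized_t(2.0, 1.0, 4.0) == pytest.approx(0.5)

    def test_invariant_under_covariate_rescaling(self, toy_null, toy_sets):
        xset, _ = toy_sets
        scaled = CovariateSet("x", 3.0 * xset.values)
        t0 = standardized_t(q_statistic(toy_null, xset), *moments_q(toy_null, xset))
        t1 = standardized_t(q_statistic(toy_null, scaled), *moments_q(toy_null, scaled))
        assert t1 == pytest.approx(t0, rel=1e-10)

    def test_nonpositive_variance_errors(self):
        with pytest.raises(ValueError):
            standardized_t(1.0, 0.5, 0.0)


class TestJointStatistic:
    def test_single_set_sum_reduces_to_q(self, toy_null, toy_sets):
        xset, _ = toy_sets
        res = joint_statistic(toy_null, [xset], mode="sum")
        assert res.combined == pytest.approx(q_statistic(toy_null, xset), rel=1e-12)

    @pytest.mark.parametrize("n_sets", [2, 3])
    def test_merged_set_identity(self, rng, n_sets):
        """Sum of per-set statistics equals the statistic on merged columns."""
        for _ in range(20):
            n = int(rng.integers(5, 51))
            _, null, _ = random_instance(rng, n, 1)
            sets = [
                CovariateSet(f"s{m}", rng.normal(size=(n, int(rng.integers(1, 8)))))
                for m in range(n_sets)
            ]
            res = joint_statistic(null, sets, mode="sum")
            merged = q_statistic(
                null, CovariateSet("m", np.hstack([s.values for s in sets]))
            )
            assert abs(res.combined - merged) <= 1e-10 * max(1.0, abs(merged))

    def test_centered_squared_matches_componentwise_oracle(self, rng):
        y = ResponseVector(np.array([0.3, -1.2, 0.7, 2.0, -0.5, 1.1]))
        null = fit_null(y)
        sets = [CovariateSet(f"s{m}", rng.normal(size=(6, m + 1))) for m in range(3)]
        res = joint_statistic(null, sets, mode="centered_squared")
        expected = 0.0
        for s in sets:
            q = q_statistic(null, s)
            e, _ = moments_q(null, s)
            expected += (q - e) ** 2
        assert res.combined == pytest.approx(expected, rel=1e-12)

    def test_weights_scale_the_sum(self, toy_null, toy_sets):
        xset, zset = toy_sets
        res = joint_statistic(toy_null, [xset, zset], mode="sum", weights=[2.0, 0.5])
        expected = 2.0 * q_statistic(toy_null, xset) + 0.5 * q_statistic(toy_null, zset)
        assert res.combined == pytest.approx(expected, rel=1e-12)

    def test_empty_set_flagged_and_excluded(self, toy_null, toy_sets):
        xset, _ = toy_sets
        empty = CovariateSet("me", np.empty((4, 0)))
        res = joint_statistic(toy_null, [xset, empty], mode="sum")
        assert "empty_set:me" in res.flags
        assert res.set_sizes["me"] == 0
        assert res.combined == pytest.approx(q_statistic(toy_null, xset), rel=1e-12)

    def test_zero_columns_contribute_zero_and_flag(self, toy_null, toy_sets):
        xset, _ = toy_sets
        zeros = CovariateSet("z0", np.zeros((4, 2)))
        res = joint_statistic(toy_null, [xset, zeros], mode="sum")
        assert res.combined == pytest.approx(q_statistic(toy_null, xset), rel=1e-12)
        assert "zero_variance:z0" in res.flags

    def test_empty_set_list_errors(self, toy_null):
        with pytest.raises(ValueError):
            joint_statistic(toy_null, [])

    def test_standardized_columns_option(self, toy_null, toy_sets):
        xset, _ = toy_sets
        res = joint_statistic(toy_null, [xset], mode="sum", standardize=True)
        manual = q_statistic(
            toy_null, CovariateSet("x", standardize_columns(xset.values))
        )
        assert res.combined == pytest.approx(manual, rel=1e-12)


@settings(derandomize=True, deadline=None, max_examples=25)
@given(shift=st.floats(-1e3, 1e3, allow_nan=False), seed=st.integers(0, 2**20))
def test_location_invariance_property(shift, seed):
    """All statistics are unchanged by y -> y + c when the null has an intercept."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=12)
    x = rng.normal(size=(12, 4))
    xset = CovariateSet("x", x)
    r0 = joint_statistic(fit_null(ResponseVector(y)), [xset])
    r1 = joint_statistic(fit_null(ResponseVector(y + shift)), [xset])
    assert r1.combined == pytest.approx(r0.combined, rel=1e-8, abs=1e-10)
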