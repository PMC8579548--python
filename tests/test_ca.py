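import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toxca import (
    arm_origin_distances,
    ca_fit,
    double,
    explained_inertia,
    from_percent_table,
    plane_contribution,
    table3_fixture,
)
from conftest import random_doubled


def brute_force_inertia(X: np.ndarray) -> float:
    """Chi-square double sum Σ_ij (p_ij - r_i c_j)^2 / (r_i c_j), by loops."""
    P = X / X.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    total = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            e = r[i] * c[j]
            total += (P[i, j] - e) ** 2 / e
    return total


class TestCAFit:
    def test_total_inertia_matches_brute_force_oracle(self):
        rng_master = np.random.default_rng(0)
        for seed in range(1, 101):
            rng = np.random.default_rng(seed)
            X = random_doubled(rng)
            res = ca_fit(X)
            assert res.total_inertia == pytest.approx(
                brute_force_inertia(X), abs=1e-9)

    def test_reconstruction_identity(self):
        for seed in (1, 2, 3, 4, 5):
            X = random_doubled(np.random.default_rng(seed), I=5, J=4)
            res = ca_fit(X)
            P = X / X.sum()
            r, c = res.row_masses, res.col_masses
            recon = np.outer(r, c) + (
                np.sqrt(r)[:, None] * res.U
            ) @ np.diag(res.singular_values) @ (np.sqrt(c)[:, None] * res.V).T
            np.testing.assert_allclose(recon, P, atol=1e-9)

    def test_singular_vectors_orthonormal(self):
        res = ca_fit(random_doubled(np.random.default_rng(3)))
        K = res.K
        np.testing.assert_allclose(res.U.T @ res.U, np.eye(K), atol=1e-10)
        np.testing.assert_allclose(res.V.T @ res.V, np.eye(K), atol=1e-10)

    def test_contributions_sum_to_one_per_axis(self):
        res = ca_fit(random_doubled(np.random.default_rng(4)))
        np.testing.assert_allclose(res.row_contrib.sum(axis=0), 1.0, atol=1e-9)

    def test_explained_pct_sums_to_100(self):
        res = ca_fit(double(table3_fixture()))
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_singular_values_descending_positive(self):
        res = ca_fit(random_doubled(np.random.default_rng(5)))
        sv = res.singular_values
        assert np.all(np.diff(sv) <= 0) and sv[-1] > 0

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        X = random_doubled(np.random.default_rng(11))
        a, b = ca_fit(X), ca_fit(scale * X)
        np.testing.assert_allclose(a.singular_values, b.singular_values, atol=1e-10)
        np.testing.assert_allclose(a.row_principal, b.row_principal, atol=1e-9)

    def test_doubled_column_masses_equal(self):
        res = ca_fit(double(table3_fixture()))
        np.testing.assert_allclose(res.col_masses, 0.25, atol=1e-12)

    def test_identical_columns_degenerate(self):
        X = np.tile(np.array([[0.3], [0.7], [0.6], [0.4]]), (1, 3))
        res = ca_fit(X)
        assert res.K == 0 and res.total_inertia == 0.0

    def test_rank_bound_and_r04_rank(self):
        res = ca_fit(double(table3_fixture()))
        assert res.K == 3 <= min(10, 4) - 1

    def test_barycentric_relation(self):
        """Column principal coords are mass-weighted averages of row standard coords."""
        X = random_doubled(np.random.default_rng(9), I=6, J=4)
        res = ca_fit(X)
        P = X / X.sum()
        profiles = P / P.sum(axis=0)          # column profiles
        np.testing.assert_allclose(res.col_principal,
                                   profiles.T @ res.row_standard, atol=1e-9)
        np.testing.assert_allclose(res.col_principal,
                                   res.col_standard * res.singular_values,
                                   atol=1e-12)

    def test_sign_convention_deterministic(self):
        X = random_doubled(np.random.default_rng(13))
        a, b = ca_fit(X), ca_fit(X)
        np.testing.assert_array_equal(a.U, b.U)
        for k in range(a.K):
            assert a.U[np.argmax(np.abs(a.U[:, k])), k] > 0


class TestExplainedInertia:
    def test_r04_two_dimensional(self):
        res = ca_fit(double(table3_fixture()))
        assert explained_inertia(res, 2) == pytest.approx(98.23, abs=0.2)

    def test_full_rank_is_100(self):
        res = ca_fit(double(table3_fixture()))
        assert explained_inertia(res, res.K) == pytest.approx(100.0)
        assert explained_inertia(res, res.K + 5) == pytest.approx(100.0)

    def test_zero_dims(self):
        res = ca_fit(double(table3_fixture()))
        assert explained_inertia(res, 0) == 0.0


class TestPlaneContribution:
    def test_sums_to_100(self):
        res = ca_fit(random_doubled(np.random.default_rng(21), I=5, J=4))
        assert plane_contribution(res, (1, 2)).sum() == pytest.approx(100.0)

    def test_single_dimension_reduces_to_axis_contribution(self):
        res = ca_fit(random_doubled(np.random.default_rng(22)))
        np.testing.assert_allclose(plane_contribution(res, (1, 1)),
                                   100 * res.row_contrib[:, 0], atol=1e-9)

    def test_perturbed_class_dominates(self):
        """Perturbing one class of an otherwise uniform table concentrates
        nearly all plane inertia on that class pair."""
        pi = np.full((6, 3), 0.4)
        pi[2] = [0.15, 0.4, 0.65]
        pi[3] = [0.4005, 0.399, 0.4005]   # tiny orthogonal contrast for dim 2
        tab = double(from_percent_table(
            [f"C{i}" for i in range(6)], ["A", "B", "C"], pi * 100))
        res = ca_fit(tab)
        contrib = plane_contribution(res, (1, 2))
        pair = contrib[4] + contrib[5]     # class C2 row + complement
        assert pair > 99.0

    def test_out_of_range_dimension(self):
        res = ca_fit(double(table3_fixture()))
        with pytest.raises(ValueError, match="out of range"):
            plane_contribution(res, (1, 9))


class TestArmOriginDistances:
    def test_identical_columns_all_zero(self):
        X = np.tile(np.array([[0.3], [0.7]]), (1, 3))
        np.testing.assert_array_equal(arm_origin_distances(ca_fit(X)), 0.0)

    def test_weighted_square_sum_is_total_inertia(self):
        res = ca_fit(random_doubled(np.random.default_rng(30), I=5, J=4))
        d = arm_origin_distances(res)
        assert (res.col_masses * d**2).sum() == pytest.approx(
            res.total_inertia, abs=1e-12)

    def test_deviant_arm_is_farthest(self):
        pi = np.array([[0.3, 0.3, 0.8],
                       [0.5, 0.5, 0.1],
                       [0.2, 0.2, 0.6]])
        tab = double(from_percent_table(["X", "Y", "Z"],
                                        ["A", "B", "C"], pi * 100))
        d = arm_origin_distances(ca_fit(tab))
        assert d[2] > d[0] and d[2] > d[1]
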