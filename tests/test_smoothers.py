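"""Spline bases, RW2/MRF penalties and sum-to-zero constraint absorption."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adstar.smoothers import (
    apply_constraint,
    bspline_basis,
    mrf_penalty,
    nullspace_dimension,
    rw2_penalty,
)


def cox_de_boor(x, i, k, t):
    """Textbook Cox-de Boor recursion, written independently of scipy."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    out = 0.0
    if t[i + k] > t[i]:
        out += (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, i, k - 1, t)
    if t[i + k + 1] > t[i + 1]:
        out += (
            (t[i + k + 1] - x)
            / (t[i + k + 1] - t[i + 1])
            * cox_de_boor(x, i + 1, k - 1, t)
        )
    return out


class TestBsplineBasis:
    def test_partition_of_unity(self):
        x = np.linspace(0.0, 10.0, 57)
        _, B = bspline_basis(x, n_interior_knots=6, degree=3)
        assert np.allclose(np.asarray(B.sum(axis=1)).ravel(), 1.0, atol=1e-10)

    def test_degree_zero_bins(self):
        # knots at integers over [0, 5]: value 2.5 hits its bin indicator
        x = np.array([0.0, 2.5, 5.0])
        basis, B = bspline_basis(x, n_interior_knots=4, degree=0)
        row = B[1].toarray().ravel()
        assert row.sum() == 1.0
        assert row[2] == 1.0  # bin [2, 3)

    def test_matches_de_boor_recursion(self):
        x = np.array([1.3, 4.75, 7.5, 9.99])
        basis, B = bspline_basis(np.linspace(0, 10, 21), 5, degree=3)
        t = basis.knots
        for xv in x:
            expected = [cox_de_boor(xv, i, 3, t) for i in range(basis.n_basis)]
            got = basis.design(np.array([xv])).toarray().ravel()
            assert np.allclose(got, expected, atol=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bspline_basis(np.full(10, 3.0), 5)

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError, match="n_interior_knots"):
            bspline_basis(np.linspace(0, 1, 10), 2, degree=3)

    def test_out_of_range_evaluation_rejected(self):
        basis, _ = bspline_basis(np.linspace(0, 1, 10), 5)
        with pytest.raises(ValueError, match="outside"):
            basis.design(np.array([1.5]))


class TestRw2Penalty:
    def test_linear_sequence_annihilated(self):
        K = rw2_penalty(8)
        lin = 0.3 + 1.7 * np.arange(8)
        assert K.quad_form(lin) == pytest.approx(0.0, abs=1e-12)

    def test_hand_expanded_three_coef(self):
        K = rw2_penalty(3)
        assert K.quad_form(np.array([0.0, 1.0, 0.0])) == pytest.approx(4.0)

    def test_exactly_two_zero_eigenvalues(self):
        K = rw2_penalty(12)
        assert nullspace_dimension(K.matrix) == 2
        assert np.all(np.linalg.eigvalsh(K.matrix) > -1e-9)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            rw2_penalty(2)


class TestMrfPenalty:
    def test_laplacian_structure_and_row_sums(self):
        K, order = mrf_penalty([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        M = K.matrix
        assert order == ["a", "b", "c", "d"]
        assert np.allclose(M.sum(axis=1), 0.0)
        assert M[order.index("c"), order.index("c")] == 3  # degree
        assert M[order.index("a"), order.index("b")] == -1

    def test_constant_vector_in_null_space(self):
        K, _ = mrf_penalty([("a", "b"), ("b", "c")])
        assert K.quad_form(np.ones(3)) == pytest.approx(0.0)
        assert K.nullspace_dim == 1

    def test_path_graph_quad_form(self):
        K, order = mrf_penalty([("a", "b"), ("b", "c")])
        v = np.array([1.0, 0.0, 0.0])  # order is a, b, c
        assert K.quad_form(v) == pytest.approx(1.0)

    def test_disconnected_graph_null_dimension(self):
        K, _ = mrf_penalty([("a", "b"), ("c", "d")])
        assert K.nullspace_dim == 2

    def test_car_conditional_law(self):
        """Row s of K equals the conditional precision of the CAR prior:
        effect_s | rest ~ N(mean of neighbours, tau2 / n_s)."""
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]
        K, order = mrf_penalty(edges)
        M = K.matrix
        neighbours = {n: set() for n in order}
        for x, y in edges:
            neighbours[x].add(y)
            neighbours[y].add(x)
        for s, name in enumerate(order):
            n_s = len(neighbours[name])
            # conditional precision of s is n_s / tau2 -> diagonal entry n_s
            assert M[s, s] == n_s
            # conditional mean coefficient on a neighbour t is 1/n_s:
            # -M[s,t] / M[s,s] must equal 1/n_s for neighbours, 0 otherwise
            for t, other in enumerate(order):
                if t == s:
                    continue
                coef = -M[s, t] / M[s, s]
                expected = 1.0 / n_s if other in neighbours[name] else 0.0
                assert coef == pytest.approx(expected)

    def test_self_loop_and_duplicate_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            mrf_penalty([("a", "a")])
        with pytest.raises(ValueError, match="duplicate"):
            mrf_penalty([("a", "b"), ("b", "a")])


class TestApplyConstraint:
    def _toy(self, weighted: bool, seed=0):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 1, 80))
        _, B = bspline_basis(x, 6, degree=3)
        K = rw2_penalty(B.shape[1])
        w = rng.uniform(0.5, 2.0, 80) if weighted else None
        return x, B, K, w

    @pytest.mark.parametrize("weighted", [False, True])
    def test_fitted_contribution_sums_to_zero(self, weighted):
        x, B, K, w = self._toy(weighted)
        sm = apply_constraint("s", B, K, weights=w)
        rng = np.random.default_rng(1)
        beta = rng.normal(size=sm.n_coef)
        contrib = np.asarray(sm.design @ beta).ravel()
        ww = np.ones_like(x) if w is None else w
        assert abs(np.sum(ww * contrib)) < 1e-8 * np.abs(contrib).max()

    def test_constraining_twice_is_idempotent_in_fitted_space(self):
        x, B, K, _ = self._toy(False)
        sm1 = apply_constraint("s", B, K)
        sm2 = apply_constraint("s", sm1.design, sm1.penalty)
        # the two constrained design column spaces coincide
        D1 = sm1.design.toarray()
        D2 = sm2.design.toarray()
        proj = D1 @ np.linalg.lstsq(D1, D2, rcond=None)[0]
        assert np.allclose(proj, D2, atol=1e-8)

    def test_rw2_null_dimension_drops_to_one(self):
        x, B, K, _ = self._toy(False)
        sm = apply_constraint("s", B, K)
        assert sm.penalty.nullspace_dim == 1

    def test_constrained_plus_intercept_matches_unconstrained(self):
        """Dense LS oracle: intercept + constrained smooth spans the same
        fitted values as intercept + raw smooth (both unpenalized)."""
        x, B, K, _ = self._toy(False, seed=3)
        rng = np.random.default_rng(4)
        y = np.sin(2 * np.pi * x) + rng.normal(scale=0.1, size=len(x))
        Braw = B.toarray()
        X1 = np.column_stack([np.ones(len(x)), Braw])
        f1 = X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
        sm = apply_constraint("s", B, K)
        X2 = np.column_stack([np.ones(len(x)), sm.design.toarray()])
        f2 = X2 @ np.linalg.lstsq(X2, y, rcond=None)[0]
        assert np.allclose(f1, f2, atol=1e-8)

    def test_infinite_penalty_limit_is_linear_projection(self):
        """lambda -> inf drives the constrained RW2 smooth to the centered
        linear projection of the data."""
        x, B, K, _ = self._toy(False, seed=5)
        rng = np.random.default_rng(6)
        y = 1.0 + 2.0 * x + np.sin(6 * x) + rng.normal(scale=0.05, size=len(x))
        sm = apply_constraint("s", B, K)
        D = sm.design.toarray()
        lam = 1e10
        A = D.T @ D + lam * sm.penalty.matrix
        beta = np.linalg.solve(A, D.T @ (y - y.mean()))
        fitted = D @ beta
        # oracle: least-squares centered linear fit
        xc = x - x.mean()
        slope = xc @ (y - y.mean()) / (xc @ xc)
        assert np.allclose(fitted, slope * xc, atol=1e-3)


@given(n=st.integers(min_value=3, max_value=15))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_rw2_penalty_symmetric_psd_with_stated_nullspace(n):
    K = rw2_penalty(n)
    M = K.matrix
    assert np.allclose(M, M.T)
    ev = np.linalg.eigvalsh(M)
    assert ev.min() > -1e-9
    assert nullspace_dimension(M) == 2
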