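import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rssnmf import (
    fit,
    graph_laplacian,
    heat_kernel_weights,
    init_factors,
    objective,
    soft_threshold,
    update_H,
    update_S,
    update_W,
)


def lee_seung_reference(X, W, H):
    """Independent elementwise implementation of the classical update pair."""
    m, k = W.shape
    n = X.shape[1]
    W2 = np.empty_like(W)
    for i in range(m):
        for j in range(k):
            num = sum(X[i, c] * H[j, c] for c in range(n))
            den = sum((W @ H)[i, c] * H[j, c] for c in range(n))
            W2[i, j] = W[i, j] * num / den
    H2 = np.empty_like(H)
    for j in range(k):
        for c in range(n):
            num = sum(W2[i, j] * X[i, c] for i in range(m))
            den = sum(W2[i, j] * (W2 @ H)[i, c] for i in range(m))
            H2[j, c] = H[j, c] * num / den
    return W2, H2


class TestInitFactors:
    def test_deterministic(self):
        a = init_factors(4, 3, 2, seed=0)
        b = init_factors(4, 3, 2, seed=0)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_nonnegative(self):
        W, H = init_factors(50, 40, 5, seed=1)
        assert W.min() >= 0 and H.min() >= 0
        assert W.shape == (50, 5) and H.shape == (5, 40)

    @pytest.mark.parametrize("k", [0, 4])
    def test_invalid_rank(self, k):
        with pytest.raises(ValueError):
            init_factors(5, 3, k, seed=0)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,expected",
        [(2.0, 1.0), (-2.0, -1.0), (0.5, 0.0), (-0.5, 0.0), (1.0, 0.0)],
    )
    def test_piecewise_branches(self, z, expected):
        assert soft_threshold(z, 1.0) == expected

    def test_elementwise_on_matrix(self):
        Z = np.array([[3.0, 0.5], [-2.0, 1.0]])
        np.testing.assert_array_equal(soft_threshold(Z, 1.0),
                                      [[2.0, 0.0], [-1.0, 0.0]])

    def test_invalid_upsilon(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, 0.0)


class TestUpdateW:
    def test_fixed_point_at_exact_factorization(self, rng):
        W = rng.random((5, 2)) + 0.5
        H = rng.random((2, 4)) + 0.5
        X = W @ H
        W2 = update_W(X, W, H, np.zeros_like(X))
        np.testing.assert_allclose(W2, W, rtol=1e-8)

    def test_scalar_arithmetic(self):
        W2 = update_W(np.array([[4.0]]), np.array([[1.0]]),
                      np.array([[2.0]]), np.array([[0.0]]))
        assert W2[0, 0] == pytest.approx(2.0, rel=1e-9)

    def test_single_update_never_increases_reconstruction(self, rng):
        """Lee-Seung monotonicity of the W step on random instances."""
        for _ in range(10):
            X = rng.random((5, 4)) * 5
            W = rng.random((5, 2)) + 0.1
            H = rng.random((2, 4)) + 0.1
            before = np.sum((X - W @ H) ** 2)
            after = np.sum((X - update_W(X, W, H, np.zeros_like(X)) @ H) ** 2)
            assert after <= before + 1e-8 * before


class TestUpdateH:
    def test_fixed_point_at_exact_factorization(self, rng):
        W = rng.random((5, 2)) + 0.5
        H = rng.random((2, 4)) + 0.5
        X = W @ H
        H2 = update_H(X, W, H, np.zeros_like(X), None, 0.0)
        np.testing.assert_allclose(H2, H, rtol=1e-8)

    def test_scalar_arithmetic(self):
        H2 = update_H(np.array([[4.0]]), np.array([[2.0]]),
                      np.array([[1.0]]), np.array([[0.0]]))
        assert H2[0, 0] == pytest.approx(2.0, rel=1e-9)

    def test_matches_classical_reference_implementation(self, rng):
        """With S=0 and beta=0 the rules reduce to the classical pair."""
        X = rng.random((6, 5)) * 3 + 0.1
        W = rng.random((6, 2)) + 0.1
        H = rng.random((2, 5)) + 0.1
        Wr, Hr = lee_seung_reference(X, W, H)
        W2 = update_W(X, W, H, np.zeros_like(X))
        H2 = update_H(X, W2, H, np.zeros_like(X))
        np.testing.assert_allclose(W2, Wr, rtol=1e-9)
        np.testing.assert_allclose(H2, Hr, rtol=1e-9)

    def test_beta_without_graph_rejected(self, rng):
        with pytest.raises(ValueError):
            update_H(np.ones((2, 2)), np.ones((2, 1)), np.ones((1, 2)),
                     np.zeros((2, 2)), None, beta=1.0)


class TestUpdateS:
    def test_theorem_elementwise(self):
        R = np.array([[3.0, 0.5], [-2.0, 1.0]])
        X = R  # W H = 0
        S = update_S(X, np.zeros((2, 1)), np.zeros((1, 2)), alpha=2.0)
        np.testing.assert_array_equal(S, [[2.0, 0.0], [-1.0, 0.0]])

    def test_large_alpha_zeroes_S(self, rng):
        X = rng.random((4, 3)) * 5
        W = rng.random((4, 2))
        H = rng.random((2, 3))
        alpha = 2 * np.abs(X - W @ H).max() + 1.0
        assert np.all(update_S(X, W, H, alpha) == 0)

    def test_minimizes_scalar_subproblem_by_grid(self, rng):
        """S' entry minimizes (r-s)^2 + alpha|s| against a dense grid."""
        for _ in range(20):
            r = float(rng.normal(scale=3))
            alpha = float(rng.random() * 3 + 0.1)
            s_hat = soft_threshold(np.array([r]), alpha / 2)[0]
            grid = np.linspace(-10, 10, 200001)
            best = grid[np.argmin((r - grid) ** 2 + alpha * np.abs(grid))]
            assert s_hat == pytest.approx(best, abs=1e-4)

    def test_alpha_zero_returns_residual_with_warning(self, rng):
        X = rng.random((3, 3))
        W = rng.random((3, 2))
        H = rng.random((2, 3))
        with pytest.warns(UserWarning, match="alpha=0"):
            S = update_S(X, W, H, 0.0)
        np.testing.assert_array_equal(S, X - W @ H)


class TestObjective:
    def test_zero_at_exact_fit(self, rng):
        W = rng.random((4, 2))
        H = np.tile(rng.random((2, 1)), (1, 3))
        X = W @ H
        g = graph_laplacian(heat_kernel_weights(rng.random((2, 3)), 1))
        assert objective(X, W, H, np.zeros_like(X), g, 2.0, 2.0) == pytest.approx(0, abs=1e-10)

    def test_scalar_arithmetic(self):
        val = objective(np.array([[2.0]]), np.array([[1.0]]), np.array([[1.0]]),
                        np.array([[0.5]]), None, alpha=2.0, beta=0.0)
        assert val == pytest.approx(1.25)

    def test_trace_expansion_identity(self, rng):
        """Compact form equals the expanded trace form on random instances."""
        for _ in range(10):
            m, n, k = 5, 4, 2
            X = rng.random((m, n)) * 2
            W = rng.random((m, k))
            H = rng.random((k, n))
            S = rng.normal(size=(m, n))
            Q = heat_kernel_weights(rng.random((2, n)), 1)
            g = graph_laplacian(Q)
            alpha, beta = 1.5, 0.7
            compact = objective(X, W, H, S, g, alpha, beta)
            R = X - W @ H - S
            expanded = (
                np.trace(X @ X.T)
                - 2 * np.trace(X @ H.T @ W.T)
                - 2 * np.trace(X @ S.T)
                + 2 * np.trace(W @ H @ S.T)
                + np.trace(W @ H @ H.T @ W.T)
                + np.trace(S @ S.T)
                + beta * np.trace(H @ g.L @ H.T)
                + alpha * np.abs(S).sum()
            )
            assert compact == pytest.approx(expanded, abs=1e-8)


class TestFit:
    def test_nmf_recovers_low_rank_structure(self, clean_dataset):
        res = fit(clean_dataset.expression, k=5, variant="nmf", seed=0)
        X = clean_dataset.expression.values
        rel = np.linalg.norm(X - res.W @ res.H) / np.linalg.norm(X)
        assert rel < 0.05

    def test_trace_nonincreasing_all_variants(self, rng):
        X = rng.random((20, 15)) * 4
        Q = heat_kernel_weights(X[:3], sigma=50.0)
        g = graph_laplacian(Q)
        for variant, a, b, gg in [("nmf", 0, 0, None), ("rnmf", 2, 0, None),
                                  ("ssnmf", 0, 2, g), ("rssnmf", 2, 2, g)]:
            res = fit(X, 3, variant, gg, alpha=a, beta=b, max_iter=80, seed=3)
            tr = np.asarray(res.objective_trace)
            assert np.all(np.diff(tr) <= 1e-8 * np.abs(tr[:-1]) + 1e-12), variant

    def test_factors_stay_nonnegative(self, rng):
        X = rng.random((10, 8)) * 3
        res = fit(X, 2, "rnmf", alpha=2.0, max_iter=50, seed=1)
        assert res.W.min() >= 0 and res.H.min() >= 0

    def test_dead_zone_invariant(self, rng):
        """S is exactly 0 wherever |X - WH| <= alpha/2."""
        X = rng.random((10, 8)) * 3
        res = fit(X, 2, "rnmf", alpha=2.0, max_iter=50, seed=1)
        R = X - res.W @ res.H
        assert np.all(res.S[np.abs(R) <= 1.0] == 0)

    def test_rssnmf_beta_zero_traces_rnmf_bitwise(self, rng):
        X = rng.random((12, 10)) * 5
        a = fit(X, 3, "rssnmf", g=None, alpha=2.0, beta=0.0, max_iter=40, seed=5)
        b = fit(X, 3, "rnmf", alpha=2.0, max_iter=40, seed=5)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)
        np.testing.assert_array_equal(a.S, b.S)

    def test_ssnmf_traces_rssnmf_with_S_pinned(self, rng):
        """rssNMF whose alpha is too large for any S activity matches ssNMF."""
        X = rng.random((12, 10)) * 5
        Q = heat_kernel_weights(X[:2], sigma=100.0)
        g = graph_laplacian(Q)
        alpha_big = 1e9
        a = fit(X, 3, "rssnmf", g=g, alpha=alpha_big, beta=2.0, max_iter=40, seed=5)
        b = fit(X, 3, "ssnmf", g=g, alpha=0.0, beta=2.0, max_iter=40, seed=5)
        assert np.all(a.S == 0)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_scale_property_of_S_step(self, rng):
        """Scaling X and alpha by c scales the S step output by c."""
        X = rng.random((6, 5)) * 3
        W = rng.random((6, 2))
        H = rng.random((2, 5))
        c = 3.7
        S1 = update_S(X, W, H, alpha=1.4)
        S2 = update_S(c * X, c * W, H, alpha=c * 1.4)
        np.testing.assert_allclose(S2, c * S1, rtol=1e-10)

    @pytest.mark.parametrize(
        "variant,alpha,beta",
        [("nmf", 2.0, 0.0), ("rnmf", 0.0, 0.0), ("rnmf", 2.0, 1.0),
         ("ssnmf", 2.0, 2.0), ("ssnmf", 0.0, 0.0), ("rssnmf", 0.0, 2.0),
         ("bogus", 0.0, 0.0)],
    )
    def test_variant_argument_validation(self, rng, variant, alpha, beta):
        X = rng.random((6, 5))
        with pytest.raises(ValueError):
            fit(X, 2, variant, g=None, alpha=alpha, beta=beta, max_iter=5, seed=0)

    def test_result_records_params_and_ids(self, clean_dataset):
        res = fit(clean_dataset.expression, 5, "nmf", max_iter=10, seed=0)
        assert res.params["variant"] == "nmf"
        assert res.gene_ids == clean_dataset.expression.gene_ids
        assert 0.0 <= res.s_sparsity <= 1.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_single_iteration_monotone_property(seed):
    """One full W,H,S sweep never increases the rNMF objective."""
    rng = np.random.default_rng(seed)
    X = rng.random((8, 6)) * 5
    W = rng.random((8, 2)) + 0.05
    H = rng.random((2, 6)) + 0.05
    S = update_S(X, W, H, 2.0)
    before = objective(X, W, H, S, None, 2.0, 0.0)
    W = update_W(X, W, H, S)
    H = update_H(X, W, H, S)
    S = update_S(X, W, H, 2.0)
    after = objective(X, W, H, S, None, 2.0, 0.0)
    assert after <= before + 1e-8 * before
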