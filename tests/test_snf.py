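"""Similarity network fusion: affinity kernels, kNN kernels, cross-diffusion
and the naive loop oracle."""

import numpy as np
import pytest

from momhca import (
    SNFConfig,
    affinity,
    build_adjacency,
    full_kernel,
    knn_kernel,
    pairwise_distance,
    snf_fuse,
    snf_pipeline,
)
from momhca.snf import _renormalize


def naive_snf(X1, X2, K, mu, t, renormalize=True):
    """Straight-line loop implementation of the kernel and diffusion
    equations (independent oracle, N small)."""
    n = X1.shape[0]
    mats = []
    for X in (X1, X2):
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                dist[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
        mk = np.zeros(n)
        for i in range(n):
            others = sorted(dist[i, j] for j in range(n) if j != i)
            mk[i] = np.mean(others[:K])
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                eps = (mk[i] + mk[j] + dist[i, j]) / 3.0
                W[i, j] = np.exp(-dist[i, j] ** 2 / (mu * eps))
        W = 0.5 * (W + W.T)
        for i in range(n):
            W[i, i] = 1.0
        P = np.zeros((n, n))
        for i in range(n):
            denom = sum(W[i, k] for k in range(n) if k != i)
            for j in range(n):
                P[i, j] = 0.5 if i == j else W[i, j] / (2 * denom)
        S = np.zeros((n, n))
        for i in range(n):
            order = sorted((j for j in range(n) if j != i),
                           key=lambda j: (-W[i, j], j))
            nbrs = order[:K]
            denom = sum(W[i, j] for j in nbrs)
            for j in nbrs:
                S[i, j] = W[i, j] / denom
        mats.append((W, P, S))
    (W1, P1, S1), (W2, P2, S2) = mats
    iterates = []
    for _ in range(t):
        P1n = S1 @ P2 @ S1.T
        P2n = S2 @ P1 @ S2.T
        if renormalize:
            P1n, P2n = _renorm_loop(P1n), _renorm_loop(P2n)
        P1, P2 = P1n, P2n
        iterates.append((P1.copy(), P2.copy()))
    fused = 0.5 * (P1 + P2)
    return (W1, P1, S1), (W2, P2, S2), 0.5 * (fused + fused.T), iterates


def _renorm_loop(P):
    n = P.shape[0]
    out = np.zeros_like(P)
    for i in range(n):
        denom = sum(P[i, k] for k in range(n) if k != i)
        denom = max(denom, np.finfo(float).tiny)
        for j in range(n):
            out[i, j] = 0.5 if i == j else P[i, j] / (2 * denom)
    return out


class TestPairwiseDistance:
    def test_identical_rows_have_zero_distance(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        D = pairwise_distance(X)
        assert D[0, 1] == 0.0

    def test_one_dimensional_closed_form(self):
        X = np.array([[0.0], [3.0]])
        assert pairwise_distance(X)[0, 1] == pytest.approx(3.0)
        assert pairwise_distance(X, squared=True)[0, 1] == pytest.approx(9.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        D = pairwise_distance(X)
        for i in range(6):
            for j in range(6):
                assert D[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-10)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        D = pairwise_distance(rng.normal(size=(5, 4)))
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)


class TestAffinity:
    def test_unit_self_affinity(self):
        rng = np.random.default_rng(2)
        D = pairwise_distance(rng.normal(size=(5, 3)))
        W = affinity(D, SNFConfig(n_neighbors=2))
        assert np.all(np.diag(W) == 1.0)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        W = affinity(pairwise_distance(rng.normal(size=(6, 2))),
                     SNFConfig(n_neighbors=2))
        assert np.allclose(W, W.T, atol=1e-12)

    def test_scalar_oracle_three_points(self):
        # 1-D points {0, 1, 10}, K=1, μ=0.5, kernel applied literally
        X = np.array([[0.0], [1.0], [10.0]])
        D = pairwise_distance(X)
        W = affinity(D, SNFConfig(n_neighbors=1, mu=0.5))
        mk = np.array([1.0, 1.0, 9.0])  # nearest-neighbour distances
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                eps = (mk[i] + mk[j] + D[i, j]) / 3.0
                assert W[i, j] == pytest.approx(
                    np.exp(-D[i, j] ** 2 / (0.5 * eps)), abs=1e-12)

    def test_coincident_points_warn_not_crash(self):
        X = np.zeros((3, 2))
        D = pairwise_distance(X)
        with pytest.warns(UserWarning, match="coincident"):
            W = affinity(D, SNFConfig(n_neighbors=1))
        assert np.all(np.isfinite(W))


class TestFullKernel:
    def test_diagonal_exactly_half(self):
        rng = np.random.default_rng(4)
        W = np.abs(rng.normal(size=(5, 5))) + 0.1
        P = full_kernel(W)
        assert np.all(np.diag(P) == 0.5)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        W = np.abs(rng.normal(size=(7, 7))) + 0.1
        assert np.allclose(full_kernel(W).sum(axis=1), 1.0, atol=1e-12)

    def test_ones_matrix_closed_form(self):
        P = full_kernel(np.ones((3, 3)))
        off = P[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.25)

    def test_isolated_cell_errors(self):
        W = np.eye(3)
        with pytest.raises(ValueError, match="isolated"):
            full_kernel(W)


class TestKnnKernel:
    def test_full_neighbourhood_reduces_to_row_normalised_offdiagonal(self):
        rng = np.random.default_rng(6)
        W = np.abs(rng.normal(size=(5, 5))) + 0.1
        W = 0.5 * (W + W.T)
        S = knn_kernel(W, 4)
        off = W.copy()
        np.fill_diagonal(off, 0.0)
        expected = off / off.sum(axis=1, keepdims=True)
        assert np.allclose(S, expected, atol=1e-12)

    def test_rows_have_exactly_k_nonzeros_summing_to_one(self):
        rng = np.random.default_rng(7)
        W = np.abs(rng.normal(size=(8, 8))) + 0.1
        W = 0.5 * (W + W.T)
        S = knn_kernel(W, 3)
        assert np.all((S > 0).sum(axis=1) == 3)
        assert np.allclose(S.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_built_scalar_oracle(self):
        W = np.array([[1.0, 0.9, 0.5, 0.1],
                      [0.9, 1.0, 0.2, 0.4],
                      [0.5, 0.2, 1.0, 0.8],
                      [0.1, 0.4, 0.8, 1.0]])
        S = knn_kernel(W, 2)
        # row 0: neighbours 1 (0.9) and 2 (0.5)
        assert S[0, 1] == pytest.approx(0.9 / 1.4)
        assert S[0, 2] == pytest.approx(0.5 / 1.4)
        assert S[0, 3] == 0.0

    def test_tie_at_boundary_prefers_smaller_index(self):
        W = np.array([[1.0, 0.5, 0.5, 0.5],
                      [0.5, 1.0, 0.5, 0.5],
                      [0.5, 0.5, 1.0, 0.5],
                      [0.5, 0.5, 0.5, 1.0]])
        S = knn_kernel(W, 2)
        assert S[0, 1] > 0 and S[0, 2] > 0 and S[0, 3] == 0.0
        assert S[3, 0] > 0 and S[3, 1] > 0 and S[3, 2] == 0.0


class TestSNFFuse:
    @staticmethod
    def _two_block_reps(n_per=3, sep=5.0, seed=0, d=2):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(2 * n_per, d)) * 0.3
        X[n_per:] += sep
        return X

    def test_identical_modalities_keep_iterates_equal(self):
        X = self._two_block_reps()
        cfg = SNFConfig(n_neighbors=2, iterations=4, convergence_tol=0)
        D = pairwise_distance(X)
        W = affinity(D, cfg)
        P, S = full_kernel(W), knn_kernel(W, 2)
        fused = snf_fuse(P, P, S, S, t=4, convergence_tol=0)
        # both iterates evolve identically, so fused equals one diffused P
        P1 = P.copy()
        for _ in range(4):
            P1 = _renormalize(S @ P1 @ S.T)
        assert np.allclose(fused, 0.5 * (P1 + P1.T), atol=1e-12)

    @pytest.mark.parametrize("renorm", [True, False])
    def test_matches_loop_oracle_four_cells(self, renorm):
        rng = np.random.default_rng(8)
        X1 = self._two_block_reps(n_per=2, seed=1)
        X2 = self._two_block_reps(n_per=2, seed=2)
        cfg = SNFConfig(n_neighbors=2, mu=0.5)
        (W1, _, S1), (W2, _, S2), fused_ref, _ = naive_snf(
            X1, X2, K=2, mu=0.5, t=2, renormalize=renorm)
        D1, D2 = pairwise_distance(X1), pairwise_distance(X2)
        Wa, Wb = affinity(D1, cfg), affinity(D2, cfg)
        fused = snf_fuse(full_kernel(Wa), full_kernel(Wb),
                         knn_kernel(Wa, 2), knn_kernel(Wb, 2),
                         t=2, renormalize=renorm, convergence_tol=0)
        assert np.allclose(Wa, W1, atol=1e-10)
        assert np.allclose(fused, fused_ref, atol=1e-10)

    def test_within_block_mass_not_diluted_by_diffusion(self):
        X1 = self._two_block_reps(n_per=5, seed=3)
        X2 = self._two_block_reps(n_per=5, seed=4)
        cfg = SNFConfig(n_neighbors=3)
        D1, D2 = pairwise_distance(X1), pairwise_distance(X2)
        W1, W2 = affinity(D1, cfg), affinity(D2, cfg)
        P1, P2 = full_kernel(W1), full_kernel(W2)
        S1, S2 = knn_kernel(W1, 3), knn_kernel(W2, 3)
        fused = snf_fuse(P1, P2, S1, S2, t=10, convergence_tol=0)
        block = np.zeros((10, 10), dtype=bool)
        block[:5, :5] = block[5:, 5:] = True
        initial = 0.5 * (P1 + P2)
        frac = lambda M: M[block].sum() / M.sum()
        assert frac(fused) >= frac(initial) - 1e-12

    def test_nonnegativity_preserved_at_every_iteration(self):
        X1 = self._two_block_reps(n_per=3, seed=5)
        X2 = self._two_block_reps(n_per=3, seed=6)
        _, _, _, iterates = naive_snf(X1, X2, K=2, mu=0.5, t=6)
        for P1, P2 in iterates:
            assert np.all(P1 >= 0) and np.all(P2 >= 0)

    def test_permutation_consistency(self):
        rng = np.random.default_rng(9)
        X1, X2 = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        cfg = SNFConfig(n_neighbors=3, iterations=5, convergence_tol=0)
        fused = snf_pipeline(X1, X2, cfg).fused
        perm = rng.permutation(8)
        fused_p = snf_pipeline(X1[perm], X2[perm], cfg).fused
        assert np.allclose(fused_p, fused[np.ix_(perm, perm)], atol=1e-10)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            snf_fuse(np.ones((3, 3)), np.ones((3, 3)), np.ones((3, 3)),
                     np.ones((4, 4)))


class TestBuildAdjacency:
    def test_symmetric_with_positive_diagonal(self):
        rng = np.random.default_rng(10)
        F = np.abs(rng.normal(size=(6, 6)))
        F = 0.5 * (F + F.T)
        A = build_adjacency(F, self_loops=True)
        assert np.allclose(A, A.T)
        assert np.all(np.diag(A) > 0)

    def test_topk_sparsification_keeps_at_least_k_per_row(self):
        rng = np.random.default_rng(11)
        F = np.abs(rng.normal(size=(10, 10)))
        F = 0.5 * (F + F.T)
        A = build_adjacency(F, self_loops=False, top_k=3)
        assert np.all((A > 0).sum(axis=1) >= 3)

    def test_negative_input_errors(self):
        with pytest.raises(ValueError):
            build_adjacency(-np.ones((2, 2)))
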