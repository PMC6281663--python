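"""Stability-NNMF tests: initialization, updates, matching, variability, K."""

import itertools

import numpy as np
import pytest

from taskphase import nnmf
from taskphase import synthetic as syn


def _random_nonneg(rng, shape):
    return rng.random(shape)


def _planted_matrix(rng, n_rows=60, noise=0.0):
    """Rows built from two disjoint non-negative patterns."""
    w1 = np.zeros(1004)
    w1[:300] = 1.0
    w2 = np.zeros(1004)
    w2[600:] = 1.0
    W = np.stack([w1, w2])
    H = rng.random((n_rows, 2)) * np.array([1.0, 2.0])
    R = H @ W
    if noise:
        R = np.clip(R + rng.normal(0, noise, R.shape), 0, None)
    return R, H, W


class TestInitFactors:
    def test_determinism(self, rng):
        R = _random_nonneg(np.random.default_rng(0), (12, 20))
        a = nnmf.init_factors(R, 3, seed=5)
        b = nnmf.init_factors(R, 3, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_w0_offset_keeps_entries_above_threshold(self):
        R = _random_nonneg(np.random.default_rng(1), (10, 15))
        mins = [nnmf.init_factors(R, 4, seed=s)[0].min() for s in range(10)]
        assert min(mins) >= 0.1

    def test_h0_positive(self):
        R = _random_nonneg(np.random.default_rng(2), (10, 15))
        _, H0 = nnmf.init_factors(R, 3, seed=0)
        assert np.all(H0 > 0)

    def test_h0_recovers_planted_weights_given_true_w(self, rng):
        # constructed 6x8 instance, K=2: least-squares H against the true W
        W_true = np.abs(rng.normal(size=(2, 8))) + 0.2
        H_true = np.abs(rng.normal(size=(6, 2))) + 0.2
        R = H_true @ W_true
        H0 = nnmf._init_H(R, W_true)
        np.testing.assert_allclose(H0, H_true, atol=1e-6)


class TestMultiplicativeUpdates:
    def test_objective_never_increases(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            R = _random_nonneg(rng, (20, 30))
            W0, H0 = nnmf.init_factors(R, 4, seed=seed)
            f = nnmf.fit_multiplicative(R, W0, H0, max_iter=150, rel_tol=0)
            diffs = np.diff(f.objective)
            assert np.all(diffs <= 1e-9 * np.abs(f.objective[0]))

    def test_rank_one_matrix_fully_explained(self, rng):
        R = np.outer(rng.random(15) + 0.1, rng.random(25) + 0.1)
        W0, H0 = nnmf.init_factors(R, 1, seed=0)
        f = nnmf.fit_multiplicative(R, W0, H0, max_iter=2000, rel_tol=1e-12)
        assert f.explained_energy >= 0.9999

    def test_zero_matrix_convention(self):
        R = np.zeros((5, 8))
        W0, H0 = nnmf.init_factors(np.ones((5, 8)), 2, seed=0)
        f = nnmf.fit_multiplicative(R, W0, H0)
        assert f.residual_energy == 0.0
        np.testing.assert_array_equal(f.W, W0)

    def test_nonnegativity_preserved(self, rng):
        R = _random_nonneg(rng, (15, 20))
        W0, H0 = nnmf.init_factors(R, 3, seed=1)
        f = nnmf.fit_multiplicative(R, W0, H0, max_iter=300)
        assert np.all(f.W >= 0) and np.all(f.H >= 0)

    def test_matches_sklearn_reference_objective(self):
        # independent reference implementation reaches a comparable optimum
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(3)
        R = _random_nonneg(rng, (30, 40))
        W0, H0 = nnmf.init_factors(R, 5, seed=3)
        ours = nnmf.fit_multiplicative(R, W0, H0, max_iter=1000, rel_tol=1e-10)
        ref = NMF(n_components=5, init="custom", solver="mu", max_iter=1000,
                  tol=1e-10).fit(R, W=H0.copy(), H=W0.copy())
        ref_resid = ref.reconstruction_err_ ** 2 / np.sum(R * R)
        assert ours.residual_energy == pytest.approx(ref_resid, rel=0.02)

    def test_permutation_equivariance(self, rng):
        R = _random_nonneg(rng, (12, 18))
        W0, H0 = nnmf.init_factors(R, 3, seed=4)
        perm = rng.permutation(12)
        f = nnmf.fit_multiplicative(R, W0, H0, max_iter=100, rel_tol=0)
        g = nnmf.fit_multiplicative(R[perm], W0, H0[perm], max_iter=100, rel_tol=0)
        np.testing.assert_allclose(g.H, f.H[perm], rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(g.W, f.W, rtol=1e-8, atol=1e-10)


class TestEnergyDecomposition:
    def test_exact_factorization(self, rng):
        R, H, W = _planted_matrix(rng)
        f = nnmf.Factorization(W=W, H=H, residual_energy=0, explained_energy=1)
        explained, residual = nnmf.energy_decomposition(R, f)
        assert explained == pytest.approx(1.0)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_zero_weights(self, rng):
        R, H, W = _planted_matrix(rng)
        f = nnmf.Factorization(W=W, H=np.zeros_like(H), residual_energy=1,
                               explained_energy=0)
        explained, residual = nnmf.energy_decomposition(R, f)
        assert (explained, residual) == (0.0, 1.0)

    def test_near_complementarity_at_convergence(self, rng):
        R = _random_nonneg(rng, (10, 12))
        W0, H0 = nnmf.init_factors(R, 3, seed=0)
        f = nnmf.fit_multiplicative(R, W0, H0, max_iter=3000, rel_tol=1e-12)
        explained, residual = nnmf.energy_decomposition(R, f)
        assert 0.95 <= explained + residual <= 1.05

    def test_zero_matrix_is_an_error(self):
        f = nnmf.Factorization(W=np.ones((2, 4)), H=np.ones((3, 2)),
                               residual_energy=0, explained_energy=0)
        with pytest.raises(ValueError):
            nnmf.energy_decomposition(np.zeros((3, 4)), f)


class TestMatchComponents:
    def test_identity_matches_everything(self, rng):
        W = _random_nonneg(rng, (4, 30))
        pairs = nnmf.match_components(W, W)
        assert [(i, j) for i, j, _ in pairs] == [(k, k) for k in range(4)]
        assert all(s == pytest.approx(1.0) for *_, s in pairs)

    def test_disjoint_supports_do_not_match(self):
        W_a = np.zeros((2, 10))
        W_a[0, :3] = 1
        W_a[1, 3:6] = 1
        W_b = np.zeros((2, 10))
        W_b[0, 6:8] = 1
        W_b[1, 8:] = 1
        assert nnmf.match_components(W_a, W_b) == []

    @pytest.mark.parametrize("K", [2, 3, 4, 5])
    def test_recovers_row_permutation_against_brute_force(self, K, rng):
        W = _random_nonneg(rng, (K, 40)) + 0.1
        perm = rng.permutation(K)
        pairs = nnmf.match_components(W, W[perm] * 1.7)
        recovered = {i: j for i, j, _ in pairs}
        assert recovered == {int(perm[k]): int(k) for k in range(K)}
        # optimal assignment beats (or ties) every permutation, exhaustively
        S = nnmf.cosine_similarity_matrix(W, W[perm])
        best = max(sum(S[i, p[i]] for i in range(K))
                   for p in itertools.permutations(range(K)))
        achieved = sum(S[i, j] for i, j, _ in nnmf.match_components(W, W[perm],
                                                                    threshold=-1))
        assert achieved == pytest.approx(best)

    def test_zero_row_has_zero_similarity(self):
        W_a = np.vstack([np.zeros(10), np.ones(10)])
        S = nnmf.cosine_similarity_matrix(W_a, W_a)
        assert S[0, 0] == 0.0 and S[0, 1] == 0.0


class TestKpcaReorder:
    def test_same_matrix_receives_same_order(self, rng):
        W = _random_nonneg(rng, (4, 20))
        A, B = nnmf.kpca_reorder(W, W.copy())
        np.testing.assert_array_equal(A, B)

    def test_reordering_is_a_permutation(self, rng):
        W_a = _random_nonneg(rng, (5, 20))
        W_b = _random_nonneg(rng, (5, 20))
        A, B = nnmf.kpca_reorder(W_a, W_b)
        for orig, new in ((W_a, A), (W_b, B)):
            assert sorted(map(tuple, orig)) == sorted(map(tuple, new))

    def test_two_cluster_structure_aligns_matched_rows(self, rng):
        # rows from 2 well-separated clusters must get the same rank in both
        c1 = np.zeros(30)
        c1[:10] = 5.0
        c2 = np.zeros(30)
        c2[20:] = 5.0
        W_a = np.stack([c1 + rng.normal(0, .05, 30), c2 + rng.normal(0, .05, 30)])
        W_b = np.stack([c2 + rng.normal(0, .05, 30), c1 + rng.normal(0, .05, 30)])
        A, B = nnmf.kpca_reorder(W_a, W_b)
        # nearest-neighbour matching after reordering is the identity
        S = nnmf.cosine_similarity_matrix(A, B)
        assert np.all(np.argmax(S, axis=1) == np.arange(2))

    def test_identical_rows_fall_back_to_stable_order(self):
        W = np.ones((3, 10))
        A, B = nnmf.kpca_reorder(W, W.copy())
        np.testing.assert_array_equal(A, W)


class TestComponentVariability:
    def test_identical_history_gives_zero(self, rng):
        W = _random_nonneg(rng, (3, 20))
        hist = np.stack([W] * 15)
        np.testing.assert_allclose(nnmf.component_variability(hist), 0.0,
                                   atol=1e-15)

    def test_iid_scale_fluctuations_match_closed_form(self, rng):
        W = _random_nonneg(rng, (1, 50)) + 0.5
        eps = rng.uniform(-0.01, 0.01, size=200)
        hist = np.stack([(1 + e) * W for e in eps])
        ratio = nnmf.component_variability(hist)[0]
        expected = np.var(eps, ddof=1) / np.mean((1 + eps) ** 2)
        assert ratio == pytest.approx(expected, rel=1e-6)

    def test_uniform_amplitude_doubling_leaves_ratio_unchanged(self, rng):
        hist = rng.random((15, 2, 30)) + 0.1
        base = nnmf.component_variability(hist)
        doubled = hist.copy()
        doubled[:, 1, :] *= 2.0
        np.testing.assert_allclose(nnmf.component_variability(doubled), base)

    def test_all_zero_component_flagged_unstable(self):
        hist = np.zeros((15, 1, 10))
        assert np.isinf(nnmf.component_variability(hist)[0])


class TestBootstrapStability:
    def test_determinism_under_fixed_seed(self, rng):
        R, _, _ = _planted_matrix(rng, n_rows=30, noise=0.05)
        a = nnmf.bootstrap_stability_run(R, 2, seed=8, n_bootstrap=8,
                                         history_len=5, inner_max_iter=50)
        b = nnmf.bootstrap_stability_run(R, 2, seed=8, n_bootstrap=8,
                                         history_len=5, inner_max_iter=50)
        np.testing.assert_array_equal(a.factorization.W, b.factorization.W)
        np.testing.assert_array_equal(a.variability, b.variability)

    def test_planted_patterns_are_stable(self, rng):
        R, _, _ = _planted_matrix(rng, n_rows=100)
        run = nnmf.bootstrap_stability_run(R, 2, seed=0, n_bootstrap=16,
                                           history_len=8, inner_max_iter=200)
        assert np.all(run.variability < 1e-3)
        assert run.factorization.explained_energy >= 0.999

    def test_noise_rows_less_stable_than_planted_structure(self, rng):
        R_planted, _, _ = _planted_matrix(rng, n_rows=60, noise=0.05)
        noise_var, planted_var = [], []
        for seed in range(3):
            R_noise = np.random.default_rng(seed).random((60, 1004))
            noise_var.append(nnmf.bootstrap_stability_run(
                R_noise, 5, seed=seed, n_bootstrap=12, history_len=6,
                inner_max_iter=80).mean_variability)
            planted_var.append(nnmf.bootstrap_stability_run(
                R_planted, 2, seed=seed, n_bootstrap=12, history_len=6,
                inner_max_iter=80).mean_variability)
        assert np.median(noise_var) > np.median(planted_var)

    def test_shuffled_time_control_is_less_stable(self, rng):
        R, _, _ = _planted_matrix(rng, n_rows=60, noise=0.05)
        shuf = np.stack([np.random.default_rng(i).permutation(row) for i, row
                         in enumerate(R)])
        planted = [nnmf.bootstrap_stability_run(R, 2, seed=s, n_bootstrap=12,
                                                history_len=6, inner_max_iter=80
                                                ).mean_variability
                   for s in range(3)]
        control = [nnmf.bootstrap_stability_run(shuf, 2, seed=s, n_bootstrap=12,
                                                history_len=6, inner_max_iter=80
                                                ).mean_variability
                   for s in range(3)]
        assert np.median(control) > np.median(planted)

    def test_too_few_rows_rejected(self, rng):
        R = _random_nonneg(rng, (5, 20))
        with pytest.raises(ValueError):
            nnmf.bootstrap_stability_run(R, 3, seed=0)


class TestSelectK:
    def test_exact_rank_two_recognized_stable_with_single_run(self, rng):
        # noise-free rank-2 structure: K=2 is judged stable by a single run
        # and recovered essentially exactly.  (Over-complete K on noise-free
        # data is degenerate — duplicate components reproduce perfectly — so
        # the largest-stable-K rule is only discriminative on noisy data.)
        R, _, _ = _planted_matrix(rng, n_rows=50)
        report = nnmf.select_k(R, k_range=[2], runs=1, seed=0,
                               n_bootstrap=12, history_len=6,
                               inner_max_iter=300, inner_rel_tol=1e-7)
        assert report.selected_k == 2
        assert report.median_by_k[2] < 0.05
        assert report.factorization.explained_energy >= 0.999

    def test_no_admissible_k_raises_with_table(self, rng):
        R = np.random.default_rng(0).random((30, 1004))
        with pytest.raises(nnmf.KSelectionError, match="median"):
            nnmf.select_k(R, k_range=[5], runs=2, seed=0, n_bootstrap=10,
                          history_len=5, inner_max_iter=60,
                          variability_cutoff=1e-6)
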