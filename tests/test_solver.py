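import numpy as np
import pytest

from nmfmcc import (
    ExpressionMatrix,
    SolverConfig,
    cluster_codings,
    cm_update_H,
    cm_update_W,
    estep_rho,
    fit_baseline_nmf,
    fit_nmf_mcc,
    init_factors,
    row_squared_residuals,
    update_bandwidth,
    weighted_objective,
)

from conftest import random_instance


class TestInitFactors:
    def test_deterministic_given_seed(self):
        a = init_factors(10, 6, 3, seed=4)
        b = init_factors(10, 6, 3, seed=4)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        c = init_factors(10, 6, 3, seed=5)
        assert not np.array_equal(a[0], c[0])

    def test_strictly_positive(self):
        H, W = init_factors(50, 40, 5, seed=0)
        assert (H > 0).all() and (W > 0).all()

    def test_mean_scaling_over_many_seeds(self):
        # mean(HW) should sit within 10% of the requested target
        for seed in range(100):
            target = 0.5 + 3 * (seed % 7)  # varied positive targets
            H, W = init_factors(30, 20, 4, seed=seed, target_mean=target)
            assert np.mean(H @ W) == pytest.approx(target, rel=1e-12)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            init_factors(3, 2, 4, seed=0)


class TestWeightedObjective:
    def test_zero_iff_exact(self):
        rng = np.random.default_rng(2)
        H, W = rng.random((4, 2)), rng.random((2, 3))
        assert weighted_objective(H @ W, H, W, -np.ones(4)) == pytest.approx(0, abs=1e-24)

    def test_uniform_weights_collapse_to_l2_loss(self):
        X, H, W = random_instance(3)
        l2 = float(np.sum((X - H @ W) ** 2))
        assert weighted_objective(X, H, W, -np.ones(X.shape[0])) == pytest.approx(l2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop(self, seed):
        X, H, W = random_instance(seed, D=5, N=4, K=2)
        rng = np.random.default_rng(seed + 100)
        rho = -rng.uniform(0.01, 1.0, size=5)
        Y = H @ W
        expected = sum(
            (-rho[d]) * sum((X[d, n] - Y[d, n]) ** 2 for n in range(4))
            for d in range(5)
        )
        assert weighted_objective(X, H, W, rho) == pytest.approx(expected, rel=1e-12)


class TestCmUpdates:
    def test_hand_computed_instance(self):
        """2x2, K=1 instance worked out by hand from the update rules."""
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        H = np.array([[0.5], [1.0]])
        W = np.array([[1.0, 1.0]])
        rho = np.array([-1.0, -0.5])
        H2 = cm_update_H(X, H, W, rho, 0.0)
        np.testing.assert_allclose(H2, [[1.5], [3.5]], rtol=1e-14)
        W2 = cm_update_W(X, H2, W, rho, 0.0)
        np.testing.assert_allclose(
            W2, [[6.75 / 8.375, 10.0 / 8.375]], rtol=1e-14
        )

    def test_exact_fit_is_fixed_point(self):
        rng = np.random.default_rng(7)
        H, W = rng.random((6, 2)) + 0.1, rng.random((2, 5)) + 0.1
        X = H @ W
        rho = -rng.uniform(0.1, 1.0, size=6)
        np.testing.assert_allclose(cm_update_H(X, H, W, rho, 0.0), H, rtol=1e-13)
        np.testing.assert_allclose(cm_update_W(X, H, W, rho, 0.0), W, rtol=1e-13)

    @pytest.mark.parametrize("seed", range(5))
    def test_uniform_weights_reduce_to_lee_seung(self, seed):
        X, H, W = random_instance(seed)
        rho = -np.ones(X.shape[0])
        np.testing.assert_allclose(
            cm_update_H(X, H, W, rho, 0.0),
            H * (X @ W.T) / (H @ W @ W.T),
            rtol=1e-13,
        )
        np.testing.assert_allclose(
            cm_update_W(X, H, W, rho, 0.0),
            W * (H.T @ X) / (H.T @ H @ W),
            rtol=1e-13,
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_nonincreasing_with_rho_fixed(self, seed):
        X, H, W = random_instance(seed, D=20, N=12, K=3)
        r2 = row_squared_residuals(X, H, W)
        rho = estep_rho(r2, update_bandwidth(r2, 1.0))
        for _ in range(5):
            before = weighted_objective(X, H, W, rho)
            H = cm_update_H(X, H, W, rho)
            mid = weighted_objective(X, H, W, rho)
            W = cm_update_W(X, H, W, rho)
            after = weighted_objective(X, H, W, rho)
            assert mid <= before * (1 + 1e-9)
            assert after <= mid * (1 + 1e-9)

    def test_zeros_are_absorbing(self):
        X, H, W = random_instance(9)
        H[0, 0] = 0.0
        W[1, 2] = 0.0
        rho = -np.full(X.shape[0], 0.5)
        H2 = cm_update_H(X, H, W, rho)
        assert H2[0, 0] == 0.0
        W2 = cm_update_W(X, H2, W, rho)
        assert W2[1, 2] == 0.0


class TestFitNmfMcc:
    def test_invariants_over_seeds(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 20))
        for seed in range(8):
            res = fit_nmf_mcc(X, SolverConfig(k=3, max_iter=40, seed=seed))
            assert (res.H >= 0).all() and (res.W >= 0).all()
            assert np.isfinite(res.H).all() and np.isfinite(res.W).all()
            assert np.all(res.rho >= -1) and np.all(res.rho <= 0)
            t = res.objective_trace
            # monotone within each CM pair while rho is fixed
            assert (t["objective_after_h"] <= t["objective_estep"] * (1 + 1e-9)).all()
            assert (t["objective"] <= t["objective_after_h"] * (1 + 1e-9)).all()

    def test_exact_rank_k_input_drives_objective_down(self):
        rng = np.random.default_rng(3)
        H, W = rng.random((15, 2)) + 0.5, rng.random((2, 10)) + 0.5
        res = fit_nmf_mcc(H @ W, SolverConfig(k=2, max_iter=400, seed=1))
        obj = res.objective_trace["objective"]
        assert obj.iloc[-1] < 1e-2 * obj.iloc[0]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.random((20, 12))
        a = fit_nmf_mcc(X, SolverConfig(k=3, max_iter=30, seed=9))
        b = fit_nmf_mcc(X, SolverConfig(k=3, max_iter=30, seed=9))
        np.testing.assert_array_equal(a.H, b.H)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.rho, b.rho)

    def test_scale_indifference_of_cluster_assignments(self):
        """Rescaling X rescales sigma^2 but leaves rho and clusters alone."""
        rng = np.random.default_rng(6)
        X = rng.random((40, 16)) + 0.1
        cfg = SolverConfig(k=3, max_iter=60, seed=2, denom_guard=0.0)
        a = fit_nmf_mcc(X, cfg)
        b = fit_nmf_mcc(10.0 * X, cfg)
        np.testing.assert_allclose(b.rho, a.rho, atol=1e-8)
        assert b.sigma2 == pytest.approx(100.0 * a.sigma2, rel=1e-6)
        la = cluster_codings(a.W, 3, seed=0)
        lb = cluster_codings(b.W, 3, seed=0)
        # same partition up to label names
        from nmfmcc import matched_accuracy
        acc, _ = matched_accuracy(la, [str(x) for x in lb])
        assert acc == 1.0

    def test_rejects_invalid_inputs(self):
        with pytest.raises(Exception):
            fit_nmf_mcc(np.array([[1.0, -1.0]]), SolverConfig(k=1))
        with pytest.raises(ValueError):
            fit_nmf_mcc(np.ones((3, 2)), SolverConfig(k=3))


class TestBaselines:
    @pytest.mark.parametrize("loss", ["l2", "kl"])
    def test_objective_monotone_and_uniform_rho(self, loss):
        rng = np.random.default_rng(1)
        X = rng.random((25, 15)) + 0.05
        for seed in range(5):
            res = fit_baseline_nmf(X, SolverConfig(k=3, max_iter=50, seed=seed), loss=loss)
            obj = res.objective_trace["objective"].to_numpy()
            assert np.all(np.diff(obj) <= np.abs(obj[:-1]) * 1e-9 + 1e-12)
            np.testing.assert_array_equal(res.rho, -np.ones(25))
            assert res.sigma2 is None

    def test_l2_matches_sklearn_multiplicative_updates(self):
        """Independent cross-check against sklearn's 'mu' Frobenius solver."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(8)
        X = rng.random((18, 10)) + 0.1
        k, n_steps = 3, 25
        H0, W0 = init_factors(18, 10, k, seed=5, target_mean=float(X.mean()))
        sk = NMF(
            n_components=k, init="custom", solver="mu", beta_loss="frobenius",
            max_iter=n_steps, tol=0.0,
        )
        # sklearn factorizes X = (samples x k) @ (k x features): rows play
        # the role of samples, so its W is this package's H
        Hs = sk.fit_transform(X, W=H0.copy(), H=W0.copy())
        Ws = sk.components_

        H, W = H0.copy(), W0.copy()
        rho = -np.ones(18)
        for _ in range(n_steps):
            H = cm_update_H(X, H, W, rho, 0.0)
            W = cm_update_W(X, H, W, rho, 0.0)
        np.testing.assert_allclose(H, Hs, rtol=1e-6)
        np.testing.assert_allclose(W, Ws, rtol=1e-6)

    def test_kl_exact_fit_is_near_fixed_point(self):
        rng = np.random.default_rng(10)
        H, W = rng.random((8, 2)) + 0.2, rng.random((2, 6)) + 0.2
        X = H @ W
        cfg = SolverConfig(k=2, max_iter=1, seed=0, denom_guard=1e-14)
        res = fit_baseline_nmf(X, cfg, loss="kl")
        # from a random init one KL step runs; objective stays finite and >= 0
        assert res.objective_trace["objective"].iloc[-1] >= 0
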