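import numpy as np
import pytest

from dsirep.factorization import (
    DivergenceError,
    DSIEmbedding,
    FactorizationConfig,
    _objective_grad,
    factorize,
    mean_abs_column_corr,
    objective,
    reconstruct,
)


def small_psi(rng, n=12):
    return rng.random((n, n))


class TestObjective:
    def test_zero_at_exact_product(self, rng):
        X = rng.random((10, 3))
        W = rng.random((10, 3))
        psi = X @ W.T
        emb = DSIEmbedding(X=X, W=W, variant="decorr")
        cfg = FactorizationConfig(n_dims=3, beta=0.0, rho_l2=0.0)
        total, terms = objective(emb, psi, cfg)
        assert total == pytest.approx(0.0, abs=1e-18)

    def test_identical_columns_decorrelation_unit(self, rng):
        col = rng.random(20)
        X = np.stack([col, col], axis=1)
        W = rng.random((20, 2))
        emb = DSIEmbedding(X=X, W=W, variant="decorr")
        cfg = FactorizationConfig(n_dims=2, beta=7.0, rho_l2=0.0)
        _, terms = objective(emb, X @ W.T, cfg)
        # one offending pair with corr = 1 contributes beta * 1
        assert terms["decorrelation"] == pytest.approx(7.0)

    @pytest.mark.parametrize("variant", ["decorr", "sparse", "decorr-nonneg-off"])
    def test_gradient_matches_finite_differences(self, rng, variant):
        n, D = 10, 4
        psi = small_psi(rng, n)
        X = rng.random((n, D))
        W = rng.random((n, D))
        cfg = FactorizationConfig(
            n_dims=D, variant=variant, beta=3.0, rho_l2=0.5, rho_l1=0.5
        )
        _, _, gX, gW = _objective_grad(X, W, psi, cfg)
        eps = 1e-6
        for M, g in ((X, gX), (W, gW)):
            num = np.zeros_like(M)
            for i in range(n):
                for k in range(D):
                    Mp, Mm = M.copy(), M.copy()
                    Mp[i, k] += eps
                    Mm[i, k] -= eps
                    args_p = (Mp, W, psi, cfg) if M is X else (X, Mp, psi, cfg)
                    args_m = (Mm, W, psi, cfg) if M is X else (X, Mm, psi, cfg)
                    fp = _objective_grad(*args_p)[0]
                    fm = _objective_grad(*args_m)[0]
                    num[i, k] = (fp - fm) / (2 * eps)
            rel = np.abs(num - g).max() / max(np.abs(num).max(), 1.0)
            assert rel < 1e-4

    def test_nan_rejected(self, rng):
        X = rng.random((5, 2))
        X[0, 0] = np.nan
        cfg = FactorizationConfig(n_dims=2)
        with pytest.raises(ValueError, match="NaN"):
            _objective_grad(X, rng.random((5, 2)), rng.random((5, 5)), cfg)

    def test_column_permutation_invariance(self, rng):
        n, D = 15, 5
        psi = small_psi(rng, n)
        X, W = rng.random((n, D)), rng.random((n, D))
        cfg = FactorizationConfig(n_dims=D, beta=2.0, rho_l2=0.3)
        t1, _ = objective(DSIEmbedding(X=X, W=W, variant="decorr"), psi, cfg)
        perm = rng.permutation(D)
        t2, _ = objective(
            DSIEmbedding(X=X[:, perm], W=W[:, perm], variant="decorr"), psi, cfg
        )
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestFactorize:
    def test_planted_rank_two_recovery(self, rng):
        A, B = rng.random((20, 2)), rng.random((20, 2))
        psi = A @ B.T
        cfg = FactorizationConfig(
            n_dims=2, beta=0.0, rho_l2=0.0, learning_rate=0.02,
            n_iter=3000, seed=1, dtype="float64",
        )
        emb = factorize(psi, cfg)
        rec = reconstruct(emb)
        assert np.linalg.norm(rec - psi) / np.linalg.norm(psi) < 0.05
        assert (rec >= 0).all()  # product of nonnegative factors

    def test_nonneg_projection_exact(self, rng):
        psi = small_psi(rng)
        cfg = FactorizationConfig(n_dims=3, n_iter=50, seed=0)
        emb = factorize(psi, cfg)
        assert emb.X.min() >= 0.0 and emb.W.min() >= 0.0

    def test_nonneg_off_allows_negative(self, rng):
        psi = small_psi(rng)
        cfg = FactorizationConfig(
            n_dims=3, variant="decorr-nonneg-off", n_iter=200, seed=0
        )
        emb = factorize(psi, cfg)
        assert emb.X.min() < 0.0 or emb.W.min() < 0.0

    def test_decorrelation_reduces_column_correlation(self):
        # paired runs from the same init: beta > 0 yields strictly lower
        # mean |corr| among X columns than beta = 0
        from dsirep.gridworld import build_room
        from dsirep.successor import compute_psi, occupancy, sr_analytic

        env = build_room(12, 12)
        T = env.transition_matrix()
        psi = compute_psi(sr_analytic(T, 0.95), occupancy(T)).values
        kw = dict(n_dims=16, rho_l2=0.1, learning_rate=0.03, n_iter=800, seed=4)
        emb_plain = factorize(psi, FactorizationConfig(beta=0.0, **kw))
        emb_decor = factorize(psi, FactorizationConfig(beta=500.0, **kw))
        assert mean_abs_column_corr(emb_decor.X) < mean_abs_column_corr(emb_plain.X)

    def test_loss_trend_decreasing(self, rng):
        psi = small_psi(rng, 16)
        cfg = FactorizationConfig(n_dims=4, n_iter=400, seed=2)
        emb = factorize(psi, cfg)
        trace = emb.loss_trace
        assert np.median(trace[-50:]) < np.median(trace[:50])

    def test_divergence_raises(self, rng):
        psi = small_psi(rng)
        cfg = FactorizationConfig(
            n_dims=3, learning_rate=80.0, n_iter=500, seed=0, rho_l2=0.0, beta=0.0
        )
        with pytest.raises(DivergenceError, match="learning rate"):
            factorize(psi, cfg)

    def test_dims_must_be_smaller_than_states(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            factorize(small_psi(rng, 5), FactorizationConfig(n_dims=5))

    def test_negative_psi_rejected(self, rng):
        psi = small_psi(rng) - 1.0
        with pytest.raises(ValueError, match="nonnegative"):
            factorize(psi, FactorizationConfig(n_dims=3))

    def test_seeded_reproducibility(self, rng):
        psi = small_psi(rng)
        cfg = FactorizationConfig(n_dims=3, n_iter=100, seed=9)
        e1 = factorize(psi, cfg)
        e2 = factorize(psi, cfg)
        assert np.array_equal(e1.X, e2.X) and np.array_equal(e1.W, e2.W)


class TestWarmStart:
    def test_warm_start_shape_checked(self, rng):
        psi = small_psi(rng)
        cfg = FactorizationConfig(n_dims=3, n_iter=10)
        with pytest.raises(ValueError, match="warm-start"):
            factorize(psi, cfg, warm_start=(np.ones((2, 2)), np.ones((2, 2))))

    def test_anchor_requires_warm_start(self, rng):
        psi = small_psi(rng)
        cfg = FactorizationConfig(n_dims=3, n_iter=10)
        with pytest.raises(ValueError, match="anchor"):
            factorize(psi, cfg, anchor_weight=1.0)

    def test_anchoring_limits_drift(self, rng):
        # with a strong proximal anchor the solution stays near the
        # reference; without it the same warm start drifts further
        psi = small_psi(rng, 16)
        cfg0 = FactorizationConfig(n_dims=4, n_iter=400, seed=3, beta=0.0)
        base = factorize(psi, cfg0)
        psi2 = psi + 0.5 * rng.random(psi.shape)
        free = factorize(psi2, cfg0, warm_start=(base.X, base.W))
        anchored = factorize(
            psi2, cfg0, warm_start=(base.X, base.W), anchor_weight=50.0
        )
        drift_free = np.linalg.norm(free.X - base.X)
        drift_anch = np.linalg.norm(anchored.X - base.X)
        assert drift_anch < drift_free


class TestEmbedding:
    def test_dead_units_reported(self, rng):
        X = rng.random((8, 3))
        W = rng.random((8, 3))
        X[:, 1] = 0.0
        emb = DSIEmbedding(X=X, W=W, variant="decorr")
        assert emb.dead_units().tolist() == [1]

    def test_variant_validation(self):
        with pytest.raises(ValueError, match="variant"):
            FactorizationConfig(variant="bogus")
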