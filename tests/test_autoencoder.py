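import numpy as np
import pytest

from aesig import autoencoder as ae
from aesig.autoencoder import (
    TrainingConfig,
    TrainingDivergedError,
    encode,
    forward,
    init_model,
    loss,
    loss_gradients,
    reconstruction_r2,
    relu,
    train,
)


def zero_model(d_in=3, hidden=(2, 1)):
    m = init_model(d_in, hidden, seed=0)
    for p in m.parameters():
        p[:] = 0
    return m


def forward_oracle(model, X):
    """Independent layer-by-layer loop over samples and units."""
    outs = []
    feats = []
    n_enc = len(model.enc_W)
    for x in np.asarray(X):
        a = list(x)
        chain = list(zip(model.enc_W, model.enc_b)) + list(
            zip(model.dec_W, model.dec_b)
        )
        for li, (W, b) in enumerate(chain):
            z = []
            for j in range(W.shape[1]):
                s = b[j]
                for i in range(W.shape[0]):
                    s += a[i] * W[i, j]
                z.append(s)
            is_bottleneck = li == n_enc - 1
            is_output = li == len(chain) - 1
            if is_output or (is_bottleneck and model.linear_bottleneck):
                a = z
            else:
                a = [v if v > 0 else 0.0 for v in z]
            if is_bottleneck:
                feats.append(list(a))
        outs.append(a)
    return np.array(feats), np.array(outs)


class TestRelu:
    def test_positive(self):
        assert relu(5) == 5

    def test_negative(self):
        assert relu(-2) == 0

    def test_boundary(self):
        assert relu(0) == 0


class TestInit:
    def test_same_seed_bitwise_identical(self):
        m1 = init_model(10, (6, 3), seed=42)
        m2 = init_model(10, (6, 3), seed=42)
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_default_architecture_shapes(self):
        m = init_model(1000, (400, 100, 20), seed=0)
        assert [w.shape for w in m.enc_W] == [(1000, 400), (400, 100), (100, 20)]
        assert [w.shape for w in m.dec_W] == [(20, 100), (100, 400), (400, 1000)]
        assert not m.trained

    def test_configurable_bottleneck(self):
        m = init_model(100, (40, 10), seed=0)
        assert m.bottleneck == 10
        X = np.random.default_rng(0).standard_normal((5, 100))
        F, _ = forward(m, X)
        assert F.shape == (5, 10)

    def test_non_decreasing_sizes_rejected(self):
        with pytest.raises(ValueError, match="decrease"):
            init_model(10, (10, 5), seed=0)
        with pytest.raises(ValueError, match="decrease"):
            init_model(10, (4, 6), seed=0)

    def test_biases_zero(self):
        m = init_model(8, (4, 2), seed=1)
        for b in m.enc_b + m.dec_b:
            assert np.all(b == 0)


class TestForward:
    def test_zero_model(self):
        m = zero_model()
        F, Xhat = forward(m, np.ones((4, 3)))
        assert np.all(F == 0) and np.all(Xhat == 0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        m = init_model(6, (4, 2), seed=5)
        for b in m.enc_b + m.dec_b:  # nonzero biases exercise every term
            b[:] = rng.standard_normal(b.shape) * 0.1
        X = rng.standard_normal((7, 6))
        F, Xhat = forward(m, X)
        F_exp, Xhat_exp = forward_oracle(m, X)
        np.testing.assert_allclose(F, F_exp, atol=1e-12)
        np.testing.assert_allclose(Xhat, Xhat_exp, atol=1e-12)

    def test_linear_bottleneck_flag(self):
        m = init_model(6, (4, 2), seed=5, linear_bottleneck=True)
        X = np.random.default_rng(6).standard_normal((20, 6))
        F, _ = forward(m, X)
        F_exp, _ = forward_oracle(m, X)
        np.testing.assert_allclose(F, F_exp, atol=1e-12)
        assert (F < 0).any()  # linear bottleneck admits negative scores

    def test_shape_mismatch_error(self):
        m = init_model(6, (4, 2), seed=0)
        with pytest.raises(ValueError, match="shape"):
            forward(m, np.ones((3, 5)))


class TestLoss:
    def test_zero_model_zero_input(self):
        assert loss(zero_model(), np.zeros((2, 3)), 0.1) == 0.0

    def test_zero_model_unit_sample(self):
        m = zero_model(d_in=2, hidden=(1,))
        assert loss(m, np.array([[1.0, 1.0]]), 0.0) == pytest.approx(1.0)

    def test_matches_termwise_oracle(self):
        rng = np.random.default_rng(9)
        m = init_model(5, (3, 2), seed=9)
        X = rng.standard_normal((6, 5))
        lam = 0.37
        _, Xhat = forward(m, X)
        expected = sum(
            0.5 * sum((x[i] - xh[i]) ** 2 for i in range(5))
            for x, xh in zip(X, Xhat)
        )
        expected += lam * sum(float((w**2).sum()) for w in m.enc_W + m.dec_W)
        assert loss(m, X, lam) == pytest.approx(expected, rel=1e-12)

    def test_lambda_decomposition_exact(self):
        m = init_model(5, (3, 2), seed=10)
        X = np.random.default_rng(10).standard_normal((4, 5))
        lam = 0.25
        assert loss(m, X, lam) == loss(m, X, 0.0) + lam * m.weight_norm_sq()

    def test_nonnegative(self):
        m = init_model(5, (3, 2), seed=11)
        X = np.random.default_rng(11).standard_normal((4, 5))
        assert loss(m, X, 1e-4) >= 0


class TestGradients:
    def grad_check(self, model, X, lam, eps=1e-6):
        gW_e, gb_e, gW_d, gb_d = loss_gradients(model, X, lam)
        analytic = [*gW_e, *gb_e, *gW_d, *gb_d]
        max_rel = 0.0
        for p, g in zip(model.parameters(), analytic):
            flat = p.ravel()
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss(model, X, lam)
                flat[idx] = orig - eps
                lm = loss(model, X, lam)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(g.ravel()[idx]), 1e-8)
                max_rel = max(max_rel, abs(num - g.ravel()[idx]) / denom)
        return max_rel

    def test_central_difference_4_2_1_toy(self):
        m = init_model(4, (2, 1), seed=3)
        rng = np.random.default_rng(3)
        for b in m.enc_b + m.dec_b:
            b[:] = rng.standard_normal(b.shape) * 0.3
        X = rng.standard_normal((6, 4))
        assert self.grad_check(m, X, lam=1e-3) < 1e-5

    def test_central_difference_linear_bottleneck(self):
        m = init_model(4, (2, 1), seed=4, linear_bottleneck=True)
        rng = np.random.default_rng(4)
        for b in m.enc_b + m.dec_b:  # keep pre-activations off the ReLU kink
            b[:] = rng.standard_normal(b.shape) * 0.3
        X = rng.standard_normal((5, 4))
        assert self.grad_check(m, X, lam=0.01) < 1e-5


class TestTrain:
    def make_lowrank(self, n=60, d=12, rank=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, rank)) @ rng.standard_normal((rank, d))
        X += 0.1 * rng.standard_normal((n, d))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        return X

    def test_loss_decreases(self):
        X = self.make_lowrank()
        m = init_model(12, (8, 4), seed=0)
        _, hist = train(m, X, TrainingConfig(epochs=30, batch_size=16, seed=0,
                                             learning_rate=3e-3))
        assert hist[-1] < hist[0]
        assert m.trained

    def test_same_seed_identical_history(self):
        X = self.make_lowrank()
        cfg = TrainingConfig(epochs=10, batch_size=16, seed=5, learning_rate=3e-3)
        _, h1 = train(init_model(12, (8, 4), seed=5), X, cfg)
        _, h2 = train(init_model(12, (8, 4), seed=5), X, cfg)
        assert h1 == h2

    def test_regularization_shrinks_weights(self):
        X = self.make_lowrank(seed=2)
        cfg_small = TrainingConfig(epochs=50, batch_size=16, seed=2,
                                   learning_rate=3e-3, lambda_reg=1e-4)
        cfg_large = TrainingConfig(epochs=50, batch_size=16, seed=2,
                                   learning_rate=3e-3, lambda_reg=0.5)
        m_small, _ = train(init_model(12, (8, 4), seed=2), X, cfg_small)
        m_large, _ = train(init_model(12, (8, 4), seed=2), X, cfg_large)
        assert m_small.weight_norm_sq() > m_large.weight_norm_sq()

    def test_divergence_raises_with_advice(self):
        X = self.make_lowrank()
        m = init_model(12, (8, 4), seed=0)
        with pytest.raises(TrainingDivergedError, match="learning rate"):
            train(m, X, TrainingConfig(epochs=50, batch_size=16, seed=0,
                                       learning_rate=50.0))

    def test_batch_size_larger_than_n_rejected(self):
        X = self.make_lowrank(n=10)
        m = init_model(12, (8, 4), seed=0)
        with pytest.raises(ValueError, match="batch_size"):
            train(m, X, TrainingConfig(epochs=1, batch_size=32, seed=0))

    def test_planted_lowrank_r2(self):
        X = self.make_lowrank(n=120, d=30, rank=3, seed=7)
        m = init_model(30, (16, 8), seed=7)
        _, hist = train(m, X, TrainingConfig(epochs=150, batch_size=16, seed=7,
                                             learning_rate=2e-3))
        assert reconstruction_r2(m, X) >= 0.3

    def test_trained_beats_untrained_across_seeds(self):
        for seed in range(5):
            X = self.make_lowrank(n=80, d=20, rank=3, seed=seed)
            untrained = init_model(20, (10, 5), seed=seed)
            untrained.trained = True
            trained = init_model(20, (10, 5), seed=seed)
            train(trained, X, TrainingConfig(epochs=60, batch_size=16, seed=seed,
                                             learning_rate=2e-3))
            assert reconstruction_r2(trained, X) >= reconstruction_r2(untrained, X)


class TestEncode:
    def test_untrained_error(self):
        m = init_model(6, (4, 2), seed=0)
        with pytest.raises(RuntimeError, match="train"):
            encode(m, np.ones((2, 6)))

    def test_width_and_finiteness(self):
        X = TestTrain().make_lowrank()
        m = init_model(12, (8, 4), seed=1)
        train(m, X, TrainingConfig(epochs=5, batch_size=16, seed=1,
                                   learning_rate=1e-3))
        F = encode(m, X)
        assert F.shape == (60, 4)
        assert np.all(np.isfinite(F))
        assert np.all(F >= 0)  # ReLU bottleneck

    def test_row_separable(self):
        X = TestTrain().make_lowrank()
        m = init_model(12, (8, 4), seed=1)
        train(m, X, TrainingConfig(epochs=3, batch_size=16, seed=1,
                                   learning_rate=1e-3))
        F = encode(m, X)
        rows = np.vstack([encode(m, X[i : i + 1]) for i in range(len(X))])
        # batched and per-row BLAS paths differ only by summation order
        np.testing.assert_allclose(F, rows, atol=1e-12)


class TestReconstructionR2:
    def test_perfect_reconstruction(self, monkeypatch):
        m = init_model(4, (2, 1), seed=0)
        m.trained = True
        X = np.random.default_rng(0).standard_normal((5, 4))
        monkeypatch.setattr(ae, "forward", lambda model, x: (None, np.array(x)))
        assert reconstruction_r2(m, X) == pytest.approx(1.0)

    def test_zero_model_on_centered_data(self):
        m = zero_model(d_in=4, hidden=(2,))
        m.trained = True
        X = np.random.default_rng(1).standard_normal((50, 4))
        X -= X.mean()
        assert reconstruction_r2(m, X) == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self):
        m = init_model(5, (3, 2), seed=2)
        m.trained = True
        X = np.random.default_rng(2).standard_normal((6, 5))
        _, Xhat = forward(m, X)
        expected = 1 - ((X - Xhat) ** 2).sum() / ((X - X.mean()) ** 2).sum()
        assert reconstruction_r2(m, X) == pytest.approx(expected, rel=1e-12)

    def test_constant_input_error(self):
        m = zero_model()
        m.trained = True
        with pytest.raises(ValueError, match="constant"):
            reconstruction_r2(m, np.ones((4, 3)))
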