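import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosefm.hofm import (HOFMModel, TrainingConfig, anova_kernel, fit,
                         generalized_inner_product, gradient, load_model,
                         objective, predict, predict_brute_force, save_model)


def random_model(rng, d, m, k):
    return HOFMModel(m=m, k=k, w=rng.normal(size=d),
                     P={t: rng.normal(size=(d, k)) for t in range(2, m + 1)})


class TestGeneralizedInnerProduct:
    def test_three_vector_hand_example(self):
        assert generalized_inner_product([(1, 2), (3, 4), (5, 6)]) == 63.0

    def test_two_vectors_is_dot_product(self):
        a, b = np.array([1.0, -2.0, 0.5]), np.array([3.0, 1.0, 4.0])
        assert generalized_inner_product([a, b]) == pytest.approx(a @ b)

    def test_zero_vector_annihilates(self):
        assert generalized_inner_product([(1, 2), (0, 0), (5, 6)]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generalized_inner_product([(1, 2), (1, 2, 3)])


class TestAnovaKernel:
    def test_degree_two_hand_example(self):
        # only the pair {1, 2} survives the zero in x
        assert anova_kernel([1, 2, 3], [1, 1, 0], 2) == 2.0

    def test_degree_one_is_dot_product(self):
        p, x = np.array([1.0, 2.0, 3.0]), np.array([0.5, 1.0, -1.0])
        assert anova_kernel(p, x, 1) == pytest.approx(p @ x)

    def test_degree_above_support_is_zero(self):
        assert anova_kernel([1, 2, 3], [1, 1, 0], 3) == 0.0

    def test_invalid_degree_rejected(self):
        with pytest.raises(ValueError):
            anova_kernel([1.0], [1.0], 0)

    @pytest.mark.parametrize("t", [1, 2, 3])
    def test_multilinearity_in_p(self, t):
        """Doubling p scales a degree-t kernel of one-hot x by 2^t."""
        rng = np.random.default_rng(5)
        p = rng.normal(size=8)
        x = np.zeros(8)
        x[[1, 4, 6]] = 1.0
        assert anova_kernel(2 * p, x, t) == pytest.approx(2 ** t * anova_kernel(p, x, t))


class TestPredict:
    def test_hand_example_order_two(self):
        model = HOFMModel(m=2, k=1, w=np.array([0.5, 0.0, 0.0]),
                          P={2: np.array([[1.0], [2.0], [3.0]])})
        assert predict(model, np.array([1.0, 1.0, 0.0])) == pytest.approx(2.5)

    def test_zero_model_predicts_zero(self):
        model = HOFMModel(m=3, k=2, w=np.zeros(5),
                          P={t: np.zeros((5, 2)) for t in (2, 3)})
        assert predict(model, np.ones(5)) == 0.0

    def test_order_one_is_linear(self):
        rng = np.random.default_rng(1)
        model = HOFMModel(m=1, k=1, w=rng.normal(size=6), P={})
        x = rng.normal(size=6)
        assert predict(model, x) == pytest.approx(model.w @ x)

    def test_dimension_mismatch_rejected(self):
        model = HOFMModel(m=1, k=1, w=np.zeros(4), P={})
        with pytest.raises(ValueError):
            predict(model, np.ones(5))

    def test_oracle_equivalence_100_draws(self):
        """Fast prediction equals exhaustive enumeration of Eq-style sums."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            d = int(rng.integers(3, 13))
            m = int(rng.integers(1, 6))
            k = int(rng.integers(1, 4))
            model = random_model(rng, d, m, k)
            x = rng.normal(size=d) * (rng.random(d) < 0.6)
            fast = predict(model, x)
            slow = predict_brute_force(model, x)
            assert abs(fast - slow) <= 1e-8 * (1 + abs(slow))

    def test_brute_force_guard(self):
        rng = np.random.default_rng(0)
        model = random_model(rng, 25, 2, 1)
        with pytest.raises(ValueError):
            predict_brute_force(model, np.ones(25))


class TestObjectiveAndGradient:
    def test_perfect_model_zero_loss(self):
        model = HOFMModel(m=1, k=1, w=np.array([2.0, 0.0]), P={})
        X = np.array([[1.0, 0.0], [2.0, 0.0]])
        y = np.array([2.0, 4.0])
        assert objective(model, X, y, TrainingConfig(beta=0.0)) == 0.0

    def test_zero_model_gives_mean_square(self):
        model = HOFMModel(m=2, k=1, w=np.zeros(3), P={2: np.zeros((3, 1))})
        X = np.ones((4, 3))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert objective(model, X, y, TrainingConfig(beta=0.0)) == \
            pytest.approx(np.mean(y ** 2))

    def test_penalty_hand_sum(self):
        w = np.array([1.0, 2.0])
        P2 = np.array([[1.0], [1.0]])
        model = HOFMModel(m=2, k=1, w=w, P={2: P2})
        X = np.array([[0.0, 0.0]])
        y = np.array([0.0])
        cfg = TrainingConfig(beta=2.0)
        # residual 0, penalty = (2/2)*(1+4) + (2/2)*(1+1) = 7
        assert objective(model, X, y, cfg) == pytest.approx(7.0)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(77)
        model = random_model(rng, 6, 4, 2)
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        cfg = TrainingConfig(beta=0.7)
        gw, gP = gradient(model, X, y, cfg)
        h = 1e-5

        def fd(setter):
            setter(h)
            up = objective(model, X, y, cfg)
            setter(-2 * h)
            down = objective(model, X, y, cfg)
            setter(h)
            return (up - down) / (2 * h)

        for i in range(model.d):
            num = fd(lambda eps, i=i: model.w.__setitem__(i, model.w[i] + eps))
            assert abs(num - gw[i]) <= 1e-5 * (1 + abs(gw[i]))
        for t in range(2, model.m + 1):
            for i in range(model.d):
                for s in range(model.k):
                    num = fd(lambda eps, t=t, i=i, s=s:
                             model.P[t].__setitem__((i, s), model.P[t][i, s] + eps))
                    assert abs(num - gP[t][i, s]) <= 1e-5 * (1 + abs(gP[t][i, s]))

    def test_zero_residual_zero_beta_is_stationary(self):
        model = HOFMModel(m=1, k=1, w=np.array([1.0, 1.0]), P={})
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([1.0, 1.0])
        gw, _ = gradient(model, X, y, TrainingConfig(beta=0.0))
        np.testing.assert_allclose(gw, 0.0, atol=1e-12)

    def test_penalty_only_gradient_is_beta_times_param(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, 4, 2, 2)
        X = np.zeros((2, 4))
        y = np.zeros(2)
        cfg = TrainingConfig(beta=1.3)
        gw, gP = gradient(model, X, y, cfg)
        np.testing.assert_allclose(gw, cfg.beta * model.w)
        np.testing.assert_allclose(gP[2], cfg.beta * model.P[2])


def _low_rank_training_data(rng, n=600, d=12, m=3, k=2, noise_sd=5.0):
    """Data generated by a random order-3 rank-2 HOFM plus noise."""
    truth = random_model(rng, d, m, k)
    X = (rng.random((n, d)) < 0.4).astype(float)
    y = predict(truth, X) + rng.normal(0, noise_sd, size=n)
    return X, y, truth


class TestFit:
    CFG = TrainingConfig(beta=1e-3, learning_rate=0.05, epochs=150,
                         batch_size=128, seed=0)

    def test_recovers_low_rank_signal(self):
        rng = np.random.default_rng(10)
        X, y, truth = _low_rank_training_data(rng)
        Xte = (rng.random((200, 12)) < 0.4).astype(float)
        yte = predict(truth, Xte) + rng.normal(0, 5.0, size=200)
        model = fit(X, y, 3, 2, self.CFG)
        rmse = np.sqrt(np.mean((predict(model, Xte) - yte) ** 2))
        assert rmse <= 1.5 * 5.0

    def test_higher_order_beats_linear(self):
        rng = np.random.default_rng(10)
        X, y, truth = _low_rank_training_data(rng)
        Xte = (rng.random((200, 12)) < 0.4).astype(float)
        yte = predict(truth, Xte) + rng.normal(0, 5.0, size=200)
        m3 = fit(X, y, 3, 2, self.CFG)
        m1 = fit(X, y, 1, 1, self.CFG)
        rmse3 = np.sqrt(np.mean((predict(m3, Xte) - yte) ** 2))
        rmse1 = np.sqrt(np.mean((predict(m1, Xte) - yte) ** 2))
        assert rmse1 > rmse3

    def test_same_seed_identical_traces(self):
        rng = np.random.default_rng(11)
        X, y, _ = _low_rank_training_data(rng, n=200)
        cfg = TrainingConfig(beta=0.0, learning_rate=0.01, epochs=20,
                             batch_size=64, seed=5)
        a = fit(X, y, 2, 2, cfg)
        b = fit(X, y, 2, 2, cfg)
        assert a.loss_trace_ == b.loss_trace_
        np.testing.assert_array_equal(a.w, b.w)

    def test_loss_decreases_overall(self):
        rng = np.random.default_rng(12)
        X, y, _ = _low_rank_training_data(rng, n=300)
        cfg = TrainingConfig(beta=0.0, learning_rate=0.02, epochs=120,
                             batch_size=64, seed=1)
        model = fit(X, y, 2, 2, cfg)
        trace = np.array(model.loss_trace_)
        # monotone trend allowing mini-batch jitter
        assert trace[-6:].mean() < 0.75 * trace[:6].mean()
        assert trace[-1] < trace[0]

    def test_capacity_never_hurts_training_fit(self):
        """On noiseless representable data, larger m or k attains a
        training loss at least as good (non-inferiority)."""
        rng = np.random.default_rng(13)
        X, y, _ = _low_rank_training_data(rng, n=300, noise_sd=0.0)
        cfg = TrainingConfig(beta=0.0, learning_rate=0.05, epochs=200,
                             batch_size=128, seed=2)
        base = fit(X, y, 3, 2, cfg).loss_trace_[-1]
        wider = fit(X, y, 3, 4, cfg).loss_trace_[-1]
        deeper = fit(X, y, 4, 2, cfg).loss_trace_[-1]
        assert wider <= base * 1.1
        assert deeper <= base * 1.1

    def test_asymmetric_training_set_warns(self, toy_dataset):
        from dosefm.encoding import encode_measurements, fit_layout
        layout = fit_layout(toy_dataset)
        X = encode_measurements(toy_dataset.measurements, layout)
        y = np.array([m.response for m in toy_dataset.measurements])
        with pytest.warns(UserWarning, match="asymmetric"):
            fit(X, y, 1, 1, TrainingConfig(epochs=1, beta=0.0, learning_rate=0.01),
                layout=layout)


class TestPredictSymmetric:
    def test_orientation_invariant(self, toy_dataset):
        from dosefm.encoding import fit_layout
        from dosefm.hofm import predict_symmetric
        rng = np.random.default_rng(4)
        layout = fit_layout(toy_dataset)
        model = random_model(rng, layout.d, 2, 2)
        m = toy_dataset.measurements[0]
        assert predict_symmetric(model, m, layout) == \
            pytest.approx(predict_symmetric(model, m.swapped(), layout))

    def test_mean_of_two_orientations(self, toy_dataset):
        from dosefm.encoding import encode, fit_layout
        from dosefm.hofm import predict_symmetric
        rng = np.random.default_rng(5)
        layout = fit_layout(toy_dataset)
        model = random_model(rng, layout.d, 2, 2)
        m = toy_dataset.measurements[0]
        a = predict(model, encode(m, layout))
        b = predict(model, encode(m.swapped(), layout))
        assert predict_symmetric(model, m, layout) == pytest.approx((a + b) / 2)


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        model = random_model(rng, 7, 3, 2)
        model.loss_trace_ = [3.0, 2.0, 1.0]
        path = tmp_path / "model.npz"
        save_model(model, path, config=TrainingConfig())
        loaded, manifest = load_model(path)
        np.testing.assert_array_equal(loaded.w, model.w)
        for t in (2, 3):
            np.testing.assert_array_equal(loaded.P[t], model.P[t])
        assert loaded.loss_trace_ == model.loss_trace_
        x = rng.normal(size=7)
        assert predict(loaded, x) == pytest.approx(predict(model, x))
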