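"""Linear and LSTM COP regressors: oracles, determinism, calibration."""

import numpy as np
import pytest

from copgait import _lstm
from copgait.dataset import ChannelSpec
from copgait.evaluation import evaluate_intra_subject, rms_error
from copgait.models import (
    LSTMCOP,
    LinearCOP,
    TrainConfig,
    fine_tune,
    fit_linear,
    fit_lstm,
    load_results,
)
from copgait.synthetic import GaitParams, ProtocolStep, simulate_linear_session


class TestLinear:
    def test_zero_target_gives_zero_solution(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 4))
        res = fit_linear(X, np.zeros((30, 2)))
        np.testing.assert_allclose(res.weights, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.intercept, 0.0, atol=1e-12)
        assert res.train_mse < 1e-24

    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 6))
        W_true = rng.standard_normal((6, 2))
        c_true = np.array([3.0, -1.5])
        res = fit_linear(X, X @ W_true + c_true)
        np.testing.assert_allclose(res.weights, W_true, atol=1e-8)
        np.testing.assert_allclose(res.intercept, c_true, atol=1e-8)

    def test_rank_deficient_matches_pseudoinverse(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        Y = rng.standard_normal((40, 2))
        res = fit_linear(X, Y)
        Xa = np.hstack([X, np.ones((40, 1))])
        coef = np.linalg.pinv(Xa) @ Y
        np.testing.assert_allclose(
            np.vstack([res.weights, res.intercept]), coef, atol=1e-8
        )
        np.testing.assert_allclose(res.predict(X), Xa @ coef, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(15, 50), rng.integers(2, 10)
        X = rng.standard_normal((int(n), int(p)))
        Y = rng.standard_normal((int(n), 2))
        res = fit_linear(X, Y)
        Xa = np.hstack([X, np.ones((int(n), 1))])
        coef = np.linalg.solve(Xa.T @ Xa, Xa.T @ Y)
        np.testing.assert_allclose(
            np.vstack([res.weights, res.intercept]), coef, atol=1e-8
        )

    def test_predict_toy_case_by_hand(self):
        res = fit_linear(np.array([[1.0], [2.0], [3.0]]), np.array([[2.0, -1], [4, -2], [6, -3]]))
        X = np.array([[10.0], [0.0], [-1.0]])
        np.testing.assert_allclose(res.predict(X), [[20, -10], [0, 0], [-2, 1]], atol=1e-9)
        # zero input rows return the intercept
        np.testing.assert_allclose(res.predict(np.zeros((2, 1))), np.tile(res.intercept, (2, 1)))

    def test_shape_errors(self):
        with pytest.raises(ValueError, match="row counts"):
            LinearCOP(np.zeros((3, 2)), np.zeros((4, 2)))
        with pytest.raises(ValueError, match="finite"):
            LinearCOP(np.array([[np.nan]]), np.zeros((1, 2)))
        res = fit_linear(np.zeros((3, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError, match="columns"):
            res.predict(np.zeros((3, 5)))


class TestLstmCell:
    def test_forward_matches_manual_recurrence(self):
        """One hidden unit, two time steps, fixed weights, scalar arithmetic."""
        params = _lstm.LstmParams(
            {
                "Wx": np.array([[0.5, -0.3, 0.8, 0.2]]),  # gates: i, f, g, o
                "Wh": np.array([[0.1, 0.4, -0.2, 0.3]]),
                "b": np.array([0.05, 1.0, -0.1, 0.2]),
                "Wo": np.array([[1.5, -0.7]]),
                "bo": np.array([0.1, -0.2]),
            }
        )
        x = np.array([[[0.4], [-0.6]]])  # (B=1, T=2, d=1)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        h = c = 0.0
        for t in range(2):
            xt = x[0, t, 0]
            i = sig(0.5 * xt + 0.1 * h + 0.05)
            f = sig(-0.3 * xt + 0.4 * h + 1.0)
            g = np.tanh(0.8 * xt - 0.2 * h - 0.1)
            o = sig(0.2 * xt + 0.3 * h + 0.2)
            c = f * c + i * g
            h = o * np.tanh(c)
        expected = np.array([[1.5 * h + 0.1, -0.7 * h - 0.2]])
        np.testing.assert_allclose(_lstm.forward(params, x), expected, atol=1e-12)

    def test_backward_matches_numerical_gradient(self):
        rng = np.random.default_rng(3)
        params = _lstm.init_params(d=3, hidden=4, rng=rng)
        X = rng.standard_normal((5, 4, 3))
        Y = rng.standard_normal((5, 2))

        def loss(p):
            return float(np.mean((_lstm.forward(p, X) - Y) ** 2))

        pred, cache = _lstm.forward(params, X, cache=True)
        grads = _lstm.backward(params, cache, 2.0 * (pred - Y) / pred.size)
        eps = 1e-6
        for key in ("Wx", "Wh", "b", "Wo", "bo"):
            flat = params[key].ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss(params)
                flat[idx] = orig - eps
                down = loss(params)
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                assert abs(num - grads[key].ravel()[idx]) < 1e-6


class TestLstmModel:
    @staticmethod
    def _toy_data(n=400, seed=0):
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((n, 10, 3))
        phase = W[:, -1, 0]
        Y = np.column_stack([30 * np.tanh(2 * phase), 10 * phase**2 - 5])
        return W, Y

    def test_output_count_and_order_independence(self):
        W, Y = self._toy_data()
        res = fit_lstm(W, Y, TrainConfig(max_epochs=3, seed=0))
        pred = res.predict(W)
        assert pred.shape == (W.shape[0], 2)
        perm = np.random.default_rng(1).permutation(W.shape[0])
        np.testing.assert_allclose(res.predict(W[perm]), pred[perm], atol=1e-12)

    def test_seeded_training_is_bit_reproducible(self):
        W, Y = self._toy_data()
        cfg = TrainConfig(max_epochs=5, seed=11)
        r1 = fit_lstm(W, Y, cfg)
        r2 = fit_lstm(W, Y, cfg)
        assert r1.loss_trace == r2.loss_trace
        for k in r1.params:
            np.testing.assert_array_equal(r1.params[k], r2.params[k])

    def test_constant_target_is_learned(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((300, 10, 2))
        const = np.tile([12.0, -7.0], (300, 1))
        res = fit_lstm(W, const, TrainConfig(max_epochs=30, patience=5, seed=0))
        pred = res.predict(W)
        _, Y_control = self._toy_data()
        assert np.sqrt(np.mean((pred - const) ** 2)) <= 0.05 * Y_control.std()

    def test_best_weights_achieve_min_of_trace(self):
        W, Y = self._toy_data()
        res = fit_lstm(W, Y, TrainConfig(max_epochs=15, seed=2))
        assert res.loss_trace[-1] >= min(res.loss_trace) - 1e-15
        assert res.loss_trace[0] >= min(res.loss_trace)

    def test_shape_validation(self):
        W, Y = self._toy_data()
        res = fit_lstm(W, Y, TrainConfig(max_epochs=2, seed=0))
        with pytest.raises(ValueError, match="windows"):
            res.predict(np.zeros((4, 10, 99)))
        with pytest.raises(ValueError):
            LSTMCOP(np.zeros((0, 10, 3)), np.zeros((0, 2)))


class TestLstmOnLinearTruthSession:
    def test_lstm_approaches_noise_floor_on_linear_data(self):
        """On a session whose COP is linear in the raw channels, the LSTM
        reaches near-noise-floor absolute accuracy (≤ 2% of the target sd)
        and stays within a factor 2 of the exactly-matched linear fit."""
        session, _ = simulate_linear_session(
            GaitParams(seed=9), [ProtocolStep(0.5, 0, 60.0, "walk")]
        )
        spec = ChannelSpec(history=10)
        lin = evaluate_intra_subject(session, "linear", spec)
        cfg = TrainConfig(max_epochs=120, patience=15, seed=0)
        net = evaluate_intra_subject(session, "lstm", spec, cfg)
        target_sd = np.std(session.cop.as_array())
        assert net.total <= 0.02 * target_sd
        assert net.total <= 2.0 * lin.total


class TestFineTune:
    def test_empty_calibration_returns_model_unchanged(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 4))
        Y = rng.standard_normal((50, 2))
        res = fit_linear(X, Y)
        assert fine_tune(res, np.zeros((0, 4)), np.zeros((0, 2))) is res

    def test_linear_calibration_pulls_towards_calibration_targets(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((500, 3))
        Y = X @ rng.standard_normal((3, 2))
        res = fit_linear(X, Y)
        offset = np.array([8.0, -4.0])
        calib_X = rng.standard_normal((100, 3)) * 0.05
        calib_Y = calib_X @ np.zeros((3, 2)) + offset
        tuned = fine_tune(res, calib_X, calib_Y)
        err_before = rms_error(res.predict(calib_X), calib_Y).total
        err_after = rms_error(tuned.predict(calib_X), calib_Y).total
        assert err_after < err_before

    def test_lstm_calibration_never_worse_on_tuned_set(self):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((200, 10, 3))
        Y = np.column_stack([20 * W[:, -1, 0], -15 * W[:, -1, 1]])
        res = fit_lstm(W, Y, TrainConfig(max_epochs=5, seed=0))
        calib_W = rng.standard_normal((60, 10, 3)) * 0.1
        calib_Y = np.tile([5.0, 2.0], (60, 1))
        tuned = fine_tune(res, calib_W, calib_Y)
        before = np.sqrt(np.mean((res.predict(calib_W) - calib_Y) ** 2))
        after = np.sqrt(np.mean((tuned.predict(calib_W) - calib_Y) ** 2))
        assert after <= before + 1e-6

    def test_layout_mismatch_rejected(self):
        res = fit_linear(np.zeros((5, 3)), np.zeros((5, 2)))
        with pytest.raises(ValueError, match="layout"):
            fine_tune(res, np.zeros((4, 7)), np.zeros((4, 2)))


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    X = rng.standard_normal((60, 4))
    Y = rng.standard_normal((60, 2))
    lin = fit_linear(X, Y)
    lin.save(tmp_path / "lin.npz")
    lin2 = load_results(tmp_path / "lin.npz")
    np.testing.assert_array_equal(lin.weights, lin2.weights)
    np.testing.assert_array_equal(lin.intercept, lin2.intercept)

    W = rng.standard_normal((50, 10, 3))
    net = fit_lstm(W, Y[:50], TrainConfig(max_epochs=2, seed=0))
    net.save(tmp_path / "net.npz")
    net2 = load_results(tmp_path / "net.npz")
    np.testing.assert_array_equal(net.predict(W), net2.predict(W))
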