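"""Backpropagation network: forward pass, delta rule, training dynamics."""

import numpy as np
import pytest

from dvhpredict.network import (
    NetworkParams,
    TrainConfig,
    delta_errors,
    forward,
    forward_batch,
    load_model,
    mse,
    predict,
    save_model,
    train,
    update_step,
)
from dvhpredict.preprocessing import ScalingParams


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def numerical_gradient(params, x, target, h=1e-5):
    """Central-difference gradient of E = 1/2 sum (y - yhat)^2 in flat layout."""
    flat = params.flatten()
    grad = np.empty_like(flat)
    for i in range(len(flat)):
        for sign, store in ((+1, "plus"), (-1, "minus")):
            pert = flat.copy()
            pert[i] += sign * h
            _, out = forward(NetworkParams.unflatten(pert), x)
            e = 0.5 * np.sum((target - out) ** 2)
            if sign > 0:
                e_plus = e
            else:
                e_minus = e
        grad[i] = (e_plus - e_minus) / (2 * h)
    return grad


def analytic_gradient(params, x, target):
    """Gradient assembled from the delta rule, in the same flat layout."""
    hidden, output = forward(params, x)
    d_out, d_hid = delta_errors(params, hidden, output, target)
    g_w_ih = -np.outer(np.asarray(x), d_hid)
    g_b_h = d_hid
    g_w_ho = -np.outer(hidden, d_out)
    g_b_o = d_out
    return np.concatenate([g_w_ih.ravel(), g_b_h, g_w_ho.ravel(), g_b_o])


class TestForward:
    def test_zero_parameters_give_half_everywhere(self):
        params = NetworkParams.zeros()
        hidden, output = forward(params, np.array([0.3, 0.9, 0.1]))
        np.testing.assert_allclose(hidden, 0.5)
        np.testing.assert_allclose(output, 0.5)

    def test_hand_computed_single_path(self):
        # route everything through hidden unit 0 and output unit 0
        params = NetworkParams.zeros()
        params.w_ih[:, 0] = [1.0, 2.0, -1.0]
        params.b_h[0] = 0.5
        params.w_ho[0, 0] = 2.0
        params.b_o[0] = -0.25
        x = np.array([0.2, 0.4, 0.6])
        h0 = sigmoid(0.2 + 0.8 - 0.6 - 0.5)
        # output 0 sees only hidden unit 0 (all other hidden->output weights are 0)
        hidden, output = forward(params, x)
        assert hidden[0] == pytest.approx(h0, rel=1e-12)
        assert output[0] == pytest.approx(sigmoid(2.0 * h0 + 0.25), rel=1e-12)

    def test_activations_strictly_inside_unit_interval(self, rng):
        params = NetworkParams.random(rng)
        out = forward_batch(params, rng.uniform(0, 1, (50, 3)))
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(
                w_ih=np.full((3, 6), np.nan), b_h=np.zeros(6),
                w_ho=np.zeros((6, 4)), b_o=np.zeros(4),
            )


class TestDeltaErrors:
    def test_zero_error_gives_zero_deltas(self):
        params = NetworkParams.random(0)
        hidden, output = forward(params, np.array([0.2, 0.5, 0.8]))
        d_out, d_hid = delta_errors(params, hidden, output, output.copy())
        np.testing.assert_allclose(d_out, 0.0)
        np.testing.assert_allclose(d_hid, 0.0)

    def test_hand_example_half_activation_unit_target(self):
        # yhat = 0.5, y = 1.0 -> delta = 0.5*0.5*0.5 = 0.125
        params = NetworkParams.zeros()
        hidden, output = forward(params, np.zeros(3))
        d_out, _ = delta_errors(params, hidden, output, np.ones(4))
        np.testing.assert_allclose(d_out, 0.125)

    def test_deltas_equal_negative_net_input_gradient(self, rng):
        """Core correctness oracle: delta rule vs central finite differences."""
        for _ in range(10):
            params = NetworkParams.random(rng)
            x = rng.uniform(0, 1, 3)
            target = rng.uniform(0.1, 0.9, 4)
            np.testing.assert_allclose(
                analytic_gradient(params, x, target),
                numerical_gradient(params, x, target),
                atol=1e-6,
            )

    def test_dimension_mismatch_rejected(self):
        params = NetworkParams.zeros()
        with pytest.raises(ValueError):
            delta_errors(params, np.zeros(6), np.zeros(4), np.zeros(3))


class TestUpdateStep:
    def test_zero_deltas_are_a_fixed_point(self):
        params = NetworkParams.random(3)
        x = np.array([0.2, 0.5, 0.8])
        _, output = forward(params, x)
        updated = update_step(params, x, output.copy(), eta=0.1)
        np.testing.assert_allclose(updated.flatten(), params.flatten(), atol=1e-12)

    def test_hand_worked_single_unit_slice(self):
        # 1-1-1 slice: only w_ih[0,0], b_h[0], w_ho[0,0], b_o[0] participate
        params = NetworkParams.zeros()
        x = np.array([1.0, 0.0, 0.0])
        target = np.array([1.0, 0.5, 0.5, 0.5])
        eta = 0.5
        hidden, output = forward(params, x)  # all 0.5
        delta0 = 0.5 * 0.5 * (1.0 - 0.5)  # 0.125 on output 0
        dh = 0.5 * 0.5 * (0.0 * delta0)  # zero weights -> zero hidden delta
        updated = update_step(params, x, target, eta)
        assert updated.w_ho[0, 0] == pytest.approx(eta * delta0 * 0.5)
        assert updated.b_o[0] == pytest.approx(-eta * delta0)
        assert updated.w_ih[0, 0] == pytest.approx(eta * dh * 1.0)

    def test_small_eta_reduces_error_on_seen_sample(self, rng):
        for _ in range(20):
            params = NetworkParams.random(rng)
            x = rng.uniform(0, 1, 3)
            target = rng.uniform(0.1, 0.9, 4)
            _, before = forward(params, x)
            updated = update_step(params, x, target, eta=1e-3)
            _, after = forward(updated, x)
            assert np.sum((target - after) ** 2) <= np.sum((target - before) ** 2)


class TestTrain:
    def test_single_pair_converges_to_target(self):
        X = np.array([[0.3, 0.6, 0.2]])
        Y = np.array([[0.4, 0.6, 0.3, 0.7]])
        cfg = TrainConfig(eta=0.5, target_error=1e-5, max_epochs=5000, shuffle_seed=0)
        params, state = train(NetworkParams.random(1), X, Y, cfg)
        assert state.converged
        assert state.epoch_mse[-1] <= cfg.target_error
        out = forward_batch(params, X)
        assert np.all(np.abs(out - Y) <= np.sqrt(4 * cfg.target_error))

    def test_huge_target_stops_after_one_epoch(self, retained_cohort):
        from dvhpredict.preprocessing import apply_scaler, fit_scaler

        X, Y = apply_scaler(retained_cohort, fit_scaler(retained_cohort))
        params, state = train(
            NetworkParams.random(0), X, Y, TrainConfig(target_error=1e6, max_epochs=50)
        )
        assert state.t == 1 and state.converged

    def test_deterministic_given_seeds(self, retained_cohort):
        from dvhpredict.preprocessing import apply_scaler, fit_scaler

        X, Y = apply_scaler(retained_cohort, fit_scaler(retained_cohort))
        cfg = TrainConfig(max_epochs=20, shuffle_seed=5)
        p1, s1 = train(NetworkParams.random(2), X, Y, cfg)
        p2, s2 = train(NetworkParams.random(2), X, Y, cfg)
        np.testing.assert_array_equal(p1.flatten(), p2.flatten())
        assert s1.epoch_mse == s2.epoch_mse

    def test_epoch_mse_mostly_non_increasing(self, retained_cohort):
        """Online updates allow small upticks; the trend must descend."""
        from dvhpredict.preprocessing import apply_scaler, fit_scaler

        X, Y = apply_scaler(retained_cohort, fit_scaler(retained_cohort))
        _, state = train(
            NetworkParams.random(0), X, Y, TrainConfig(max_epochs=150, shuffle_seed=0)
        )
        m = np.array(state.epoch_mse)
        increments = np.diff(m)
        # an uptick below 0.3% of the current error is reshuffling jitter of
        # the online pass, not divergence
        ok = increments <= 3e-3 * m[:-1]
        assert ok.mean() >= 0.95
        assert m[-1] < m[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(NetworkParams.zeros(), np.empty((0, 3)), np.empty((0, 4)), TrainConfig())


class TestPredictAndSerialization:
    def _scaler(self):
        return ScalingParams(
            feature_min=np.array([0.1, 0.4, 10.0]), feature_max=np.array([0.8, 0.9, 22.0])
        )

    def test_zero_network_predicts_fifty_percent(self):
        preds = predict(NetworkParams.zeros(), self._scaler(), np.array([[0.3, 0.6, 15.0]]))
        np.testing.assert_allclose(preds, 50.0)

    def test_converged_single_sample_fit_reproduces_outcomes(self):
        scaler = self._scaler()
        raw = np.array([[0.4, 0.7, 18.0]])
        target_pct = np.array([[62.0, 41.0, 18.0, 8.0]])
        x = (raw - scaler.feature_min) / (scaler.feature_max - scaler.feature_min)
        y = target_pct / 100.0
        params, state = train(
            NetworkParams.random(4), x, y, TrainConfig(eta=0.5, max_epochs=5000)
        )
        assert state.converged
        np.testing.assert_allclose(predict(params, scaler, raw), target_pct, atol=0.7)

    def test_flat_round_trip_and_length(self):
        params = NetworkParams.random(9)
        assert params.flat_length == 52
        again = NetworkParams.unflatten(params.flatten())
        np.testing.assert_array_equal(again.flatten(), params.flatten())

    def test_json_round_trip_is_bit_exact(self, tmp_path):
        params = NetworkParams.random(11)
        scaler = self._scaler()
        path = tmp_path / "model.json"
        save_model(params, scaler, path, seed=11)
        loaded, loaded_scaler, seed = load_model(path)
        np.testing.assert_array_equal(loaded.flatten(), params.flatten())
        np.testing.assert_array_equal(loaded_scaler.feature_min, scaler.feature_min)
        assert seed == 11
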