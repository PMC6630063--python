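"""LSTM cell and bidirectional architecture: oracle equivalence, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexflow.decoder import BRNNModel, DecoderConfig, UnidirectionalModel, MLPBaseline
from cortexflow.decoder import bidirectional_encode, classify
from cortexflow.nn import (
    GateActivations,
    LSTMParams,
    LSTMState,
    init_lstm_params,
    lstm_cell_step,
    lstm_forward_batch,
    run_direction,
)


def scalar_lstm_step(x, h_prev, c_prev, p: LSTMParams):
    """Independent scalar re-implementation of the gated update (the oracle)."""
    H = p.hidden_dim
    z = list(h_prev) + list(x)
    h_new, c_new = [], []
    for j in range(H):
        af = sum(p.W_f[j][i] * z[i] for i in range(len(z))) + p.b_f[j]
        ai = sum(p.W_i[j][i] * z[i] for i in range(len(z))) + p.b_i[j]
        ao = sum(p.W_o[j][i] * z[i] for i in range(len(z))) + p.b_o[j]
        ac = sum(p.W_c[j][i] * z[i] for i in range(len(z))) + p.b_c[j]
        f = 1.0 / (1.0 + math.exp(-af))
        i_ = 1.0 / (1.0 + math.exp(-ai))
        o = 1.0 / (1.0 + math.exp(-ao))
        g = math.tanh(ac)
        c = f * c_prev[j] + i_ * g
        c_new.append(c)
        h_new.append(o * math.tanh(c))
    return np.array(h_new), np.array(c_new)


def zero_params(H, K):
    shape = (H, H + K)
    return LSTMParams(
        W_f=np.zeros(shape), W_i=np.zeros(shape), W_o=np.zeros(shape),
        W_c=np.zeros(shape), b_f=np.zeros(H), b_i=np.zeros(H),
        b_o=np.zeros(H), b_c=np.zeros(H),
    )


class TestCellStep:
    def test_all_zero_weights_give_half_gates_and_zero_state(self):
        p = zero_params(3, 2)
        state, gates = lstm_cell_step(np.ones(2), LSTMState(np.zeros(3), np.zeros(3)), p)
        assert np.allclose(gates.f, 0.5) and np.allclose(gates.i, 0.5)
        assert np.allclose(gates.o, 0.5)
        assert np.allclose(state.c, 0.0) and np.allclose(state.h, 0.0)

    def test_saturated_gates_pass_memory_through(self):
        p = zero_params(2, 2)
        p.b_f[:] = 50.0  # forget gate -> 1
        p.b_i[:] = -50.0  # input gate -> 0
        c_prev = np.array([0.3, -0.7])
        state, _ = lstm_cell_step(
            np.array([1.0, -1.0]), LSTMState(np.zeros(2), c_prev), p
        )
        assert np.all(np.abs(state.c - c_prev) < 1e-6)

    def test_matches_scalar_oracle_on_random_cells(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            H = int(rng.integers(1, 5))
            K = int(rng.integers(1, 5))
            p = init_lstm_params(K, H, rng)
            x = rng.standard_normal(K)
            h0 = rng.uniform(-0.9, 0.9, H)
            c0 = rng.standard_normal(H)
            state, _ = lstm_cell_step(x, LSTMState(h0, c0), p)
            h_ref, c_ref = scalar_lstm_step(x, h0, c0, p)
            assert np.allclose(state.h, h_ref, atol=1e-10)
            assert np.allclose(state.c, c_ref, atol=1e-10)

    def test_non_finite_input_rejected(self):
        p = zero_params(2, 2)
        with pytest.raises(ValueError):
            lstm_cell_step(np.array([np.inf, 0.0]),
                           LSTMState(np.zeros(2), np.zeros(2)), p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_gate_and_state_bounds(self, seed):
        """Gates stay in (0,1); hidden states in (-1,1), on any input."""
        rng = np.random.default_rng(seed)
        p = init_lstm_params(3, 4, rng)
        state = LSTMState(np.zeros(4), np.zeros(4))
        for _ in range(5):
            state, gates = lstm_cell_step(rng.standard_normal(3) * 10, state, p)
            for g in (gates.f, gates.i, gates.o):
                assert np.all((g > 0) & (g < 1))
            assert np.all(np.abs(gates.candidate) < 1)
            assert np.all(np.abs(state.h) < 1)


class TestRunDirection:
    def test_zero_params_zero_state(self):
        seq = np.ones((5, 3))
        assert np.allclose(run_direction(seq, zero_params(2, 3)), 0.0)

    def test_backward_equals_forward_on_reversed(self):
        rng = np.random.default_rng(2)
        p = init_lstm_params(4, 3, rng)
        seq = rng.standard_normal((5, 4))
        assert np.allclose(
            run_direction(seq, p, "backward"),
            run_direction(seq[::-1], p, "forward"),
        )

    def test_length_one_is_single_step(self):
        rng = np.random.default_rng(3)
        p = init_lstm_params(3, 2, rng)
        x = rng.standard_normal((1, 3))
        state, _ = lstm_cell_step(x[0], LSTMState(np.zeros(2), np.zeros(2)), p)
        assert np.allclose(run_direction(x, p), state.h)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            run_direction(np.empty((0, 3)), zero_params(2, 3))

    def test_batched_forward_agrees_with_stepwise(self):
        rng = np.random.default_rng(4)
        p = init_lstm_params(4, 3, rng)
        X = rng.standard_normal((6, 5, 4))
        h_batch, _ = lstm_forward_batch(X, p, reverse=False)
        for b in range(6):
            assert np.allclose(h_batch[b], run_direction(X[b], p), atol=1e-12)


class TestBidirectionalArchitecture:
    def test_combined_feature_is_32d_at_default_width(self):
        model = BRNNModel(100, DecoderConfig())
        feat = bidirectional_encode(np.zeros((5, 100)), model)
        assert feat.shape == (32,)

    def test_both_halves_see_every_node(self):
        cfg = DecoderConfig(hidden_dim=4, seed=0)
        model = BRNNModel(6, cfg)
        rng = np.random.default_rng(0)
        seq = rng.standard_normal((5, 6))
        base = bidirectional_encode(seq, model)
        bumped = seq.copy()
        bumped[0] += 1.0  # perturb only the V1 node
        moved = bidirectional_encode(bumped, model)
        assert np.any(moved[:4] != base[:4])  # forward half
        assert np.any(moved[4:] != base[4:])  # backward half

    def test_per_direction_parameter_count(self):
        model = BRNNModel(100, DecoderConfig(hidden_dim=16))
        assert model.n_params_per_direction() == 4 * ((100 + 16) * 16 + 16) == 7488
        assert (model.forward_params.n_params()
                + model.backward_params.n_params()) == 14976

    def test_nn_baseline_parameter_count(self):
        model = MLPBaseline(500, DecoderConfig(hidden_dim=16, label_level="coarse"))
        assert model.n_params() == (500 * 64 + 64) + (64 * 32 + 32) + (32 * 5 + 5)

    def test_classify_softmax_properties(self):
        cfg = DecoderConfig(hidden_dim=4, seed=1)
        model = BRNNModel(6, cfg)
        probs = classify(np.random.default_rng(0).standard_normal(8), model)
        assert probs.shape == (5,)
        assert probs.min() >= 0
        assert abs(probs.sum() - 1.0) < 1e-9

    def test_zero_head_gives_uniform_probabilities(self):
        cfg = DecoderConfig(hidden_dim=4, seed=1)
        model = BRNNModel(6, cfg)
        model.head_W[:] = 0.0
        model.head_b[:] = 0.0
        probs = classify(np.ones(8), model)
        assert np.allclose(probs, 0.2)


class TestGradients:
    def _numeric_check(self, model, X, y, rng, n_probes=20, eps=1e-6):
        _, grads = model.loss_and_grads(X, y, None)
        params = model.params()
        names = list(params)
        worst = 0.0
        for _ in range(n_probes):
            name = names[rng.integers(len(names))]
            arr = params[name]
            ij = tuple(rng.integers(s) for s in arr.shape)
            orig = arr[ij]
            arr[ij] = orig + eps
            lp, _ = model.loss_and_grads(X, y, None)
            arr[ij] = orig - eps
            lm, _ = model.loss_and_grads(X, y, None)
            arr[ij] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[name][ij]
            worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
        return worst

    def test_brnn_gradient_matches_finite_differences(self):
        cfg = DecoderConfig(hidden_dim=3, dropout_rate=0.0, gamma=5.0, seed=3)
        model = BRNNModel(4, cfg)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 5, 4))
        y = rng.integers(0, 5, 8)
        assert self._numeric_check(model, X, y, rng) < 1e-4

    def test_unidirectional_gradient_matches_finite_differences(self):
        cfg = DecoderConfig(hidden_dim=3, dropout_rate=0.0, gamma=2.0, seed=4)
        model = UnidirectionalModel(4, cfg, "backward")
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 5, 4))
        y = rng.integers(0, 5, 6)
        assert self._numeric_check(model, X, y, rng) < 1e-4

    def test_mlp_gradient_matches_finite_differences(self):
        cfg = DecoderConfig(dropout_rate=0.0, gamma=5.0, seed=5)
        model = MLPBaseline(20, cfg, hidden_dims=(8, 6))
        rng = np.random.default_rng(2)
        X = rng.standard_normal((7, 20))
        y = rng.integers(0, 5, 7)
        assert self._numeric_check(model, X, y, rng) < 1e-4
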