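"""Numerical core for the sequence decoders: LSTM cell, losses, optimizer.

Everything here is plain numpy with hand-written backpropagation, double
precision throughout.  Parameters live in flat ``{name: ndarray}`` dicts so
the same Adam loop and the finite-difference gradient checker work for every
model.

The LSTM cell follows the standard gated formulation: forget, input and
output gates are logistic functions of ``W @ [h_prev, x_t] + b``; the cell
state mixes the previous state and a tanh candidate through the forget and
input gates; the hidden state is the output gate times ``tanh(c_t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS_PROB = 1e-12  # floor for predicted true-class probability in the loss


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# focal loss


def focal_loss(probs: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Mean multiclass focal loss  -(1 - p_y)^gamma * log(p_y).

    ``gamma`` down-weights well-classified samples; ``gamma=0`` recovers the
    cross-entropy.  ``p_y`` is floored at 1e-12.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    probs = np.atleast_2d(probs)
    labels = np.atleast_1d(labels)
    p_y = np.clip(probs[np.arange(len(labels)), labels], EPS_PROB, 1.0)
    return float(np.mean(-((1.0 - p_y) ** gamma) * np.log(p_y)))


def focal_loss_and_dlogits(
    logits: np.ndarray, labels: np.ndarray, gamma: float
) -> tuple[float, np.ndarray]:
    """Focal loss of softmax(logits) and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    B = logits.shape[0]
    idx = np.arange(B)
    p_y = np.clip(probs[idx, labels], EPS_PROB, 1.0)
    one_minus = 1.0 - p_y
    loss = float(np.mean(-(one_minus**gamma) * np.log(p_y)))
    # dL/dp_y, with the gamma=0 / p_y=1 limits handled explicitly
    if gamma == 0:
        dl_dpy = -1.0 / p_y
    else:
        dl_dpy = gamma * one_minus ** (gamma - 1.0) * np.log(p_y) - one_minus**gamma / p_y
    # dp_y/dlogit_j = p_y * (delta_{jy} - p_j)
    dlogits = probs * (dl_dpy * p_y)[:, None]
    dlogits[idx, labels] -= dl_dpy * p_y
    dlogits *= -1.0 / B
    return loss, dlogits


# ---------------------------------------------------------------------------
# LSTM cell


@dataclass
class LSTMParams:
    """Gate weights acting on the concatenation [h_prev, x_t]."""

    W_f: np.ndarray  # (H, H+K)
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_f: np.ndarray  # (H,)
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def hidden_dim(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    def n_params(self) -> int:
        return sum(
            a.size
            for a in (self.W_f, self.W_i, self.W_o, self.W_c,
                      self.b_f, self.b_i, self.b_o, self.b_c)
        )

    def as_dict(self, prefix: str) -> dict[str, np.ndarray]:
        return {
            f"{prefix}W_f": self.W_f, f"{prefix}W_i": self.W_i,
            f"{prefix}W_o": self.W_o, f"{prefix}W_c": self.W_c,
            f"{prefix}b_f": self.b_f, f"{prefix}b_i": self.b_i,
            f"{prefix}b_o": self.b_o, f"{prefix}b_c": self.b_c,
        }


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


@dataclass
class GateActivations:
    f: np.ndarray  # in (0, 1)
    i: np.ndarray
    o: np.ndarray
    candidate: np.ndarray  # tanh term, in (-1, 1)


def init_lstm_params(
    input_dim: int, hidden_dim: int, rng: np.random.Generator
) -> LSTMParams:
    """Uniform +/- 1/sqrt(H) weights, zero biases except forget bias +1."""
    bound = 1.0 / np.sqrt(hidden_dim)
    shape = (hidden_dim, hidden_dim + input_dim)

    def w() -> np.ndarray:
        return rng.uniform(-bound, bound, size=shape)

    return LSTMParams(
        W_f=w(), W_i=w(), W_o=w(), W_c=w(),
        b_f=np.ones(hidden_dim),  # start remembering; standard practice
        b_i=np.zeros(hidden_dim),
        b_o=np.zeros(hidden_dim),
        b_c=np.zeros(hidden_dim),
    )


def lstm_cell_step(
    x_t: np.ndarray, prev: LSTMState, params: LSTMParams
) -> tuple[LSTMState, GateActivations]:
    """One gated update of (h, c) for a single input vector."""
    x_t = np.asarray(x_t, dtype=float)
    if not np.isfinite(x_t).all():
        raise ValueError("non-finite input to LSTM cell")
    z = np.concatenate([prev.h, x_t])
    f = sigmoid(params.W_f @ z + params.b_f)
    i = sigmoid(params.W_i @ z + params.b_i)
    o = sigmoid(params.W_o @ z + params.b_o)
    g = np.tanh(params.W_c @ z + params.b_c)
    c = f * prev.c + i * g
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c), GateActivations(f=f, i=i, o=o, candidate=g)


def run_direction(
    sequence: np.ndarray, params: LSTMParams, direction: str = "forward"
) -> np.ndarray:
    """Consume an (L, K) sequence from zero state; return the final hidden state.

    ``forward`` consumes nodes in the given (V1..LO) order, ``backward`` in
    reversed order.
    """
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 2 or sequence.shape[0] == 0:
        raise ValueError("sequence must be a nonempty (L, K) array")
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    order = range(sequence.shape[0])
    if direction == "backward":
        order = reversed(order)
    H = params.hidden_dim
    state = LSTMState(h=np.zeros(H), c=np.zeros(H))
    for t in order:
        state, _ = lstm_cell_step(sequence[t], state, params)
    return state.h


# ---------------------------------------------------------------------------
# batched LSTM forward/backward (final-state readout)


def lstm_forward_batch(
    X: np.ndarray, params: LSTMParams, reverse: bool
) -> tuple[np.ndarray, list]:
    """Run a (B, L, K) batch; return final hidden states (B, H) and a cache."""
    B, L, _ = X.shape
    H = params.hidden_dim
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    steps = range(L - 1, -1, -1) if reverse else range(L)
    for t in steps:
        z = np.concatenate([h, X[:, t, :]], axis=1)
        f = sigmoid(z @ params.W_f.T + params.b_f)
        i = sigmoid(z @ params.W_i.T + params.b_i)
        o = sigmoid(z @ params.W_o.T + params.b_o)
        g = np.tanh(z @ params.W_c.T + params.b_c)
        c_prev = c
        c = f * c_prev + i * g
        tanh_c = np.tanh(c)
        h = o * tanh_c
        cache.append((z, f, i, o, g, tanh_c, c_prev))
    return h, cache


def lstm_backward_batch(
    dh_final: np.ndarray, cache: list, params: LSTMParams
) -> dict[str, np.ndarray]:
    """Backpropagate a gradient at the final hidden state through time."""
    H = params.hidden_dim
    grads = {
        "W_f": np.zeros_like(params.W_f), "W_i": np.zeros_like(params.W_i),
        "W_o": np.zeros_like(params.W_o), "W_c": np.zeros_like(params.W_c),
        "b_f": np.zeros_like(params.b_f), "b_i": np.zeros_like(params.b_i),
        "b_o": np.zeros_like(params.b_o), "b_c": np.zeros_like(params.b_c),
    }
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for z, f, i, o, g, tanh_c, c_prev in reversed(cache):
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_prev = dc * f
        da_f = df * f * (1.0 - f)
        da_i = di * i * (1.0 - i)
        da_o = do * o * (1.0 - o)
        da_g = dg * (1.0 - g**2)
        grads["W_f"] += da_f.T @ z
        grads["W_i"] += da_i.T @ z
        grads["W_o"] += da_o.T @ z
        grads["W_c"] += da_g.T @ z
        grads["b_f"] += da_f.sum(axis=0)
        grads["b_i"] += da_i.sum(axis=0)
        grads["b_o"] += da_o.sum(axis=0)
        grads["b_c"] += da_g.sum(axis=0)
        dz = da_f @ params.W_f + da_i @ params.W_i + da_o @ params.W_o + da_g @ params.W_c
        dh = dz[:, :H]
        dc = dc_prev
    return grads


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with decoupled L2 weight decay on weight matrices (not biases)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        learning_rate: float = 1e-3,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = learning_rate
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    @staticmethod
    def _decays(name: str) -> bool:
        return name.rsplit(".", 1)[-1].startswith("W")

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            p -= self.lr * update
            if self.wd and self._decays(k):
                p -= self.lr * self.wd * p
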