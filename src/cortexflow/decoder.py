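"""Category decoders over the five-area voxel sequence.

The proposed decoder is a bidirectional LSTM: one LSTM consumes the area
nodes bottom-up (V1 -> V2 -> V3 -> V4 -> LO), a second one top-down, and the
two final 16-D hidden states are concatenated into a 32-D feature that a
fully connected softmax layer maps to 5/10/23 category probabilities.
Training minimizes the multiclass focal loss (gamma 5.0 by default) with
Adam, batch size 64, learning rate 1e-3, decoupled L2 weight regularization
1e-3, and dropout 0.5 on the combined feature.

Baselines mirror the comparisons the method is judged against: the same
architecture without recurrence (a 500-64-32 fully connected network), the
two unidirectional LSTM ablations, and classical classifiers (decision tree,
random forest, AdaBoost, linear/RBF SVM) on the concatenated 500-D voxel
vector.

All numpy models are deterministic functions of their config seed when run
single-threaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import nn
from .nn import Adam, init_lstm_params
from .synthetic import SequenceSample, stack_sequences

N_CLASSES = {"coarse": 5, "mid": 10, "fine": 23}

CLASSICAL_KINDS = ("decision_tree", "random_forest", "adaboost", "svm_linear", "svm_rbf")


@dataclass
class DecoderConfig:
    """Training recipe for the sequence decoders."""

    hidden_dim: int = 16
    dropout_rate: float = 0.5
    gamma: float = 5.0
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 200
    label_level: str = "coarse"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if min(self.hidden_dim, self.batch_size, self.epochs) <= 0:
            raise ValueError("hidden_dim, batch_size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.label_level not in N_CLASSES:
            raise ValueError(f"label_level must be one of {sorted(N_CLASSES)}")

    @property
    def n_classes(self) -> int:
        return N_CLASSES[self.label_level]


def _head_init(n_in: int, n_out: int, rng: np.random.Generator, scale_dim: int):
    bound = 1.0 / np.sqrt(scale_dim)
    return rng.uniform(-bound, bound, size=(n_out, n_in)), np.zeros(n_out)


def _dropout_mask(shape, rate: float, rng: np.random.Generator | None):
    if rng is None or rate == 0.0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


class BRNNModel:
    """Bidirectional LSTM + fully connected softmax head."""

    def __init__(self, input_dim: int, config: DecoderConfig) -> None:
        self.config = config
        H = config.hidden_dim
        rng = np.random.default_rng([131, config.seed])
        self.forward_params = init_lstm_params(input_dim, H, rng)
        self.backward_params = init_lstm_params(input_dim, H, rng)
        self.head_W, self.head_b = _head_init(2 * H, config.n_classes, rng, H)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> dict[str, np.ndarray]:
        out = self.forward_params.as_dict("fwd.")
        out.update(self.backward_params.as_dict("bwd."))
        out["head.W"] = self.head_W
        out["head.b"] = self.head_b
        return out

    def n_params_per_direction(self) -> int:
        return self.forward_params.n_params()

    # -- inference ----------------------------------------------------------
    def encode_batch(self, X: np.ndarray):
        hf, cache_f = nn.lstm_forward_batch(X, self.forward_params, reverse=False)
        hb, cache_b = nn.lstm_forward_batch(X, self.backward_params, reverse=True)
        return np.concatenate([hf, hb], axis=1), (cache_f, cache_b)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        feat, _ = self.encode_batch(np.asarray(X, dtype=float))
        return nn.softmax(feat @ self.head_W.T + self.head_b)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- training -----------------------------------------------------------
    def loss_and_grads(self, X, y, rng: np.random.Generator | None):
        cfg = self.config
        H = cfg.hidden_dim
        feat, (cache_f, cache_b) = self.encode_batch(X)
        mask = _dropout_mask(feat.shape, cfg.dropout_rate, rng)
        dropped = feat * mask if mask is not None else feat
        logits = dropped @ self.head_W.T + self.head_b
        loss, dlogits = nn.focal_loss_and_dlogits(logits, y, cfg.gamma)
        grads = {
            "head.W": dlogits.T @ dropped,
            "head.b": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ self.head_W
        if mask is not None:
            dfeat = dfeat * mask
        gf = nn.lstm_backward_batch(dfeat[:, :H], cache_f, self.forward_params)
        gb = nn.lstm_backward_batch(dfeat[:, H:], cache_b, self.backward_params)
        grads.update({f"fwd.{k}": v for k, v in gf.items()})
        grads.update({f"bwd.{k}": v for k, v in gb.items()})
        return loss, grads


class UnidirectionalModel:
    """Single-direction LSTM ablation (16-D feature into the softmax head)."""

    def __init__(self, input_dim: int, config: DecoderConfig, direction: str) -> None:
        if direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {direction!r}")
        self.config = config
        self.direction = direction
        H = config.hidden_dim
        rng = np.random.default_rng([137, config.seed])
        self.lstm_params = init_lstm_params(input_dim, H, rng)
        self.head_W, self.head_b = _head_init(H, config.n_classes, rng, H)

    def params(self) -> dict[str, np.ndarray]:
        out = self.lstm_params.as_dict("lstm.")
        out["head.W"] = self.head_W
        out["head.b"] = self.head_b
        return out

    def encode_batch(self, X: np.ndarray):
        return nn.lstm_forward_batch(
            X, self.lstm_params, reverse=(self.direction == "backward")
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        feat, _ = self.encode_batch(np.asarray(X, dtype=float))
        return nn.softmax(feat @ self.head_W.T + self.head_b)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def loss_and_grads(self, X, y, rng: np.random.Generator | None):
        cfg = self.config
        feat, cache = self.encode_batch(X)
        mask = _dropout_mask(feat.shape, cfg.dropout_rate, rng)
        dropped = feat * mask if mask is not None else feat
        logits = dropped @ self.head_W.T + self.head_b
        loss, dlogits = nn.focal_loss_and_dlogits(logits, y, cfg.gamma)
        grads = {
            "head.W": dlogits.T @ dropped,
            "head.b": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ self.head_W
        if mask is not None:
            dfeat = dfeat * mask
        g = nn.lstm_backward_batch(dfeat, cache, self.lstm_params)
        grads.update({f"lstm.{k}": v for k, v in g.items()})
        return loss, grads


class MLPBaseline:
    """Fully connected baseline: input (5K) -> 64 -> 32 -> softmax.

    Same loss, optimizer and dropout placement (on the last hidden feature)
    as the recurrent decoders, so the only difference is the absence of
    recurrence over the area sequence.
    """

    def __init__(self, input_dim: int, config: DecoderConfig,
                 hidden_dims: tuple[int, int] = (64, 32)) -> None:
        self.config = config
        rng = np.random.default_rng([139, config.seed])
        d1, d2 = hidden_dims
        self.W1, self.b1 = _head_init(input_dim, d1, rng, input_dim)
        self.W2, self.b2 = _head_init(d1, d2, rng, d1)
        self.W3, self.b3 = _head_init(d2, config.n_classes, rng, d2)

    def params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
                "W3": self.W3, "b3": self.b3}

    def n_params(self) -> int:
        return sum(a.size for a in self.params().values())

    def _forward(self, X: np.ndarray):
        a1 = np.maximum(X @ self.W1.T + self.b1, 0.0)
        a2 = np.maximum(a1 @ self.W2.T + self.b2, 0.0)
        return a1, a2

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, a2 = self._forward(np.asarray(X, dtype=float))
        return nn.softmax(a2 @ self.W3.T + self.b3)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def loss_and_grads(self, X, y, rng: np.random.Generator | None):
        cfg = self.config
        a1, a2 = self._forward(X)
        mask = _dropout_mask(a2.shape, cfg.dropout_rate, rng)
        dropped = a2 * mask if mask is not None else a2
        logits = dropped @ self.W3.T + self.b3
        loss, dlogits = nn.focal_loss_and_dlogits(logits, y, cfg.gamma)
        grads = {"W3": dlogits.T @ dropped, "b3": dlogits.sum(axis=0)}
        da2 = dlogits @ self.W3
        if mask is not None:
            da2 = da2 * mask
        da2 = da2 * (a2 > 0)
        grads["W2"] = da2.T @ a1
        grads["b2"] = da2.sum(axis=0)
        da1 = (da2 @ self.W2) * (a1 > 0)
        grads["W1"] = da1.T @ X
        grads["b1"] = da1.sum(axis=0)
        return loss, grads


# ---------------------------------------------------------------------------
# spec-level convenience wrappers


def bidirectional_encode(sequence: np.ndarray, model: BRNNModel) -> np.ndarray:
    """Concatenated (forward, backward) final hidden states; 32-D at H=16."""
    feat, _ = model.encode_batch(np.asarray(sequence, dtype=float)[None])
    return feat[0]


def classify(feature: np.ndarray, model) -> np.ndarray:
    """Softmax head probabilities for an already-encoded feature vector."""
    logits = np.asarray(feature, dtype=float) @ model.head_W.T + model.head_b
    return nn.softmax(logits)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[-1]


def _labels_at_level(samples: list[SequenceSample], level: str) -> np.ndarray:
    _, labels = stack_sequences(samples)
    return labels[level]


def _train_loop(model, Xtr, ytr, Xva, yva) -> TrainingHistory:
    cfg = model.config
    rng = np.random.default_rng([149, cfg.seed])
    params = model.params()
    opt = Adam(params, cfg.learning_rate, cfg.weight_decay)
    history = TrainingHistory()
    n = len(ytr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = model.loss_and_grads(Xtr[idx], ytr[idx], rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            opt.step(params, grads)
            total += loss * len(idx)
        history.train_loss.append(total / n)
        history.val_accuracy.append(float(np.mean(model.predict(Xva) == yva)))
    return history


def train_decoder(
    train: list[SequenceSample], val: list[SequenceSample], config: DecoderConfig
) -> tuple[BRNNModel, TrainingHistory]:
    """Train the bidirectional LSTM decoder end to end."""
    if not train or not val:
        raise ValueError("train and validation splits must be nonempty")
    Xtr, _ = stack_sequences(train)
    Xva, _ = stack_sequences(val)
    ytr = _labels_at_level(train, config.label_level)
    yva = _labels_at_level(val, config.label_level)
    model = BRNNModel(Xtr.shape[2], config)
    history = _train_loop(model, Xtr, ytr, Xva, yva)
    return model, history


def train_unidirectional(
    train: list[SequenceSample],
    val: list[SequenceSample],
    config: DecoderConfig,
    direction: str,
) -> tuple[UnidirectionalModel, TrainingHistory]:
    """Single-direction LSTM ablation (bottom-up or top-down only)."""
    if not train or not val:
        raise ValueError("train and validation splits must be nonempty")
    Xtr, _ = stack_sequences(train)
    Xva, _ = stack_sequences(val)
    ytr = _labels_at_level(train, config.label_level)
    yva = _labels_at_level(val, config.label_level)
    model = UnidirectionalModel(Xtr.shape[2], config, direction)
    history = _train_loop(model, Xtr, ytr, Xva, yva)
    return model, history


def train_nn_baseline(
    train: list[SequenceSample], val: list[SequenceSample], config: DecoderConfig
) -> tuple[MLPBaseline, TrainingHistory]:
    """Train the non-recurrent fully connected baseline on concatenated areas."""
    if not train or not val:
        raise ValueError("train and validation splits must be nonempty")
    Xtr, _ = stack_sequences(train)
    Xva, _ = stack_sequences(val)
    ytr = _labels_at_level(train, config.label_level)
    yva = _labels_at_level(val, config.label_level)
    Xtr = Xtr.reshape(len(train), -1)
    Xva = Xva.reshape(len(val), -1)
    model = MLPBaseline(Xtr.shape[1], config)
    history = _train_loop(model, Xtr, ytr, Xva, yva)
    return model, history


def train_classical(
    train: list[SequenceSample],
    val: list[SequenceSample],
    kind: str,
    seed: int = 0,
    label_level: str = "coarse",
):
    """Fit a classical classifier on the concatenated 5*K voxel vector.

    Returns the fitted scikit-learn model and its validation accuracy.
    """
    if kind not in CLASSICAL_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSICAL_KINDS}")
    Xtr, _ = stack_sequences(train)
    Xva, _ = stack_sequences(val)
    ytr = _labels_at_level(train, label_level)
    yva = _labels_at_level(val, label_level)
    Xtr = Xtr.reshape(len(train), -1)
    Xva = Xva.reshape(len(val), -1)
    if kind == "decision_tree":
        model = DecisionTreeClassifier(random_state=seed)
    elif kind == "random_forest":
        model = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif kind == "adaboost":
        model = AdaBoostClassifier(random_state=seed)
    elif kind == "svm_linear":
        model = SVC(kernel="linear", random_state=seed)
    else:
        model = SVC(kernel="rbf", random_state=seed)
    model.fit(Xtr, ytr)
    val_acc = float(np.mean(model.predict(Xva) == yva))
    return model, val_acc
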