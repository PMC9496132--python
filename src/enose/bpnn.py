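"""From-scratch back-propagation neural network classifier.

A feedforward multilayer perceptron: sigmoid (or ReLU) hidden layers, a
softmax output head, cross-entropy loss, trained by plain gradient descent
(full batch by default). This is the object whose hidden-layer node counts
the swarm optimizers search over, so it is deliberately written from first
principles rather than delegated to a library: the weights, the forward
pass and the analytic gradients are all explicit and unit-checkable
against finite differences.

Inputs are standardized with training-set mean and standard deviation; the
statistics are stored on the model and re-applied at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["BPNNConfig", "BPNNModel", "init_model", "forward", "train",
           "predict", "accuracy"]

ACTIVATIONS = ("sigmoid", "relu")


@dataclass(frozen=True)
class BPNNConfig:
    input_dim: int
    hidden_sizes: tuple[int, ...] = (10, 10)
    n_classes: int = 4
    activation: str = "sigmoid"
    learning_rate: float = 0.01
    epochs: int = 500
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        if self.input_dim < 1 or self.n_classes < 2:
            raise ValueError("need input_dim >= 1 and n_classes >= 2")
        if len(self.hidden_sizes) == 0:
            raise ValueError("at least one hidden layer is required")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("every hidden size must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class BPNNModel:
    config: BPNNConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_history: list[float] = field(default_factory=list)
    classes_: list | None = None
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None

    @property
    def layer_sizes(self) -> list[int]:
        return [self.config.input_dim, *self.config.hidden_sizes,
                self.config.n_classes]


#: Weight init half-range constant: W ~ U(-c/sqrt(fan_in), +c/sqrt(fan_in)).
INIT_SCALE = 1.0


def init_model(config: BPNNConfig) -> BPNNModel:
    """Fan-in-scaled symmetric uniform weights, zero biases; deterministic
    given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sizes = [config.input_dim, *config.hidden_sizes, config.n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        a = INIT_SCALE / np.sqrt(fan_in)
        weights.append(rng.uniform(-a, a, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return BPNNModel(config, weights, biases)


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    return np.maximum(z, 0.0)


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    # expressed in terms of the activation output
    if kind == "sigmoid":
        return a * (1.0 - a)
    return (a > 0).astype(a.dtype)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _standardize(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    if model.input_mean is None:
        return X
    return (X - model.input_mean) / model.input_sd


def _forward_pass(model: BPNNModel, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Return hidden activations (including the input) and output probs."""
    acts = [X]
    a = X
    kind = model.config.activation
    n_layers = len(model.weights)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        a = _softmax(z) if i == n_layers - 1 else _act(z, kind)
        acts.append(a)
    return acts, a


def forward(model: BPNNModel, x: np.ndarray) -> np.ndarray:
    """Class-probability vector(s) for one input row or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects "
            f"{model.config.input_dim}"
        )
    _, probs = _forward_pass(model, _standardize(model, X))
    return probs[0] if single else probs


def _loss_and_grads(
    model: BPNNModel, X: np.ndarray, Y: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean cross-entropy and its gradients w.r.t. every weight and bias.

    X is assumed already standardized; Y is one-hot. Standard backprop:
    the softmax/cross-entropy head gives delta = (p - y)/n, then deltas are
    chained through the hidden activations.
    """
    n = len(X)
    acts, probs = _forward_pass(model, X)
    eps = 1e-12
    loss = -np.sum(Y * np.log(probs + eps)) / n
    grads_W: list[np.ndarray] = [None] * len(model.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(model.biases)  # type: ignore
    delta = (probs - Y) / n
    kind = model.config.activation
    for i in range(len(model.weights) - 1, -1, -1):
        grads_W[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * _act_grad(acts[i], kind)
    return float(loss), grads_W, grads_b


def _one_hot(labels: np.ndarray, classes: list) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        Y[r, index[lab]] = 1.0
    return Y


def train(model: BPNNModel, X: np.ndarray, labels: np.ndarray) -> BPNNModel:
    """Gradient descent on cross-entropy. Trains in place and returns the
    model. Deterministic given the config seed (mini-batch order is drawn
    from a generator seeded from it)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(X) != len(labels):
        raise ValueError("rows of X must match labels")
    cfg = model.config
    classes = sorted(set(labels.tolist()))
    if len(classes) > cfg.n_classes:
        raise ValueError(
            f"{len(classes)} distinct labels exceed n_classes={cfg.n_classes}"
        )
    if model.classes_ is None:
        model.classes_ = classes
    else:
        unknown = set(classes) - set(model.classes_)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")
        classes = model.classes_
    model.input_mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    model.input_sd = sd
    Xs = _standardize(model, X)
    Y = _one_hot(labels, classes)
    rng = np.random.default_rng(cfg.seed + 1)
    bs = cfg.batch_size or len(X)
    for _ in range(cfg.epochs):
        if bs >= len(X):
            loss, gW, gb = _loss_and_grads(model, Xs, Y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training loss became non-finite; try a smaller "
                    "learning rate"
                )
            for i in range(len(model.weights)):
                model.weights[i] -= cfg.learning_rate * gW[i]
                model.biases[i] -= cfg.learning_rate * gb[i]
        else:
            perm = rng.permutation(len(X))
            for start in range(0, len(X), bs):
                sel = perm[start : start + bs]
                _, gW, gb = _loss_and_grads(model, Xs[sel], Y[sel])
                for i in range(len(model.weights)):
                    model.weights[i] -= cfg.learning_rate * gW[i]
                    model.biases[i] -= cfg.learning_rate * gb[i]
            loss, _, _ = _loss_and_grads(model, Xs, Y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training loss became non-finite; try a smaller "
                    "learning rate"
                )
        model.loss_history.append(loss)
    return model


def predict(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels (argmax of the output probabilities)."""
    if model.classes_ is None:
        raise RuntimeError("model has not been trained")
    probs = forward(model, np.asarray(X, dtype=float))
    probs = np.atleast_2d(probs)
    idx = probs.argmax(axis=1)
    return np.array([model.classes_[i] for i in idx], dtype=object)


def accuracy(model: BPNNModel, X: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of correctly classified rows."""
    pred = predict(model, X)
    labels = np.asarray(labels)
    return float(np.mean(pred == labels))
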