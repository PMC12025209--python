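"""Two-hidden-layer backpropagation network for movement recognition.

The classifier maps the 16 selected time-domain features to the seven
wrist-movement classes.  Architecture and training follow the classical
BPNN recipe: two equal hidden layers whose width comes from the
empirical sizing rule

    M = round(sqrt(m + n)) + a,   a in [0, 10],

with m input nodes and n output nodes (m=16, n=7, a=10 gives M=15);
sigmoid hidden activations; a softmax output layer trained by
full-batch gradient descent on the cross-entropy.  The gradient step
uses the cross-entropy summed over the training set, which with the
conventional learning rate of 1e-3 gives well-scaled steps at the
dataset sizes this package targets; the reported loss curve tracks the
per-sample mean (so a balanced 7-class problem starts near ln 7).

Everything is implemented directly in numpy so the backward pass can be
validated against finite differences; scikit-learn is used only for the
stratified train/test split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .features import FeatureMatrix
from .synthetic import MOVEMENTS

_EPS = 1e-12  # probability floor before log in the cross-entropy


def hidden_size(m: int, n: int, a: int) -> int:
    """Hidden-layer width from the empirical sizing rule
    round(sqrt(m + n)) + a, rounding half-up, minimum 1."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if not 0 <= a <= 10:
        raise ValueError(f"a must be in [0, 10], got {a}")
    return max(1, int(math.floor(math.sqrt(m + n) + 0.5)) + a)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters: full-batch gradient descent on the
    cross-entropy at a fixed learning rate, stratified train/test split."""

    learning_rate: float = 0.001
    iterations: int = 50_000
    train_fraction: float = 0.8
    seed: int = 0
    activation: str = "sigmoid"
    hidden_sizes: tuple[int, int] | None = None  # None -> sizing rule, a=10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.activation not in ("sigmoid", "relu"):
            raise ValueError("activation must be 'sigmoid' or 'relu'")


@dataclass
class MLPModel:
    """A trained feed-forward network with stored standardisation
    statistics; ``forward`` and ``predict`` expect raw (unstandardised)
    feature vectors and apply the stored statistics internally."""

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str
    label_order: list[str]
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if len(self.label_order) != self.layer_sizes[-1]:
            raise ValueError("output size must match label_order length")
        if len(set(self.label_order)) != len(self.label_order):
            raise ValueError("label_order contains duplicates")
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            expected = (self.layer_sizes[i], self.layer_sizes[i + 1])
            if W.shape != expected or b.shape != (expected[1],):
                raise ValueError(
                    f"layer {i}: weight shape {W.shape} inconsistent with "
                    f"layer_sizes {self.layer_sizes}"
                )

    def to_json(self, path) -> None:
        payload = {
            "layer_sizes": self.layer_sizes,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "activation": self.activation,
            "label_order": self.label_order,
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            layer_sizes=payload["layer_sizes"],
            weights=[np.asarray(W) for W in payload["weights"]],
            biases=[np.asarray(b) for b in payload["biases"]],
            activation=payload["activation"],
            label_order=payload["label_order"],
            feature_names=payload["feature_names"],
            mean=np.asarray(payload["mean"]),
            scale=np.asarray(payload["scale"]),
        )


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return np.maximum(z, 0.0)


def _activate_grad(a: np.ndarray, z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return a * (1.0 - a)
    return (z > 0).astype(float)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_pass(
    X: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    activation: str,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """All layer pre-activations and activations for a standardised
    batch; the last activation is the softmax probability matrix."""
    zs, activations = [], [X]
    a = X
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W + b
        zs.append(z)
        a = _softmax(z) if i == len(weights) - 1 else _activate(z, activation)
        activations.append(a)
    return zs, activations


def _gradients(
    X: np.ndarray,
    Y: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    activation: str,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backprop gradients of the summed cross-entropy over the batch."""
    zs, activations = _forward_pass(X, weights, biases, activation)
    delta = activations[-1] - Y  # softmax + cross-entropy
    grads_W, grads_b = [], []
    for i in range(len(weights) - 1, -1, -1):
        grads_W.append(activations[i].T @ delta)
        grads_b.append(delta.sum(axis=0))
        if i > 0:
            delta = (delta @ weights[i].T) * _activate_grad(
                activations[i], zs[i - 1], activation
            )
    return grads_W[::-1], grads_b[::-1]


def batch_cross_entropy(
    X: np.ndarray,
    Y: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    activation: str,
) -> float:
    """Summed cross-entropy of a standardised batch (the training loss
    whose gradient the backward pass computes)."""
    _, activations = _forward_pass(X, weights, biases, activation)
    probs = np.clip(activations[-1], _EPS, None)
    return float(-(Y * np.log(probs)).sum())


def cross_entropy(
    predicted: np.ndarray, true_class: str, label_order: list[str]
) -> float:
    """Cross-entropy of one prediction against a one-hot true class:
    minus the log probability assigned to the true class.  Probabilities
    below the machine floor (1e-12) are clamped before the log."""
    p = np.asarray(predicted, dtype=float)
    if p.ndim != 1 or len(p) != len(label_order):
        raise ValueError("predicted must be one probability per label")
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("predicted must lie on the probability simplex")
    try:
        idx = label_order.index(true_class)
    except ValueError:
        raise ValueError(f"{true_class!r} not in label_order") from None
    return float(-np.log(max(p[idx], _EPS)))


def _standardise(X: np.ndarray, mean: np.ndarray, scale: np.ndarray):
    return (X - mean) / scale


def forward(model: MLPModel, x) -> np.ndarray:
    """Class-probability vector for one raw feature vector."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != model.layer_sizes[0]:
        raise ValueError(
            f"expected {model.layer_sizes[0]} features, got {len(x)}"
        )
    xs = _standardise(x, model.mean, model.scale)
    _, activations = _forward_pass(
        xs[None, :], model.weights, model.biases, model.activation
    )
    return activations[-1][0]


def predict(model: MLPModel, x) -> str:
    """Most probable movement label; exact ties resolve to the label
    appearing earlier in ``label_order``."""
    probs = forward(model, x)
    return model.label_order[int(np.argmax(probs))]


def predict_batch(model: MLPModel, features: FeatureMatrix) -> list[str]:
    """Predicted label for every window of a feature matrix."""
    if features.feature_names != model.feature_names:
        raise ValueError("feature columns do not match the trained model")
    Xs = _standardise(features.values, model.mean, model.scale)
    _, activations = _forward_pass(
        Xs, model.weights, model.biases, model.activation
    )
    idx = np.argmax(activations[-1], axis=1)
    return [model.label_order[i] for i in idx]


@dataclass
class TrainReport:
    """Training outcome: accuracies, final mean loss, and the
    per-iteration mean cross-entropy curve on the training split."""

    final_loss: float
    train_accuracy: float
    test_accuracy: float
    loss_curve: np.ndarray = field(repr=False)


def _init_layers(sizes: list[int], rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train(
    features: FeatureMatrix, config: TrainConfig | None = None
) -> tuple[MLPModel, TrainReport]:
    """Train the network on a labeled feature matrix.

    Performs a stratified train/test split, standardises features with
    training-set statistics, runs full-batch gradient descent for the
    configured number of iterations, and reports held-out accuracy.
    """
    if config is None:
        config = TrainConfig()
    if features.labels is None:
        raise ValueError("training requires labeled features")
    y = np.asarray(features.labels)
    present = [m for m in MOVEMENTS if m in set(y)]
    extra = sorted(set(y) - set(MOVEMENTS))
    label_order = present + extra
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 instances")

    X = features.values
    m_in, n_out = X.shape[1], len(label_order)
    if config.hidden_sizes is None:
        width = hidden_size(m_in, n_out, 10)
        hidden = (width, width)
    else:
        hidden = config.hidden_sizes
    sizes = [m_in, *hidden, n_out]

    X_train, X_test, y_train, y_test = train_test_split(
        X,
        y,
        train_size=config.train_fraction,
        stratify=y,
        random_state=config.seed % (2**32),
    )
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = _standardise(X_train, mean, scale)
    label_index = {lab: i for i, lab in enumerate(label_order)}
    Y = np.zeros((len(y_train), n_out))
    Y[np.arange(len(y_train)), [label_index[l] for l in y_train]] = 1.0

    rng = np.random.default_rng(config.seed)
    weights, biases = _init_layers(sizes, rng)

    n_train = len(Xs)
    loss_curve = np.empty(config.iterations)
    for it in range(config.iterations):
        grads_W, grads_b = _gradients(
            Xs, Y, weights, biases, config.activation
        )
        for i in range(len(weights)):
            weights[i] -= config.learning_rate * grads_W[i]
            biases[i] -= config.learning_rate * grads_b[i]
        loss = batch_cross_entropy(
            Xs, Y, weights, biases, config.activation
        ) / n_train
        if not math.isfinite(loss):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss is not finite "
                f"(learning_rate={config.learning_rate})"
            )
        loss_curve[it] = loss

    model = MLPModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        activation=config.activation,
        label_order=label_order,
        feature_names=list(features.feature_names),
        mean=mean,
        scale=scale,
    )

    def _accuracy(Xa, ya):
        Xa_s = _standardise(Xa, mean, scale)
        _, acts = _forward_pass(Xa_s, weights, biases, config.activation)
        pred = np.argmax(acts[-1], axis=1)
        truth = np.array([label_index[l] for l in ya])
        return float(np.mean(pred == truth))

    report = TrainReport(
        final_loss=float(loss_curve[-1]),
        train_accuracy=_accuracy(X_train, y_train),
        test_accuracy=_accuracy(X_test, y_test),
        loss_curve=loss_curve,
    )
    return model, report
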