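"""Feedforward neural classifier: ReLU hidden layers, softmax output,
inverted dropout, Adam with an exponentially decaying learning rate, and
exhaustive grid search over architecture candidates.

Training is full batch (the datasets here are tens of rows), so one epoch
corresponds to one optimizer step of the decay schedule.  Everything is
seeded and deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["MLPConfig", "TrainedMLP", "lr_schedule", "mlp_init", "mlp_train", "mlp_predict", "grid_search"]


@dataclass(frozen=True)
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (300, 400, 300)
    dropout: float = 0.5
    lr0: float = 0.01
    decay_rate: float = 0.96
    decay_steps: int = 10000
    epochs: int = 500
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        if any(h < 1 for h in self.hidden_sizes):
            raise ValidationError("hidden sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.lr0 <= 0:
            raise ValidationError("lr0 must be positive")
        if not (0.0 < self.decay_rate <= 1.0):
            raise ValidationError("decay_rate must be in (0, 1]")
        if self.decay_steps < 1:
            raise ValidationError("decay_steps must be positive")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValidationError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")


def lr_schedule(step: int, lr0: float = 0.01, decay_rate: float = 0.96, decay_steps: int = 10000) -> float:
    """lr0 * decay_rate^min(step, decay_steps): exponential decay with a floor."""
    if step < 0:
        raise ValidationError("step must be >= 0")
    return lr0 * decay_rate ** min(step, decay_steps)


@dataclass
class TrainedMLP:
    """Weights, biases and training history of a (possibly untrained) net."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MLPConfig
    input_dim: int
    n_classes: int
    history: list[dict] = field(default_factory=list)

    def layer_shapes(self) -> list[tuple[int, int]]:
        return [w.shape for w in self.weights]


def mlp_init(input_dim: int, n_classes: int, config: MLPConfig | None = None) -> TrainedMLP:
    """Glorot-uniform seeded initialization of input -> hidden* -> classes."""
    config = config or MLPConfig()
    if input_dim < 1 or n_classes < 2:
        raise ValidationError("input_dim must be >= 1 and n_classes >= 2")
    dims = [input_dim, *config.hidden_sizes, n_classes]
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return TrainedMLP(weights, biases, config, input_dim, n_classes)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    model: TrainedMLP,
    X: np.ndarray,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Returns (probs, activations per layer, dropout masks). Dropout is
    inverted and applied to hidden activations only when a rng is given."""
    p_drop = model.config.dropout
    a = X
    activations = [a]
    masks: list[np.ndarray] = []
    n_layers = len(model.weights)
    for li, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        if li < n_layers - 1:
            a = np.maximum(z, 0.0)
            if dropout_rng is not None and p_drop > 0:
                mask = (dropout_rng.random(a.shape) >= p_drop) / (1.0 - p_drop)
                a = a * mask
                masks.append(mask)
            activations.append(a)
        else:
            a = _softmax(z)
            activations.append(a)
    return a, activations, masks


def mlp_train(model: TrainedMLP, X: np.ndarray, y: Sequence[int], config: MLPConfig | None = None) -> TrainedMLP:
    """Full-batch cross-entropy training with Adam (or SGD) and Eq.-style
    exponential learning-rate decay; one epoch = one optimizer step."""
    config = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y lengths differ")
    if X.shape[1] != model.input_dim:
        raise ValidationError(f"X has {X.shape[1]} columns, model expects {model.input_dim}")
    if len(np.unique(y)) < 2:
        raise ValidationError("training requires at least 2 represented classes")
    n = X.shape[0]
    onehot = np.zeros((n, model.n_classes))
    onehot[np.arange(n), y] = 1.0

    rng = np.random.default_rng(config.seed + 1)  # dropout stream, distinct from init
    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for epoch in range(config.epochs):
        probs, activations, masks = _forward(model, X, dropout_rng=rng)
        loss = -np.mean(np.sum(onehot * np.log(np.clip(probs, 1e-12, None)), axis=1))
        if not np.isfinite(loss):
            raise ValidationError(f"non-finite loss at epoch {epoch}")
        acc = float(np.mean(np.argmax(probs, axis=1) == y))

        # backprop
        grads_w: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        delta = (probs - onehot) / n
        for li in range(len(model.weights) - 1, -1, -1):
            a_prev = activations[li]
            grads_w.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if li > 0:
                delta = delta @ model.weights[li].T
                if masks:
                    delta = delta * masks[li - 1]
                delta = delta * (activations[li] > 0)
        grads = list(reversed(grads_w)) + list(reversed(grads_b))

        lr = lr_schedule(epoch, config.lr0, config.decay_rate, config.decay_steps)
        if config.optimizer == "adam":
            t = epoch + 1
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                m_hat = m[i] / (1 - beta1**t)
                v_hat = v[i] / (1 - beta2**t)
                params[i] -= lr * m_hat / (np.sqrt(v_hat) + eps)
        else:
            for i, g in enumerate(grads):
                params[i] -= lr * g

        model.history.append({"epoch": epoch, "loss": float(loss), "accuracy": acc, "lr": lr})
    return model


def mlp_predict(model: TrainedMLP, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dropout-free forward pass: (argmax labels, softmax probabilities)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValidationError(f"X has {X.shape[1]} columns, model expects {model.input_dim}")
    probs, _, _ = _forward(model, X, dropout_rng=None)
    return np.argmax(probs, axis=1), probs


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def grid_search(
    grid: Mapping[str, Sequence],
    X: np.ndarray,
    y: Sequence[int],
    k_folds: int = 5,
    seed: int = 0,
    base_config: MLPConfig | None = None,
) -> tuple[MLPConfig, list[dict]]:
    """Exhaustive Cartesian-product search scored by k-fold CV mean accuracy.

    Ties go to the first combination in product order; a combination that
    fails to train scores 0 with a warning.
    """
    if not grid:
        raise ValidationError("grid must be non-empty")
    base = base_config or MLPConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    remap = {c: i for i, c in enumerate(classes)}
    y_enc = np.array([remap[c] for c in y])
    folds = _stratified_folds(y_enc, k_folds, seed)

    keys = list(grid.keys())
    table: list[dict] = []
    best_config, best_score = None, -1.0
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)))
        accs = []
        try:
            for fi in range(k_folds):
                test_idx = folds[fi]
                train_idx = np.setdiff1d(np.arange(len(y_enc)), test_idx)
                net = mlp_init(X.shape[1], len(classes), cfg)
                net = mlp_train(net, X[train_idx], y_enc[train_idx], cfg)
                pred, _ = mlp_predict(net, X[test_idx])
                accs.append(float(np.mean(pred == y_enc[test_idx])))
            score = float(np.mean(accs))
        except Exception as exc:
            logger.warning("grid combination %s failed to train: %s", combo, exc)
            score = 0.0
        table.append({**dict(zip(keys, combo)), "mean_accuracy": score})
        if score > best_score:
            best_score, best_config = score, cfg
    assert best_config is not None
    return best_config, table
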