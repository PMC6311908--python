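"""The two-tower feed-forward pair classifier.

Each protein's AC vector is processed by its own tower of fully connected
ReLU layers; the two tower outputs are concatenated and passed through
further fused ReLU layers and a logistic output unit.  Training minimizes
binary cross-entropy with mini-batch Adam, dropout, optional batch
normalization, and glorot-normal weight initialization.  Everything is
implemented directly on numpy arrays, so training is CPU-only and fully
deterministic given a seed.

A fast linear fallback (:func:`train_linear_fallback`) with the same
predict contract backs quick experiments and large cross-validation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LogisticRegression

from .features import EncodedPairDataset


@dataclass
class NetworkConfig:
    """Hyperparameters of the two-tower network.

    Defaults follow the recommended configuration: towers of widths
    128-64-32 (depth h1 = 3), one fused hidden layer of 32 after
    concatenation, learning rate 0.002, batch size 1024, dropout 0.6,
    glorot-normal initialization and Adam.
    """

    tower_widths: tuple[int, ...] = (128, 64, 32)
    fused_widths: tuple[int, ...] = (32,)
    learning_rate: float = 0.002
    batch_size: int = 1024
    dropout: float = 0.6
    epochs: int = 100
    batch_norm: bool = True
    early_stopping_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.tower_widths + self.fused_widths):
            raise ValueError("all layer widths must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def concatenated_config(**overrides) -> NetworkConfig:
    """Preset for the single-network variant: the two AC vectors are
    concatenated up front and fed to one network with hidden layers
    420-256-32 (no towers)."""
    cfg = NetworkConfig(tower_widths=(), fused_widths=(420, 256, 32))
    return replace(cfg, **overrides)


class _Linear:
    """A dense layer with optional batch normalization, trained by Adam."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 batch_norm: bool) -> None:
        # glorot-normal initialization
        sd = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, sd, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.batch_norm = batch_norm
        if batch_norm:
            self.gamma = np.ones(n_out)
            self.beta = np.zeros(n_out)
            self.running_mean = np.zeros(n_out)
            self.running_var = np.ones(n_out)
        self._adam_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def params(self) -> dict[str, np.ndarray]:
        out = {"W": self.W, "b": self.b}
        if self.batch_norm:
            out.update({"gamma": self.gamma, "beta": self.beta})
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if not self.batch_norm:
            return z
        if training:
            mean = z.mean(axis=0)
            var = z.var(axis=0)
            self.running_mean = 0.9 * self.running_mean + 0.1 * mean
            self.running_var = 0.9 * self.running_var + 0.1 * var
        else:
            mean, var = self.running_mean, self.running_var
        self._z_hat = (z - mean) / np.sqrt(var + 1e-8)
        self._var = var
        return self.gamma * self._z_hat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.batch_norm:
            n = grad.shape[0]
            self._grads = {
                "gamma": (grad * self._z_hat).sum(axis=0),
                "beta": grad.sum(axis=0),
            }
            dz_hat = grad * self.gamma
            inv_sd = 1.0 / np.sqrt(self._var + 1e-8)
            dz = (
                dz_hat
                - dz_hat.mean(axis=0)
                - self._z_hat * (dz_hat * self._z_hat).mean(axis=0)
            ) * inv_sd
        else:
            self._grads = {}
            dz = grad
        self._grads["W"] = self._x.T @ dz
        self._grads["b"] = dz.sum(axis=0)
        return dz @ self.W.T

    def adam_step(self, lr: float, t: int, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8) -> None:
        params = self.params()
        for name, grad in self._grads.items():
            if name not in self._adam_state:
                self._adam_state[name] = (np.zeros_like(grad), np.zeros_like(grad))
            m, v = self._adam_state[name]
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            self._adam_state[name] = (m, v)
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            params[name] -= lr * m_hat / (np.sqrt(v_hat) + eps)


class TrainedModel:
    """A trained two-tower classifier.

    ``predict`` maps pairs of AC vectors to interaction probabilities in
    (0, 1); dropout and batch statistics are frozen at inference time.
    """

    def __init__(self, config: NetworkConfig, n_features: int) -> None:
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(config.seed)
        self.towers: list[list[_Linear]] = []
        for _ in range(2 if config.tower_widths else 0):
            layers, n_in = [], n_features
            for w in config.tower_widths:
                layers.append(_Linear(n_in, w, rng, config.batch_norm))
                n_in = w
            self.towers.append(layers)
        n_in = (
            2 * config.tower_widths[-1] if config.tower_widths else 2 * n_features
        )
        self.fused: list[_Linear] = []
        for w in config.fused_widths:
            self.fused.append(_Linear(n_in, w, rng, config.batch_norm))
            n_in = w
        self.output = _Linear(n_in, 1, rng, batch_norm=False)
        self.history: list[dict[str, float]] = []
        self._rng = rng

    # -- forward / backward -------------------------------------------------

    def _forward(self, xa: np.ndarray, xb: np.ndarray, training: bool
                 ) -> np.ndarray:
        self._relu_masks: list[np.ndarray] = []
        self._drop_masks: list[np.ndarray | None] = []

        def hidden(layer: _Linear, x: np.ndarray) -> np.ndarray:
            z = layer.forward(x, training)
            mask = z > 0
            h = z * mask
            self._relu_masks.append(mask)
            if training and self.config.dropout > 0:
                keep = 1.0 - self.config.dropout
                dmask = self._rng.random(h.shape) < keep
                h = h * dmask / keep
                self._drop_masks.append(dmask)
            else:
                self._drop_masks.append(None)
            return h

        if self.towers:
            ha, hb = xa, xb
            for la, lb in zip(*self.towers):
                ha = hidden(la, ha)
                hb = hidden(lb, hb)
            h = np.hstack([ha, hb])
        else:
            h = np.hstack([xa, xb])
        for layer in self.fused:
            h = hidden(layer, h)
        logit = self.output.forward(h, training)[:, 0]
        return 1.0 / (1.0 + np.exp(-logit))

    def _backward(self, prob: np.ndarray, y: np.ndarray) -> None:
        n = len(y)
        grad = ((prob - y) / n)[:, None]  # d(BCE)/d(logit)
        grad = self.output.backward(grad)
        masks = list(zip(self._relu_masks, self._drop_masks))
        fused_masks = masks[len(masks) - len(self.fused):] if self.fused else []
        for layer, (rmask, dmask) in zip(reversed(self.fused),
                                         reversed(fused_masks)):
            if dmask is not None:
                grad = grad * dmask / (1.0 - self.config.dropout)
            grad = layer.backward(grad * rmask)
        if self.towers:
            w = self.config.tower_widths[-1]
            grad_a, grad_b = grad[:, :w], grad[:, w:]
            tower_masks = masks[: 2 * len(self.towers[0])]
            for i in range(len(self.towers[0]) - 1, -1, -1):
                rm_a, dm_a = tower_masks[2 * i]
                rm_b, dm_b = tower_masks[2 * i + 1]
                if dm_a is not None:
                    grad_a = grad_a * dm_a / (1.0 - self.config.dropout)
                    grad_b = grad_b * dm_b / (1.0 - self.config.dropout)
                grad_a = self.towers[0][i].backward(grad_a * rm_a)
                grad_b = self.towers[1][i].backward(grad_b * rm_b)

    def _all_layers(self) -> list[_Linear]:
        return [l for tower in self.towers for l in tower] + self.fused + [
            self.output
        ]

    # -- public API ---------------------------------------------------------

    def predict(self, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        """Interaction probabilities for encoded pairs."""
        xa, xb = np.atleast_2d(xa), np.atleast_2d(xb)
        if xa.shape[1] != self.n_features or xb.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: model expects {self.n_features}"
            )
        return self._forward(xa, xb, training=False)


def bce_loss(prob: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    prob = np.clip(prob, eps, 1 - eps)
    return float(-np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def train(dataset: EncodedPairDataset, config: NetworkConfig | None = None
          ) -> TrainedModel:
    """Train the two-tower network by mini-batch Adam on cross-entropy.

    A ``validation_fraction`` split monitors the loss for early stopping
    (patience in epochs); set the fraction to 0 to train on everything.
    Seeded runs are bit-reproducible.
    """
    if config is None:
        config = NetworkConfig()
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = TrainedModel(config, dataset.xa.shape[1])
    rng = np.random.default_rng(config.seed + 1)
    n = len(dataset)
    idx = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    # keep both classes in the training part
    while n_val and len(np.unique(y[idx[n_val:]])) < 2:
        n_val -= 1
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    xa_t, xb_t, y_t = dataset.xa[train_idx], dataset.xb[train_idx], y[train_idx]
    batch = min(config.batch_size, len(train_idx))
    best_val, best_epoch = np.inf, 0
    t = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), batch):
            sel = order[start : start + batch]
            prob = model._forward(xa_t[sel], xb_t[sel], training=True)
            loss = bce_loss(prob, y_t[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            model._backward(prob, y_t[sel])
            t += 1
            for layer in model._all_layers():
                layer.adam_step(config.learning_rate, t)
            epoch_loss += loss
            n_batches += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / n_batches}
        if n_val:
            val_prob = model.predict(dataset.xa[val_idx], dataset.xb[val_idx])
            record["val_loss"] = bce_loss(val_prob, y[val_idx])
            if record["val_loss"] < best_val - 1e-6:
                best_val, best_epoch = record["val_loss"], epoch
            elif epoch - best_epoch >= config.early_stopping_patience:
                model.history.append(record)
                break
        model.history.append(record)
    return model


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities into 0/1 labels (label 1 iff p >= threshold)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(probabilities) >= threshold).astype(int)


class LinearPairModel:
    """Logistic regression on concatenated pair features.

    Satisfies the same ``predict`` contract as :class:`TrainedModel`; used
    as the fast CPU fallback for cross-validation and smoke tests.
    """

    def __init__(self, estimator: LogisticRegression, n_features: int) -> None:
        self._est = estimator
        self.n_features = n_features

    def predict(self, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        xa, xb = np.atleast_2d(xa), np.atleast_2d(xb)
        if xa.shape[1] != self.n_features or xb.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: model expects {self.n_features}"
            )
        return self._est.predict_proba(np.hstack([xa, xb]))[:, 1]


def train_linear_fallback(dataset: EncodedPairDataset, seed: int = 0
                          ) -> LinearPairModel:
    """Fit the linear fallback classifier."""
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("training data must contain both classes")
    est = LogisticRegression(max_iter=2000, random_state=seed)
    est.fit(np.hstack([dataset.xa, dataset.xb]), dataset.y)
    return LinearPairModel(est, dataset.xa.shape[1])
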