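"""Baseline classifiers: a fully connected network and a gradient-boosted tree adapter.

The network uses ReLU hidden layers and a single sigmoid output unit.  One
hidden layer (``ncr_layer``, by default the last) is designated as the
latent space for neighbour-consistency regularization; its post-activation
output is exposed alongside the logits so the NCR loss can backpropagate
into the representation as well as the classifier head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["MLPConfig", "ForwardOutput", "MLPClassifier", "Adam", "train_gbt_baseline"]


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and optimization settings for the baseline network."""

    hidden_sizes: tuple[int, ...] = (32, 32)
    learning_rate: float = 1e-3
    batch_size: int = 256
    n_epochs: int = 60
    ncr_layer: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        hs = tuple(self.hidden_sizes)
        object.__setattr__(self, "hidden_sizes", hs)
        if not hs or any(h < 1 for h in hs):
            raise ValueError(f"hidden_sizes must be positive integers, got {hs}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be positive, got {self.batch_size}")
        if self.n_epochs < 1:
            raise ValueError(f"n_epochs must be positive, got {self.n_epochs}")
        if not -len(hs) <= self.ncr_layer < len(hs):
            raise ValueError(f"ncr_layer {self.ncr_layer} out of range for {len(hs)} hidden layers")


@dataclass
class ForwardOutput:
    """Per-sample outputs of a forward pass.

    ``v``: post-ReLU activations of the designated latent layer (elementwise
    non-negative); ``z``: output-unit logits; ``p``: sigmoid of ``z``, the
    predicted positive-class probability.
    """

    v: np.ndarray
    z: np.ndarray
    p: np.ndarray


class MLPClassifier:
    """Fully connected ReLU network with a single sigmoid output unit.

    Weights use fan-in-scaled normal initialization (He scaling for the ReLU
    layers) under ``config.seed``; training uses Adam (see
    :mod:`noisytab.training`).
    """

    def __init__(self, n_features: int, config: MLPConfig):
        self.n_features = n_features
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = [n_features, *config.hidden_sizes, 1]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(
                Tensor(rng.standard_normal((fan_in, fan_out)) * scale, requires_grad=True)
            )
            self.biases.append(Tensor(np.zeros(fan_out), requires_grad=True))

    @property
    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def forward_tensors(self, X: np.ndarray) -> tuple[Tensor, Tensor]:
        """Differentiable forward pass; returns (latent ``V``, logits ``Z``)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected features of shape (n, {self.n_features}), got {X.shape}"
            )
        h: Tensor = Tensor(X)
        ncr_index = self.config.ncr_layer % len(self.config.hidden_sizes)
        v: Tensor | None = None
        for i in range(len(self.weights) - 1):
            h = ad.relu(h @ self.weights[i] + self.biases[i])
            if i == ncr_index:
                v = h
        z = (h @ self.weights[-1] + self.biases[-1]).reshape(-1)
        assert v is not None
        return v, z

    def forward(self, features: np.ndarray) -> ForwardOutput:
        """Plain-numpy forward pass for inference and diagnostics."""
        X = np.asarray(features, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected features of shape (n, {self.n_features}), got {X.shape}"
            )
        h = X
        ncr_index = self.config.ncr_layer % len(self.config.hidden_sizes)
        v = None
        for i in range(len(self.weights) - 1):
            h = np.maximum(h @ self.weights[i].data + self.biases[i].data, 0.0)
            if i == ncr_index:
                v = h
        z = (h @ self.weights[-1].data + self.biases[-1].data).reshape(-1)
        p = 1.0 / (1.0 + np.exp(-z))
        return ForwardOutput(v=v, z=z, p=p)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.forward(features).p

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Write architecture and weights to a JSON checkpoint."""
        payload = {
            "n_features": self.n_features,
            "config": {
                "hidden_sizes": list(self.config.hidden_sizes),
                "learning_rate": self.config.learning_rate,
                "batch_size": self.config.batch_size,
                "n_epochs": self.config.n_epochs,
                "ncr_layer": self.config.ncr_layer,
                "seed": self.config.seed,
            },
            "weights": [w.data.tolist() for w in self.weights],
            "biases": [b.data.tolist() for b in self.biases],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "MLPClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        model = cls(payload["n_features"], MLPConfig(**cfg))
        for w, data in zip(model.weights, payload["weights"]):
            w.data = np.asarray(data, dtype=np.float64)
        for b, data in zip(model.biases, payload["biases"]):
            b.data = np.asarray(data, dtype=np.float64)
        return model


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train_gbt_baseline(train, params: dict | None = None):
    """Fit a gradient-boosted tree baseline; returns a probability scorer.

    Thin adapter over XGBoost.  ``params`` may override any booster
    hyperparameter (``max_depth``, ``n_estimators``, ``learning_rate``,
    ...); a fixed ``random_state`` makes scores reproducible.

    Raises
    ------
    ValueError
        If the training labels contain a single class.
    """
    from xgboost import XGBClassifier

    y = np.asarray(train.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    defaults = {
        "max_depth": 4,
        "n_estimators": 200,
        "learning_rate": 0.1,
        "random_state": 0,
        "n_jobs": 1,
    }
    defaults.update(params or {})
    clf = XGBClassifier(**defaults)
    clf.fit(train.features, y)

    def scorer(features: np.ndarray) -> np.ndarray:
        return clf.predict_proba(np.asarray(features, dtype=np.float64))[:, 1]

    scorer.model = clf  # type: ignore[attr-defined]
    return scorer
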