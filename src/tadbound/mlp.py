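"""A small feed-forward neural network implemented in numpy.

The default architecture is a 6-layer binary classifier: four hidden layers
(512 identity / 256 softplus / 512 identity / 1024 hard-sigmoid units, with
per-layer dropout and batch normalisation of the input of layers 2 and 3)
feeding a single sigmoid output neuron. Each neuron computes
``f(theta^T x + b)``; training minimises binary cross-entropy by
back-propagation with Adam updates. Dropout and batch statistics are only
active during training, so inference is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["HiddenLayer", "MLPSpec", "MLPNetwork", "DivergenceError"]

_EPS = 1e-7
_BN_EPS = 1e-5


class DivergenceError(RuntimeError):
    """Training loss became non-finite; try a smaller learning rate."""


@dataclass(frozen=True)
class HiddenLayer:
    """One hidden layer: width, activation, dropout rate, input batch-norm."""

    units: int
    activation: str = "linear"  # linear | softplus | hard_sigmoid | sigmoid | relu
    dropout: float = 0.0
    batch_norm: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.units < 1:
            raise ValueError("layer width must be >= 1")


#: Default hidden stack (widths, activations, dropout, BN flags).
DEFAULT_HIDDEN = (
    HiddenLayer(512, "linear", 0.6975, False),
    HiddenLayer(256, "softplus", 0.5153, True),
    HiddenLayer(512, "linear", 0.4252, True),
    HiddenLayer(1024, "hard_sigmoid", 0.0, False),
)


@dataclass(frozen=True)
class MLPSpec:
    """Hyperparameters of the MLP classifier."""

    hidden: tuple[HiddenLayer, ...] = DEFAULT_HIDDEN
    threshold: float = 0.5
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "softplus":
        return np.logaddexp(0.0, z)
    if name == "hard_sigmoid":
        return np.clip(0.2 * z + 0.5, 0.0, 1.0)
    if name == "sigmoid":
        return expit(z)
    if name == "relu":
        return np.maximum(z, 0.0)
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return np.ones_like(z)
    if name == "softplus":
        return expit(z)
    if name == "hard_sigmoid":
        return np.where((z > -2.5) & (z < 2.5), 0.2, 0.0)
    if name == "sigmoid":
        s = expit(z)
        return s * (1.0 - s)
    if name == "relu":
        return (z > 0).astype(z.dtype)
    raise ValueError(f"unknown activation {name!r}")


class MLPNetwork:
    """Binary MLP classifier with a scikit-learn-flavoured interface."""

    def __init__(self, spec: MLPSpec = MLPSpec(), n_features: int | None = None):
        self.spec = spec
        self._rng = np.random.default_rng(spec.seed)
        self._params: dict[str, np.ndarray] = {}
        self._running: dict[str, np.ndarray] = {}
        self.n_features_: int | None = None
        if n_features is not None:
            self._init_params(n_features)

    # -- parameters --------------------------------------------------------
    def _init_params(self, n_features: int) -> None:
        self.n_features_ = n_features
        fan_in = n_features
        for i, layer in enumerate(self.spec.hidden):
            if layer.batch_norm:
                self._params[f"gamma{i}"] = np.ones(fan_in)
                self._params[f"beta{i}"] = np.zeros(fan_in)
                self._running[f"mean{i}"] = np.zeros(fan_in)
                self._running[f"var{i}"] = np.ones(fan_in)
            limit = np.sqrt(6.0 / (fan_in + layer.units))
            self._params[f"W{i}"] = self._rng.uniform(-limit, limit, (fan_in, layer.units))
            self._params[f"b{i}"] = np.zeros(layer.units)
            fan_in = layer.units
        limit = np.sqrt(6.0 / (fan_in + 1))
        self._params["Wout"] = self._rng.uniform(-limit, limit, (fan_in, 1))
        self._params["bout"] = np.zeros(1)

    def set_output_weights(self, W: np.ndarray, b: np.ndarray) -> None:
        self._params["Wout"] = np.asarray(W, dtype=float).reshape(-1, 1)
        self._params["bout"] = np.asarray(b, dtype=float).reshape(1)

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Forward pass; returns (probabilities, caches-for-backprop)."""
        a = np.asarray(X, dtype=float)
        caches = []
        momentum = 0.9
        for i, layer in enumerate(self.spec.hidden):
            cache: dict = {"input": a, "layer": layer, "i": i}
            if layer.batch_norm:
                if training:
                    mu = a.mean(axis=0)
                    var = a.var(axis=0)
                    self._running[f"mean{i}"] = (
                        momentum * self._running[f"mean{i}"] + (1 - momentum) * mu
                    )
                    self._running[f"var{i}"] = (
                        momentum * self._running[f"var{i}"] + (1 - momentum) * var
                    )
                else:
                    mu = self._running[f"mean{i}"]
                    var = self._running[f"var{i}"]
                ivar = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (a - mu) * ivar
                cache.update(bn_x=a, bn_xhat=xhat, bn_ivar=ivar)
                a = self._params[f"gamma{i}"] * xhat + self._params[f"beta{i}"]
            cache["dense_in"] = a
            z = a @ self._params[f"W{i}"] + self._params[f"b{i}"]
            cache["z"] = z
            a = _act(layer.activation, z)
            if training and layer.dropout > 0:
                keep = 1.0 - layer.dropout
                mask = (rng or self._rng).random(a.shape) < keep
                a = a * mask / keep
                cache["drop_mask"] = mask
                cache["keep"] = keep
            caches.append(cache)
        z_out = a @ self._params["Wout"] + self._params["bout"]
        p = expit(z_out).ravel()
        return p, (caches, a)

    # -- backward ----------------------------------------------------------
    def _backward(self, p: np.ndarray, y: np.ndarray, caches, last_a: np.ndarray):
        n = len(y)
        grads: dict[str, np.ndarray] = {}
        dz_out = ((p - y) / n).reshape(-1, 1)  # combined sigmoid + BCE gradient
        grads["Wout"] = last_a.T @ dz_out
        grads["bout"] = dz_out.sum(axis=0)
        da = dz_out @ self._params["Wout"].T
        for cache in reversed(caches):
            i, layer = cache["i"], cache["layer"]
            if "drop_mask" in cache:
                da = da * cache["drop_mask"] / cache["keep"]
            dz = da * _act_grad(layer.activation, cache["z"])
            grads[f"W{i}"] = cache["dense_in"].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            da = dz @ self._params[f"W{i}"].T
            if layer.batch_norm:
                xhat, ivar = cache["bn_xhat"], cache["bn_ivar"]
                gamma = self._params[f"gamma{i}"]
                grads[f"gamma{i}"] = (da * xhat).sum(axis=0)
                grads[f"beta{i}"] = da.sum(axis=0)
                dxhat = da * gamma
                m = xhat.shape[0]
                da = (ivar / m) * (
                    m * dxhat
                    - dxhat.sum(axis=0)
                    - xhat * (dxhat * xhat).sum(axis=0)
                )
        return grads

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPNetwork":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if self.n_features_ is None:
            self._init_params(X.shape[1])
        adam_m = {k: np.zeros_like(v) for k, v in self._params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self._params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.spec.learning_rate
        t = 0
        n = len(y)
        batch = min(self.spec.batch_size, n)
        for _epoch in range(self.spec.epochs):
            order = self._rng.permutation(n)
            for lo in range(0, n, batch):
                idx = order[lo : lo + batch]
                if len(idx) < 2:
                    continue  # batch statistics need >= 2 rows
                p, (caches, last_a) = self.forward(X[idx], training=True, rng=self._rng)
                loss = -np.mean(
                    y[idx] * np.log(p + _EPS) + (1 - y[idx]) * np.log(1 - p + _EPS)
                )
                if not np.isfinite(loss):
                    raise DivergenceError(
                        "training loss is non-finite; reduce the learning rate"
                    )
                grads = self._backward(p, y[idx], caches, last_a)
                t += 1
                for k, g in grads.items():
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                    mhat = adam_m[k] / (1 - beta1**t)
                    vhat = adam_v[k] / (1 - beta2**t)
                    self._params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-probability matrix of shape (n, 2), inference mode."""
        p, _ = self.forward(np.asarray(X, dtype=float), training=False)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > self.spec.threshold).astype(int)
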