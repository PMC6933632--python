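"""The numpy MLP: forward-pass semantics, gradients, training behaviour."""

import numpy as np
import pytest
from scipy.special import expit
from sklearn.metrics import roc_auc_score

import tadbound as tb
from tadbound.mlp import DivergenceError, HiddenLayer, MLPNetwork, MLPSpec

_BN_EPS = 1e-5


def test_zero_output_weights_give_half():
    """A sigmoid output neuron with zero weights and bias returns S(0) = 0.5."""
    net = MLPNetwork(MLPSpec(hidden=(HiddenLayer(4, "linear"),), seed=0), n_features=3)
    net.set_output_weights(np.zeros(4), np.zeros(1))
    proba = net.predict_proba(np.random.default_rng(0).normal(size=(5, 3)))
    np.testing.assert_allclose(proba[:, 1], 0.5)


def hand_forward(net: MLPNetwork, X: np.ndarray) -> np.ndarray:
    """Independent re-implementation of the inference-mode forward pass."""
    a = X.astype(float)
    for i, layer in enumerate(net.spec.hidden):
        if layer.batch_norm:
            mu = net._running[f"mean{i}"]
            var = net._running[f"var{i}"]
            xhat = (a - mu) / np.sqrt(var + _BN_EPS)
            a = net._params[f"gamma{i}"] * xhat + net._params[f"beta{i}"]
        z = a @ net._params[f"W{i}"] + net._params[f"b{i}"]
        if layer.activation == "linear":
            a = z
        elif layer.activation == "softplus":
            a = np.log1p(np.exp(z))
        elif layer.activation == "hard_sigmoid":
            a = np.minimum(np.maximum(0.2 * z + 0.5, 0.0), 1.0)
        else:
            raise AssertionError(layer.activation)
    z = a @ net._params["Wout"] + net._params["bout"]
    return 1.0 / (1.0 + np.exp(-z.ravel()))


def test_forward_pass_matches_hand_coded_oracle(rng):
    """Per-neuron f(theta^T x + b) composition agrees with an independent oracle."""
    hidden = (
        HiddenLayer(6, "linear", 0.3, False),
        HiddenLayer(4, "softplus", 0.2, True),
        HiddenLayer(5, "hard_sigmoid", 0.0, True),
    )
    net = MLPNetwork(MLPSpec(hidden=hidden, seed=3), n_features=7)
    # randomize BN statistics and affine parameters away from their defaults
    for key in list(net._running):
        net._running[key] = np.abs(rng.normal(size=net._running[key].shape)) + 0.5
    for i, layer in enumerate(hidden):
        if layer.batch_norm:
            net._params[f"gamma{i}"] = rng.normal(size=net._params[f"gamma{i}"].shape)
            net._params[f"beta{i}"] = rng.normal(size=net._params[f"beta{i}"].shape)
    X = rng.normal(size=(11, 7))
    np.testing.assert_allclose(net.predict_proba(X)[:, 1], hand_forward(net, X), atol=1e-6)


def test_inference_is_deterministic_despite_dropout(rng):
    net = MLPNetwork(MLPSpec(seed=1), n_features=5)
    X = rng.normal(size=(8, 5))
    np.testing.assert_array_equal(net.predict_proba(X), net.predict_proba(X))


def test_backprop_matches_numerical_gradient(rng):
    hidden = (
        HiddenLayer(4, "softplus", 0.0, True),
        HiddenLayer(3, "linear", 0.0, False),
    )
    net = MLPNetwork(MLPSpec(hidden=hidden, seed=5), n_features=4)
    X = rng.normal(size=(10, 4))
    y = rng.integers(0, 2, size=10).astype(float)

    def loss() -> float:
        p, _ = net.forward(X, training=True)
        return float(-np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12)))

    p, (caches, last_a) = net.forward(X, training=True)
    grads = net._backward(p, y, caches, last_a)
    eps = 1e-6
    for key in ("W0", "b0", "gamma0", "beta0", "W1", "Wout"):
        param = net._params[key]
        flat = param.reshape(-1)
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss()
            flat[idx] = orig - eps
            down = loss()
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grads[key].reshape(-1)[idx] == pytest.approx(numeric, abs=1e-4)


def test_training_separates_a_separable_toy_set(rng):
    X = np.vstack([
        rng.normal(loc=-2.0, size=(40, 4)),
        rng.normal(loc=2.0, size=(40, 4)),
    ])
    y = np.repeat([0, 1], 40)
    net = MLPNetwork(MLPSpec(epochs=40, seed=2), n_features=4)
    net.fit(X, y)
    auc = roc_auc_score(y, net.predict_proba(X)[:, 1])
    assert auc >= 0.99


def test_default_architecture_matches_spec():
    spec = MLPSpec()
    widths = [h.units for h in spec.hidden]
    acts = [h.activation for h in spec.hidden]
    drops = [h.dropout for h in spec.hidden]
    bn = [h.batch_norm for h in spec.hidden]
    assert widths == [512, 256, 512, 1024]
    assert acts == ["linear", "softplus", "linear", "hard_sigmoid"]
    assert drops == [0.6975, 0.5153, 0.4252, 0.0]
    assert bn == [False, True, True, False]


def test_invalid_dropout_rejected():
    with pytest.raises(ValueError):
        HiddenLayer(8, "linear", dropout=1.0)
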