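"""Three-hidden-layer feed-forward binary classifier.

The network is deliberately tiny — ReLU hidden layers, a single sigmoid
output unit — and is parameterised by one flat weight vector so that a
population optimizer can search it directly.  The layout is fixed: for
each layer in order, the weight matrix in row-major (input x output)
order followed by the bias vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .optimizer import OptimizerConfig, OptimizeResult, optimize

__all__ = [
    "NetworkSpec",
    "wbcd_spec",
    "wdbc_spec",
    "parameter_count",
    "flatten_weights",
    "unflatten_weights",
    "init_weights",
    "forward",
    "loss",
    "predict",
    "train_population",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Layer widths ``(d_in, h1, h2, h3, 1)`` of the classifier."""

    layer_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) != 5:
            raise ValueError(
                f"expected exactly three hidden layers, i.e. 5 sizes, got {sizes}"
            )
        if any(s < 1 for s in sizes):
            raise ValueError(f"all layer sizes must be >= 1, got {sizes}")
        if sizes[-1] != 1:
            raise ValueError("output layer must have exactly one unit")

    @property
    def d_in(self) -> int:
        return self.layer_sizes[0]


def wbcd_spec() -> NetworkSpec:
    """Architecture used for the 9-feature cytology data: 9-5-3-2-1."""
    return NetworkSpec((9, 5, 3, 2, 1))


def wdbc_spec() -> NetworkSpec:
    """Architecture used for the 17-feature FNA-image data: 17-8-4-2-1."""
    return NetworkSpec((17, 8, 4, 2, 1))


def parameter_count(spec: NetworkSpec) -> int:
    """Total number of weights and biases, the search dimension ``P``."""
    sizes = spec.layer_sizes
    return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))


def unflatten_weights(spec: NetworkSpec, values: np.ndarray):
    """Split a flat vector into per-layer ``(W, b)`` pairs.

    ``W`` has shape ``(fan_in, fan_out)``; the inverse of
    :func:`flatten_weights`.
    """
    v = np.asarray(values, dtype=float).ravel()
    expected = parameter_count(spec)
    if v.size != expected:
        raise ValueError(f"weight vector has length {v.size}, expected {expected}")
    layers = []
    pos = 0
    sizes = spec.layer_sizes
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = v[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out)
        pos += fan_in * fan_out
        b = v[pos : pos + fan_out]
        pos += fan_out
        layers.append((W, b))
    return layers


def flatten_weights(layers) -> np.ndarray:
    """Concatenate per-layer ``(W, b)`` pairs into one flat vector."""
    parts = []
    for W, b in layers:
        parts.append(np.asarray(W, dtype=float).ravel())
        parts.append(np.asarray(b, dtype=float).ravel())
    return np.concatenate(parts)


def init_weights(spec: NetworkSpec, rng: np.random.Generator,
                 scheme: str = "he", bias: float = 0.1) -> np.ndarray:
    """Initial weights for the gradient trainers.

    ``he`` (default): He-normal fan-in scaling with a small positive
    bias — with only 5/3/2 hidden units per layer a zero-centred init
    regularly kills an entire ReLU layer on all-positive inputs.
    ``uniform``: flat on [-0.5, 0.5], kept for comparison.
    """
    if scheme == "uniform":
        return rng.uniform(-0.5, 0.5, parameter_count(spec))
    if scheme != "he":
        raise ValueError(f"unknown init scheme {scheme!r}")
    layers = []
    sizes = spec.layer_sizes
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
        layers.append((W, np.full(fan_out, bias)))
    return flatten_weights(layers)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward_cached(spec: NetworkSpec, weights: np.ndarray, X: np.ndarray):
    """Forward pass retaining per-layer pre-activations for backprop.

    Returns ``(probabilities, activations, pre_activations)`` where
    ``activations[0]`` is the input batch.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != spec.d_in:
        raise ValueError(f"X has {X.shape[1]} columns, spec expects {spec.d_in}")
    layers = unflatten_weights(spec, weights)
    a = X
    activations = [a]
    pre = []
    for li, (W, b) in enumerate(layers):
        z = a @ W + b
        pre.append(z)
        a = _sigmoid(z) if li == len(layers) - 1 else np.maximum(z, 0.0)
        activations.append(a)
    return activations[-1][:, 0], activations, pre


def forward(spec: NetworkSpec, weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Predicted malignancy probabilities, one per row of ``X``."""
    probs, _, _ = forward_cached(spec, weights, X)
    return probs


def loss(spec: NetworkSpec, weights: np.ndarray, X: np.ndarray,
         y: np.ndarray, kind: str = "mse") -> float:
    """Training loss: mean squared error (default) or binary cross-entropy.

    MSE is the fitness the population optimizers minimize; BCE is kept
    behind the ``kind`` switch for experimentation.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("loss requires at least one sample")
    p = forward(spec, weights, X)
    if p.size != y.size:
        raise ValueError("X and y disagree on the number of samples")
    if kind == "mse":
        return float(np.mean((p - y) ** 2))
    if kind == "bce":
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    raise ValueError(f"unknown loss kind {kind!r}; use 'mse' or 'bce'")


def predict(spec: NetworkSpec, weights: np.ndarray, X: np.ndarray,
            threshold: float = 0.5) -> np.ndarray:
    """Hard labels; ties at the threshold go to the positive class."""
    return (forward(spec, weights, X) >= threshold).astype(int)


def train_population(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    cfg: OptimizerConfig,
    loss_kind: str = "mse",
    trace_path=None,
) -> tuple[np.ndarray, OptimizeResult]:
    """Train by population search over the flattened weight vector.

    Wraps the full-training-set loss as the objective for
    :func:`gmvonet.optimizer.optimize` and returns the elitist best
    weights together with the optimizer's convergence record.  With
    ``cfg.max_iter = 0`` the best of the random initial population is
    returned.
    """
    d = parameter_count(spec)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    def objective(w: np.ndarray) -> float:
        return loss(spec, w, X, y, kind=loss_kind)

    result = optimize(objective, cfg, d=d, trace_path=trace_path)
    return result.best_position, result


def save_model(path, spec: NetworkSpec, weights: np.ndarray,
               feature_stats=None, seed=None, extra=None) -> None:
    """Serialize a trained model (spec, flat weights, preprocessing stats)."""
    payload = {
        "layer_sizes": list(spec.layer_sizes),
        "weights": np.asarray(weights, dtype=float).tolist(),
        "feature_stats": feature_stats,
        "seed": seed,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> tuple[NetworkSpec, np.ndarray, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    spec = NetworkSpec(tuple(payload["layer_sizes"]))
    weights = np.asarray(payload["weights"], dtype=float)
    return spec, weights, payload
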