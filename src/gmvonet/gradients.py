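"""Mini-batch gradient trainers (SGDM and ADAM) for the same network.

These are the conventional comparators for the population search:
exact backpropagated gradients of the batch loss, stepped either by
stochastic gradient descent with momentum or by ADAM with the standard
bias-corrected moment estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    NetworkSpec,
    forward_cached,
    init_weights,
    loss as network_loss,
    parameter_count,
    predict,
    unflatten_weights,
)

__all__ = [
    "GradientTrainerConfig",
    "AdamState",
    "sgdm_step",
    "adam_step",
    "backprop_gradient",
    "train_gradient",
]


@dataclass
class GradientTrainerConfig:
    """Hyperparameters shared by the SGDM and ADAM trainers.

    Defaults follow common practice for the constants the comparison
    study leaves unstated (momentum 0.9; ADAM betas 0.9/0.999) and the
    stated training regime otherwise (learning rate 1e-3, batch size
    10, six epochs).
    """

    learning_rate: float = 1e-3
    momentum: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    eps_adam: float = 1e-8
    batch_size: int = 10
    epochs: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ValueError("beta1 and beta2 must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")


@dataclass
class AdamState:
    """First/second moment accumulators and the step counter."""

    m: np.ndarray
    v: np.ndarray
    k: int = 0

    @classmethod
    def zeros(cls, n_params: int) -> "AdamState":
        return cls(m=np.zeros(n_params), v=np.zeros(n_params), k=0)


def sgdm_step(params: np.ndarray, grad: np.ndarray, velocity: np.ndarray,
              cfg: GradientTrainerConfig) -> tuple[np.ndarray, np.ndarray]:
    """One heavy-ball step: ``v <- mu*v + g``; ``x <- x - eta*v``."""
    params = np.asarray(params, dtype=float)
    grad = np.asarray(grad, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if not (params.shape == grad.shape == velocity.shape):
        raise ValueError("params, grad and velocity must share a shape")
    new_velocity = cfg.momentum * velocity + grad
    return params - cfg.learning_rate * new_velocity, new_velocity


def adam_step(params: np.ndarray, grad: np.ndarray, state: AdamState,
              cfg: GradientTrainerConfig) -> tuple[np.ndarray, AdamState]:
    """One ADAM step with bias-corrected moment estimates."""
    params = np.asarray(params, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if params.shape != grad.shape or params.shape != state.m.shape:
        raise ValueError("params, grad and moment state must share a shape")
    k = state.k + 1
    m = cfg.beta1 * state.m + (1.0 - cfg.beta1) * grad
    v = cfg.beta2 * state.v + (1.0 - cfg.beta2) * grad**2
    m_hat = m / (1.0 - cfg.beta1**k)
    v_hat = v / (1.0 - cfg.beta2**k)
    new_params = params - cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps_adam)
    return new_params, AdamState(m=m, v=v, k=k)


def backprop_gradient(spec: NetworkSpec, weights: np.ndarray,
                      X: np.ndarray, y: np.ndarray,
                      loss_kind: str = "mse") -> np.ndarray:
    """Exact gradient of the batch loss w.r.t. the flat weight vector.

    ReLU hidden layers use the subgradient 0 at exactly-zero
    pre-activations; the sigmoid output couples with MSE as
    ``dL/dz = 2(p - y) p (1 - p) / B`` and with BCE as ``(p - y)/B``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("backprop requires a non-empty batch")
    probs, activations, pre = forward_cached(spec, weights, X)
    if probs.size != y.size:
        raise ValueError("X and y disagree on the number of samples")
    layers = unflatten_weights(spec, weights)
    B = y.size

    p = probs
    if loss_kind == "mse":
        delta = (2.0 * (p - y) * p * (1.0 - p) / B)[:, None]
    elif loss_kind == "bce":
        delta = ((p - y) / B)[:, None]
    else:
        raise ValueError(f"unknown loss kind {loss_kind!r}")

    grads = [None] * len(layers)
    for li in range(len(layers) - 1, -1, -1):
        a_prev = activations[li]
        grads[li] = (a_prev.T @ delta, delta.sum(axis=0))
        if li > 0:
            W, _ = layers[li]
            delta = (delta @ W.T) * (pre[li - 1] > 0.0)

    out = np.empty(parameter_count(spec))
    pos = 0
    for gW, gb in grads:
        out[pos : pos + gW.size] = gW.ravel()
        pos += gW.size
        out[pos : pos + gb.size] = gb
        pos += gb.size
    return out


def train_gradient(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    cfg: GradientTrainerConfig,
    optimizer: str = "sgdm",
    init: np.ndarray | None = None,
    loss_kind: str = "bce",
) -> tuple[np.ndarray, dict]:
    """Mini-batch training loop with seeded per-epoch shuffling.

    Cross-entropy is the default objective here (the conventional choice
    for gradient-trained classifiers; the population optimizers minimize
    MSE fitness instead).  Returns the final flat weights and a history
    dict with per-epoch training ``loss`` and ``accuracy``.
    """
    if optimizer not in ("sgdm", "adam"):
        raise ValueError(f"unknown optimizer {optimizer!r}; use 'sgdm' or 'adam'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(cfg.seed)
    n_params = parameter_count(spec)
    w = init_weights(spec, rng) if init is None else np.asarray(init, dtype=float).copy()

    velocity = np.zeros(n_params)
    adam = AdamState.zeros(n_params)
    history = {"loss": [], "accuracy": []}
    N = y.size
    for _ in range(cfg.epochs):
        order = rng.permutation(N)
        for start in range(0, N, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            g = backprop_gradient(spec, w, X[idx], y[idx], loss_kind=loss_kind)
            if optimizer == "sgdm":
                w, velocity = sgdm_step(w, g, velocity, cfg)
            else:
                w, adam = adam_step(w, g, adam, cfg)
        history["loss"].append(network_loss(spec, w, X, y, kind=loss_kind))
        history["accuracy"].append(float(np.mean(predict(spec, w, X) == y)))
    return w, history
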