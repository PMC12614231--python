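"""Minimal fully-connected network core on numpy.

Shared by the deep-ensemble members (point networks trained on MSE +
L2) and the mean-field variational network (which samples its weights
through this forward/backward machinery).  float32 throughout; all
randomness comes from explicitly passed Generators.
"""
from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

Weights = List[Tuple[np.ndarray, np.ndarray]]  # [(W, b), ...]


def layer_dims(input_dim: int, hidden_layers: int, hidden_width: int, output_dim: int):
    return [input_dim] + [hidden_width] * hidden_layers + [output_dim]


def init_weights(dims: Sequence[int], rng: np.random.Generator) -> Weights:
    """Glorot-normal initialization (suits tanh hidden units)."""
    ws = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        sd = np.sqrt(2.0 / (fan_in + fan_out))
        W = rng.normal(0.0, sd, size=(fan_in, fan_out)).astype(np.float32)
        b = np.zeros(fan_out, dtype=np.float32)
        ws.append((W, b))
    return ws


def forward(weights: Weights, X: np.ndarray, return_cache: bool = False):
    """Forward pass: tanh hidden layers, linear output."""
    h = X.astype(np.float32, copy=False)
    cache = [h]
    for i, (W, b) in enumerate(weights):
        z = h @ W + b
        h = np.tanh(z) if i < len(weights) - 1 else z
        if return_cache:
            cache.append(h)
    return (h, cache) if return_cache else h


def backward(weights: Weights, cache: List[np.ndarray], grad_out: np.ndarray) -> Weights:
    """Backprop an output-gradient through the cached activations.

    ``grad_out`` is dLoss/d(output), shape (batch, output_dim).  Returns
    gradients with the same structure as ``weights`` (no L2 term).
    """
    grads: Weights = [None] * len(weights)  # type: ignore[list-item]
    delta = grad_out.astype(np.float32, copy=False)
    for i in range(len(weights) - 1, -1, -1):
        h_prev = cache[i]
        grads[i] = (h_prev.T @ delta, delta.sum(axis=0))
        if i > 0:
            W, _ = weights[i]
            delta = (delta @ W.T) * (1.0 - cache[i] ** 2)
    return grads


class Adam:
    """Adam optimizer over a flat list of arrays (updated in place)."""

    def __init__(self, arrays: List[np.ndarray], lr: float = 2e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def flatten(weights: Weights) -> List[np.ndarray]:
    out: List[np.ndarray] = []
    for W, b in weights:
        out.extend((W, b))
    return out


def unflatten(arrays: Sequence[np.ndarray]) -> Weights:
    return [(arrays[i], arrays[i + 1]) for i in range(0, len(arrays), 2)]


def clone(weights: Weights) -> Weights:
    return [(W.copy(), b.copy()) for W, b in weights]


def mse(weights: Weights, X: np.ndarray, y: np.ndarray) -> float:
    pred = forward(weights, X)
    return float(np.mean((pred - y) ** 2))


def train_point_network(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    dims: Sequence[int],
    rng: np.random.Generator,
    *,
    lr: float = 2e-3,
    batch_size: int = 512,
    max_epochs: int = 200,
    patience: int = 15,
    weight_decay: float = 1e-4,
) -> Tuple[Weights, dict]:
    """Train a point network on MSE + L2 with early stopping.

    Early stopping monitors MSE on the supplied validation split; the
    best-validation weights are restored.  Returns (weights, history)
    where history holds per-epoch training and validation MSE.
    """
    X = X.astype(np.float32)
    y = y.astype(np.float32)
    X_val = X_val.astype(np.float32)
    y_val = y_val.astype(np.float32)
    n = len(X)
    weights = init_weights(dims, rng)
    flat = flatten(weights)
    opt = Adam(flat, lr=lr)
    best_val = np.inf
    best_weights = clone(weights)
    bad_epochs = 0
    hist = {"train_mse": [], "val_mse": []}
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], y[idx]
            pred, cache = forward(weights, xb, return_cache=True)
            err = pred - yb
            ep_loss += float(np.sum(err**2)) / y.shape[1]
            grad_out = (2.0 / (len(xb) * y.shape[1])) * err
            grads = backward(weights, cache, grad_out)
            gflat = flatten(grads)
            if weight_decay:
                for a, g in zip(flat, gflat):
                    g += 2.0 * weight_decay * a
            opt.step(gflat)
        train_mse = ep_loss / n
        val_mse = mse(weights, X_val, y_val)
        if not np.isfinite(val_mse) or not np.isfinite(train_mse):
            raise FloatingPointError(
                f"non-finite loss at epoch {_epoch}: train={train_mse} val={val_mse}"
            )
        hist["train_mse"].append(train_mse)
        hist["val_mse"].append(val_mse)
        if val_mse < best_val - 1e-7:
            best_val = val_mse
            best_weights = clone(weights)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    hist["best_val_mse"] = best_val
    return best_weights, hist


# ---------------------------------------------------------------------------
# mean-field variational machinery


def gaussian_kl(
    mu_q: np.ndarray, sd_q: np.ndarray, mu_p: float, sd_p: float
) -> float:
    """Closed-form KL( N(mu_q, sd_q^2) || N(mu_p, sd_p^2) ), summed over elements."""
    var_q = sd_q.astype(np.float64) ** 2
    return float(
        np.sum(
            np.log(sd_p / sd_q.astype(np.float64))
            + (var_q + (mu_q.astype(np.float64) - mu_p) ** 2) / (2.0 * sd_p**2)
            - 0.5
        )
    )
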