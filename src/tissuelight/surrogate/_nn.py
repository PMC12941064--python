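"""Minimal dense-network engine for the reflectance surrogate.

A fully connected multilayer perceptron with leaky-ReLU hidden activations,
a logistic output unit, Kaiming-normal initialization, mean-squared-error
loss, AdamW (decoupled weight decay) and a halve-on-plateau learning-rate
schedule.  Written against NumPy in 32-bit precision; small enough to audit,
fast enough for the problem sizes used here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "AdamW", "PlateauScheduler", "parameter_count"]


def parameter_count(input_dim: int, hidden_units: int, hidden_layers: int) -> int:
    """Closed-form trainable parameter count of the MLP.

    input->h1, (hidden_layers - 1) h->h blocks, h->1 output; biases included.
    """
    return (
        input_dim * hidden_units + hidden_units
        + (hidden_layers - 1) * (hidden_units * hidden_units + hidden_units)
        + hidden_units + 1
    )


def _leaky(x, slope):
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(x, slope):
    return np.where(x >= 0, 1.0, slope).astype(x.dtype)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLP:
    """Dense net: hidden leaky-ReLU layers plus a logistic scalar output."""

    def __init__(self, input_dim: int, hidden_units: int, hidden_layers: int,
                 leaky_slope: float = 0.2, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        self.input_dim = input_dim
        self.hidden_units = hidden_units
        self.hidden_layers = hidden_layers
        self.leaky_slope = float(leaky_slope)
        self.dtype = dtype
        rng = rng or np.random.default_rng()
        dims = [input_dim] + [hidden_units] * hidden_layers + [1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        gain2 = 2.0 / (1.0 + leaky_slope**2)  # Kaiming-normal for leaky ReLU
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            std = np.sqrt(gain2 / fan_in)
            self.weights.append(rng.normal(0.0, std, (fan_in, fan_out)).astype(dtype))
            self.biases.append(np.zeros(fan_out, dtype=dtype))

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def parameters(self):
        return self.weights + self.biases

    def forward(self, x: np.ndarray, cache: bool = False):
        """Batch forward pass; returns predictions in (0, 1), shape (n,)."""
        h = np.asarray(x, dtype=self.dtype)
        pre_acts, acts = [], [h]
        for i in range(self.hidden_layers):
            z = h @ self.weights[i] + self.biases[i]
            h = _leaky(z, self.leaky_slope)
            if cache:
                pre_acts.append(z)
                acts.append(h)
        z_out = h @ self.weights[-1] + self.biases[-1]
        y = _sigmoid(z_out)[:, 0]
        if cache:
            self._cache = (pre_acts, acts, y)
        return y

    def backward(self, x: np.ndarray, target: np.ndarray):
        """MSE loss and its gradients; uses the cache of forward(cache=True)."""
        pre_acts, acts, y = self._cache
        n = y.shape[0]
        target = np.asarray(target, dtype=self.dtype)
        err = y - target
        loss = float(np.mean(err**2))
        # d loss / d z_out through the logistic unit
        delta = (2.0 / n) * err * y * (1.0 - y)
        delta = delta[:, None].astype(self.dtype)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        grads_w[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        for i in range(self.hidden_layers - 1, -1, -1):
            delta = (delta @ self.weights[i + 1].T) * _leaky_grad(pre_acts[i], self.leaky_slope)
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
        return loss, grads_w + grads_b

    def get_state(self) -> dict:
        state = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            state[f"w{i}"] = w.copy()
            state[f"b{i}"] = b.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i in range(len(self.weights)):
            self.weights[i] = np.asarray(state[f"w{i}"], dtype=self.dtype)
            self.biases[i] = np.asarray(state[f"b{i}"], dtype=self.dtype)


class AdamW:
    """Adam with decoupled weight decay (weights only, not biases exempted)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-3):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if p.ndim > 1 and self.weight_decay:
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * update


class PlateauScheduler:
    """Halve the learning rate when the validation loss stops improving."""

    def __init__(self, optimizer: AdamW, patience: int = 20, factor: float = 0.5,
                 min_lr: float = 1e-8, rel_threshold: float = 1e-4):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.rel_threshold = rel_threshold
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> None:
        if val_loss < self.best * (1.0 - self.rel_threshold):
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
                # judge the new learning rate against its own starting point,
                # not a lucky noise spike from the previous phase
                self.best = val_loss
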