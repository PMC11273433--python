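"""Minimal dense-network primitives with explicit backprop.

Fully connected stacks, standard activations, Glorot initialization, and the
two optimizers the pipeline trains with (SGD with classical momentum and
weight decay; Adamax). Everything is plain numpy: parameters live in dicts
of arrays, gradients are returned in matching dicts, and forward passes are
pure functions of (input, params), which keeps runs bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7  # probability clamp, keeps log() finite


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    # numerically stable piecewise form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood; y holds integer class indices."""
    p = np.clip(probs[np.arange(len(y)), y], EPS, None)
    return float(-np.mean(np.log(p)))


class MLP:
    """A fully connected stack with ReLU hidden units and a configurable
    final activation ('tanh', 'sigmoid' or 'linear').

    Parameters are held as ``{"W0": ..., "b0": ..., "W1": ...}``; ``forward``
    optionally records a cache that ``backward`` consumes.
    """

    def __init__(
        self,
        widths: list[int],
        final_activation: str = "linear",
        hidden_activation: str = "relu",
        leak: float = 0.2,
    ):
        # widths includes the input width: [in, h1, ..., out]
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.widths = list(widths)
        self.final_activation = final_activation
        self.hidden_activation = hidden_activation
        self.leak = leak

    @property
    def n_layers(self) -> int:
        return len(self.widths) - 1

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        params = {}
        for i in range(self.n_layers):
            params[f"W{i}"] = glorot_uniform(rng, self.widths[i], self.widths[i + 1])
            params[f"b{i}"] = np.zeros(self.widths[i + 1])
        return params

    def forward(
        self, x: np.ndarray, params: dict, cache: list | None = None
    ) -> np.ndarray:
        h = np.asarray(x, dtype=float)
        if h.ndim == 1:
            h = h[None, :]
        for i in range(self.n_layers):
            z = h @ params[f"W{i}"] + params[f"b{i}"]
            last = i == self.n_layers - 1
            if not last:
                if self.hidden_activation == "lrelu":
                    a = np.where(z > 0, z, self.leak * z)
                else:
                    a = relu(z)
            elif self.final_activation == "tanh":
                a = np.tanh(z)
            elif self.final_activation == "sigmoid":
                a = sigmoid(z)
            else:
                a = z
            if cache is not None:
                cache.append((h, z, a))
            h = a
        return h

    def backward(
        self, dout: np.ndarray, params: dict, cache: list
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Backprop ``dout`` (gradient w.r.t. the stack output) through the
        cached forward pass; returns (dinput, param gradients)."""
        grads: dict[str, np.ndarray] = {}
        d = np.asarray(dout, dtype=float)
        for i in reversed(range(self.n_layers)):
            h, z, a = cache[i]
            last = i == self.n_layers - 1
            if not last:
                if self.hidden_activation == "lrelu":
                    dz = d * np.where(z > 0, 1.0, self.leak)
                else:
                    dz = d * (z > 0)
            elif self.final_activation == "tanh":
                dz = d * (1.0 - a**2)
            elif self.final_activation == "sigmoid":
                dz = d * a * (1.0 - a)
            else:
                dz = d
            grads[f"W{i}"] = h.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            d = dz @ params[f"W{i}"].T
        return d, grads


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight
    decay (decay applied to weight matrices, not biases)."""

    def __init__(self, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        for name, g in grads.items():
            if self.weight_decay and not name.startswith("b"):
                g = g + self.weight_decay * params[name]
            v = self._velocity.get(name)
            if v is None:
                v = np.zeros_like(params[name])
            v = self.momentum * v - self.lr * g
            self._velocity[name] = v
            params[name] += v


class Adamax:
    """Adamax (Adam with an infinity-norm second moment)."""

    def __init__(
        self,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self._m: dict[str, np.ndarray] = {}
        self._u: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self._t += 1
        for name, g in grads.items():
            if self.weight_decay and not name.startswith("b"):
                g = g + self.weight_decay * params[name]
            m = self._m.get(name, np.zeros_like(params[name]))
            u = self._u.get(name, np.zeros_like(params[name]))
            m = self.beta1 * m + (1 - self.beta1) * g
            u = np.maximum(self.beta2 * u, np.abs(g))
            self._m[name] = m
            self._u[name] = u
            params[name] -= (
                self.lr / (1 - self.beta1**self._t) * m / (u + self.eps)
            )


def make_optimizer(name: str, lr: float, weight_decay: float = 0.0, momentum: float = 0.9):
    name = name.lower()
    if name == "sgd":
        return SGD(lr, momentum=momentum, weight_decay=weight_decay)
    if name == "adamax":
        return Adamax(lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}")
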