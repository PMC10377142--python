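"""Minimal numpy neural-network primitives: dense layers, embeddings,
activations, and an Adam optimizer.

The models in this package are small (thousands of parameters), so the
forward/backward passes are written directly in numpy; each layer caches
what its backward pass needs and accumulates gradients in place.
"""

from __future__ import annotations

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def identity(x):
    return x


ACTIVATIONS = {"relu": relu, "sigmoid": sigmoid, "identity": identity}


def _act_grad(name, out):
    """d activation / d pre-activation, expressed through the output."""
    if name == "relu":
        return (out > 0).astype(float)
    if name == "sigmoid":
        return out * (1.0 - out)
    if name == "identity":
        return np.ones_like(out)
    raise ValueError(f"unknown activation {name!r}")


def glorot_uniform(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Dense:
    """Fully connected layer y = act(x @ W + b)."""

    def __init__(self, n_in, n_out, activation, rng, bias=True):
        self.W = glorot_uniform(rng, n_in, n_out)
        self.b = np.zeros(n_out) if bias else None
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x = self._out = None

    def forward(self, x):
        pre = x @ self.W
        if self.b is not None:
            pre = pre + self.b
        self._x = x
        self._out = ACTIVATIONS[self.activation](pre)
        return self._out

    def backward(self, dout):
        dpre = dout * _act_grad(self.activation, self._out)
        self.dW += self._x.T @ dpre
        if self.b is not None:
            self.db += dpre.sum(axis=0)
        return dpre @ self.W.T

    def parameters(self):
        if self.b is None:
            return [(self.W, self.dW)]
        return [(self.W, self.dW), (self.b, self.db)]


class Embedding:
    """Lookup table with scatter-add gradient accumulation."""

    def __init__(self, n_entities, dim, rng):
        self.E = glorot_uniform(rng, n_entities, dim)
        self.dE = np.zeros_like(self.E)
        self._idx = None

    def forward(self, idx):
        self._idx = idx
        return self.E[idx]

    def backward(self, dout):
        np.add.at(self.dE, self._idx, dout)

    def parameters(self):
        return [(self.E, self.dE)]


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


def bce_loss_and_grad(p, y, eps=1e-12):
    """Binary cross-entropy (mean) and its gradient wrt the sigmoid logit."""
    p = np.clip(p, eps, 1 - eps)
    loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    dlogit = (p - y) / len(y)
    return loss, dlogit
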