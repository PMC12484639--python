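"""Minimal feed-forward network with manual backprop and Adam.

Small multilayer perceptrons (a few hundred units, tabular inputs) are all
this pipeline needs, so the forward/backward passes are written directly in
numpy: `Linear` layers with ReLU between them, explicit caches, and an Adam
optimizer over the flat parameter list.  Everything is seeded through
``numpy.random.Generator`` for end-to-end determinism on CPU.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """Fully connected net: Linear -> ReLU -> ... -> Linear (no final activation)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = list(sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, suited to the ReLU hidden units
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (output, cache of layer inputs) for use in backward()."""
        cache = []
        h = np.asarray(X, dtype=float)
        for i in range(self.n_layers):
            cache.append(h)
            h = h @ self.W[i] + self.b[i]
            if i < self.n_layers - 1:
                h = np.maximum(h, 0.0)
        return h, cache

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(
        self, cache: list[np.ndarray], grad_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Backprop ``grad_out`` (dL/d output); returns (dW, db, dX)."""
        dW = [np.empty(0)] * self.n_layers
        db = [np.empty(0)] * self.n_layers
        g = grad_out
        for i in range(self.n_layers - 1, -1, -1):
            h_in = cache[i]
            if i < self.n_layers - 1:
                # ReLU mask of this layer's output: recompute pre-activation sign
                pre = h_in @ self.W[i] + self.b[i]
                g = g * (pre > 0)
            dW[i] = h_in.T @ g
            db[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return dW, db, g

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def grads_to_list(self, dW: list[np.ndarray], db: list[np.ndarray]) -> list[np.ndarray]:
        return dW + db


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def normalize_rows(U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """L2-normalize rows; returns (Z, norms). Zero rows pass through a floor."""
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    return U / norms, norms


def normalize_rows_backward(
    U: np.ndarray, Z: np.ndarray, norms: np.ndarray, dZ: np.ndarray
) -> np.ndarray:
    """Backprop through row L2 normalization."""
    dot = (dZ * Z).sum(axis=1, keepdims=True)
    return (dZ - dot * Z) / norms
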