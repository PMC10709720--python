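"""Minimal feed-forward network machinery with hand-written backpropagation.

Only what the survival networks need: dense layers, ReLU, inverted dropout,
and SGD with momentum.  Everything is float64 numpy and fully deterministic
given a seeded Generator, so fitted models are bitwise reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "SGD"]


class Dense:
    """Affine layer y = x W + b with cached input for the backward pass."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he"):
        if init == "he":
            sd = np.sqrt(2.0 / n_in)
            self.W = rng.normal(0.0, sd, (n_in, n_out))
        elif init == "identity":
            self.W = np.eye(n_in, n_out)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        # in-place so optimizer-held (param, grad) views stay valid
        self.gW[...] = self._x.T @ grad_out
        self.gb[...] = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class MLP:
    """Dense stack with ReLU between layers and optional inverted dropout.

    ``hidden=[]`` makes the network a single affine map (or, with
    ``init="identity"`` and equal widths, the identity at initialization).
    """

    def __init__(self, n_in: int, hidden: list, n_out: int,
                 rng: np.random.Generator, dropout: float = 0.0,
                 init: str = "he"):
        widths = [n_in] + list(hidden) + [n_out]
        self.layers = [Dense(widths[i], widths[i + 1], rng, init=init)
                       for i in range(len(widths) - 1)]
        self.dropout = float(dropout)
        self._masks = None

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = False) -> np.ndarray:
        self._masks = []
        h = x
        for i, layer in enumerate(self.layers):
            h = layer.forward(h)
            if i < len(self.layers) - 1:
                mask = (h > 0).astype(float)
                h = h * mask
                if train and self.dropout > 0.0:
                    keep = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * keep
                    mask = mask * keep
                self._masks.append(mask)
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                g = g * self._masks[i]
            g = self.layers[i].backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self):
        for layer in self.layers:
            layer.gW[...] = 0.0
            layer.gb[...] = 0.0


class SGD:
    """SGD with classical momentum, weight decay and global-norm clipping.

    Clipping guards against the unbounded directions of the Cox partial
    likelihood (risk separation within a batch can push the linear predictor
    to infinity); weight decay keeps the predictor scale identified.
    """

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_grad: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.clip_grad = float(clip_grad)
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self):
        scale = 1.0
        if self.clip_grad > 0:
            total = np.sqrt(sum(float((g * g).sum()) for _, g in self.params))
            if total > self.clip_grad:
                scale = self.clip_grad / total
        for i, (p, g) in enumerate(self.params):
            step_g = g * scale + self.weight_decay * p
            self.v[i] = self.momentum * self.v[i] - self.lr * step_g
            p += self.v[i]
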