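"""Minimal feed-forward neural-network engine (NumPy).

Supports exactly what the translation models need: dense layers, a
convolution that slides along the gene axis only (kernel K x 1 over a
genes x time x channels block), floor-division max pooling on the gene axis,
ReLU/sigmoid/linear activations, L1 activity regularization on chosen
layers, mean-absolute-error loss, and Adam. Everything is seeded and
single-threaded, so training is bit-reproducible.

No autodiff framework is available in the runtime environment, so gradients
are written out by hand and checked against finite differences in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["Dense", "ConvGenes", "MaxPoolGenes", "Flatten", "Network", "AdamState"]


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "linear":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0.0).astype(z.dtype)
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "linear":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {kind!r}")


class Dense:
    """Fully connected layer with optional L1 activity regularization on the
    post-activation output."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        activation: str = "relu",
        activity_l1: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        if activation == "relu":
            scale = np.sqrt(2.0 / in_dim)  # He init
        else:
            scale = np.sqrt(1.0 / in_dim)  # Glorot-ish
        self.W = rng.normal(0.0, scale, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.activation = activation
        self.activity_l1 = float(activity_l1)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._z = x @ self.W + self.b
        self._a = _activate(self._z, self.activation)
        return self._a

    def backward(self, da: np.ndarray) -> np.ndarray:
        n = da.shape[0]
        if self.activity_l1:
            da = da + self.activity_l1 * np.sign(self._a) / n
        dz = da * _activate_grad(self._z, self._a, self.activation)
        self.dW = self._x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]

    def activity_penalty(self) -> float:
        if not self.activity_l1:
            return 0.0
        return self.activity_l1 * float(np.abs(self._a).sum()) / self._a.shape[0]


class ConvGenes:
    """Convolution along the gene axis of a (N, G, T, C) block.

    Kernel is K x 1: it mixes K neighbouring genes within a single time
    column. Same-padding keeps the gene-axis length, so small gene sets stay
    admissible.
    """

    def __init__(
        self,
        kernel: int,
        in_channels: int,
        filters: int,
        activation: str = "relu",
        activity_l1: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = kernel * in_channels
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, in_channels, filters))
        self.b = np.zeros(filters)
        self.kernel = kernel
        self.activation = activation
        self.activity_l1 = float(activity_l1)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _pad(self) -> tuple[int, int]:
        # Keras-style 'same' for stride 1
        return (self.kernel - 1) // 2, self.kernel // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, g, t, c = x.shape
        lo, hi = self._pad()
        xp = np.pad(x, ((0, 0), (lo, hi), (0, 0), (0, 0)))
        self._in_shape = x.shape
        # im2col: one matmul instead of a loop of per-offset products
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 3)).reshape(
            n * g * t, self.kernel * c
        )
        self._cols = cols
        f = self.W.shape[2]
        z = (cols @ self.W.reshape(self.kernel * c, f) + self.b).reshape(n, g, t, f)
        self._z = z
        self._a = _activate(z, self.activation)
        return self._a

    def backward(self, da: np.ndarray) -> np.ndarray:
        n, g, t, c = self._in_shape
        if self.activity_l1:
            da = da + self.activity_l1 * np.sign(self._a) / n
        dz = da * _activate_grad(self._z, self._a, self.activation)
        f = self.W.shape[2]
        dz_flat = dz.reshape(n * g * t, f)
        self.dW = (self._cols.T @ dz_flat).reshape(self.kernel, c, f)
        self.db = dz_flat.sum(axis=0)
        dcols = (dz_flat @ self.W.reshape(self.kernel * c, f).T).reshape(
            n, g, t, self.kernel, c
        )
        lo, hi = self._pad()
        dxp = np.zeros((n, g + self.kernel - 1, t, c))
        for k in range(self.kernel):
            dxp[:, k : k + g] += dcols[:, :, :, k, :]
        return dxp[:, lo : lo + g]

    def params(self):
        return [("W", self), ("b", self)]

    def activity_penalty(self) -> float:
        if not self.activity_l1:
            return 0.0
        return self.activity_l1 * float(np.abs(self._a).sum()) / self._a.shape[0]


class MaxPoolGenes:
    """Max pooling of size ``pool`` x 1 along the gene axis; trailing genes
    that do not fill a window are dropped (floor division)."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, g, t, c = x.shape
        g_out = g // self.pool
        trimmed = x[:, : g_out * self.pool].reshape(n, g_out, self.pool, t, c)
        self._argmax = trimmed.argmax(axis=2)
        self._in_shape = x.shape
        return trimmed.max(axis=2)

    def backward(self, da: np.ndarray) -> np.ndarray:
        n, g, t, c = self._in_shape
        g_out = g // self.pool
        dx = np.zeros((n, g_out, self.pool, t, c))
        idx = np.indices((n, g_out, t, c))
        dx[idx[0], idx[1], self._argmax, idx[2], idx[3]] = da
        out = np.zeros(self._in_shape)
        out[:, : g_out * self.pool] = dx.reshape(n, g_out * self.pool, t, c)
        return out

    def params(self):
        return []

    def activity_penalty(self) -> float:
        return 0.0


class Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, da: np.ndarray) -> np.ndarray:
        return da.reshape(self._in_shape)

    def params(self):
        return []

    def activity_penalty(self) -> float:
        return 0.0


@dataclass
class AdamState:
    """Per-parameter Adam moments."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: Sequence[tuple[str, object]]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, (name, layer) in enumerate(params):
            key = (i, name)
            grad = getattr(layer, "d" + name)
            if key not in self.m:
                self.m[key] = np.zeros_like(grad)
                self.v[key] = np.zeros_like(grad)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad**2
            update = self.lr * (self.m[key] / b1c) / (np.sqrt(self.v[key] / b2c) + self.eps)
            setattr(layer, name, getattr(layer, name) - update)


class Network:
    """A sequential stack trained with Adam on MAE + L1 activity penalties."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    predict = forward

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def loss(self, pred: np.ndarray, y: np.ndarray) -> float:
        mae = float(np.mean(np.abs(pred - y)))
        return mae + sum(layer.activity_penalty() for layer in self.layers)

    def _backward_from_loss(self, pred: np.ndarray, y: np.ndarray) -> None:
        grad = np.sign(pred - y) / pred.size
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        adam: AdamState,
        rng: np.random.Generator,
        callback: Callable[[int, float], None] | None = None,
    ) -> list[float]:
        """Mini-batch Adam; returns the per-epoch mean training loss."""
        n = x.shape[0]
        history: list[float] = []
        params = self.parameters()
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                pred = self.forward(x[idx])
                loss = self.loss(pred, y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {start // batch_size}: {loss}"
                    )
                self._backward_from_loss(pred, y[idx])
                adam.step(params)
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if callback is not None:
                callback(epoch, history[-1])
        return history

    # --------------------------------------------------------- weight access

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for name, layer in self.parameters():
            out.append(getattr(layer, name).copy())
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for (name, layer), w in zip(params, weights):
            current = getattr(layer, name)
            if current.shape != w.shape:
                raise ValueError(f"shape mismatch for {name}: {current.shape} vs {w.shape}")
            setattr(layer, name, w.copy())
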