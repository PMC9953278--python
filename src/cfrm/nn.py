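"""Minimal numpy CNN engine for hyperspectral crops.

Implements exactly the layer kinds the stage classifier needs — grouped
1x1 convolutions (per-pixel channel mixing in groups), plain 3x3
convolutions, ReLU, global average pooling, and dense layers — with
hand-written backpropagation and an Adam optimizer.  Tensors are
channels-last ``(batch, height, width, channels)`` float32.

Grouped 1x1 convolutions are the cheap way to collapse 1600 spectral
channels: each group mixes only its slice of channels, cutting the weight
count by the group factor while still learning which wavenumber ranges
matter.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GroupedConv1x1",
    "Conv3x3",
    "ReLU",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_loss_and_grad",
]

_DT = np.float32


class Layer:
    """Base layer: parameter-free unless overridden."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class GroupedConv1x1(Layer):
    """1x1 convolution with channel groups: (B,H,W,Cin) -> (B,H,W,Cout)."""

    def __init__(self, cin: int, cout: int, groups: int, rng: np.random.Generator):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError(
                f"groups={groups} must divide both cin={cin} and cout={cout}"
            )
        self.cin, self.cout, self.groups = cin, cout, groups
        std = np.sqrt(2.0 / (cin / groups))
        self.w = rng.normal(0.0, std, size=(groups, cin // groups, cout // groups)).astype(_DT)
        self.b = np.zeros(cout, dtype=_DT)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, _ = x.shape
        self._xr = x.reshape(-1, self.groups, self.cin // self.groups)
        y = np.einsum("ngi,gio->ngo", self._xr, self.w, optimize=True)
        self._shape = (b, h, w)
        return y.reshape(b, h, w, self.cout) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dyr = dout.reshape(-1, self.groups, self.cout // self.groups)
        self.grads[0][...] = np.einsum("ngi,ngo->gio", self._xr, dyr, optimize=True)
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        dx = np.einsum("ngo,gio->ngi", dyr, self.w, optimize=True)
        b, h, w = self._shape
        return dx.reshape(b, h, w, self.cin)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero 'same' padding, no grouping."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (9 * cin))
        # weight layout matches im2col patch layout (3, 3, cin) flattened
        self.w = rng.normal(0.0, std, size=(9 * cin, cout)).astype(_DT)
        self.b = np.zeros(cout, dtype=_DT)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        view = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (B,H,W,C,3,3)
        cols = np.ascontiguousarray(np.moveaxis(view, 3, 5)).reshape(b * h * w, 9 * c)
        self._cols, self._shape = cols, (b, h, w, c)
        y = cols @ self.w + self.b
        return y.reshape(b, h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        dyr = dout.reshape(b * h * w, self.cout)
        self.grads[0][...] = self._cols.T @ dyr
        self.grads[1][...] = dyr.sum(axis=0)
        dcols = (dyr @ self.w.T).reshape(b, h, w, 3, 3, c)
        dxp = np.zeros((b, h + 2, w + 2, c), dtype=_DT)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class GlobalAvgPool(Layer):
    """(B,H,W,C) -> (B,C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(_DT)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, std, size=(cin, cout)).astype(_DT)
        self.b = np.zeros(cout, dtype=_DT)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def param_checksum(self) -> float:
        """Order-dependent checksum for identity comparisons across builds."""
        total = 0.0
        for i, p in enumerate(self.params):
            total += float(np.sum(np.abs(p.astype(np.float64)))) * (1.0 + 0.01 * i)
        return total

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    """Adam with bias correction; lr=0 leaves parameters untouched."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-300))))
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(_DT)
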