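"""Minimal NumPy CNN: layers, softmax cross-entropy, SGD.

Implements exactly what the feature extractor needs — 3x3 same-padded
convolution (im2col + matmul), ReLU, 2x2 max-pooling, dense layers,
inverted dropout — with explicit backward passes and a plain SGD update.
All parameters are float32; every random draw (init, dropout) comes from a
Generator owned by the network, so training is bit-reproducible per seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    params: list  # list of [name, value, grad]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded k x k convolution over NHWC tensors."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.W = _he_init(rng, (k * k * in_ch, out_ch), k * k * in_ch)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [["W", self.W, self.dW], ["b", self.b, self.db]]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C)
        v = sliding_window_view(xp, (k, k), axis=(1, 2))
        v = v.transpose(0, 1, 2, 4, 5, 3)
        return np.ascontiguousarray(v).reshape(-1, k * k * x.shape[3])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        n, h, w, _ = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape
        g = grad.reshape(-1, self.out_ch)
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, h, w, self.k, self.k, self.in_ch)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.in_ch), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; odd trailing rows/columns are cropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        # split gradient equally among tied maxima
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, grad):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        g = self._mask * grad[:, :, None, :, None, :]
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : 2 * h2, : 2 * w2, :] = g.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [["W", self.W, self.dW], ["b", self.b, self.db]]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean categorical cross-entropy and its gradient wrt logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Network:
    """A plain layer stack with optional activation capture."""

    def __init__(self, layers: list[Layer], feature_layers: tuple[int, ...] = ()):
        self.layers = layers
        self.feature_layers = feature_layers

    def forward(self, x: np.ndarray, train: bool = False, capture: bool = False):
        captured = []
        out = x.astype(np.float32)
        for i, layer in enumerate(self.layers):
            out = layer.forward(out, train)
            if capture and i in self.feature_layers:
                captured.append(out)
        return (out, captured) if capture else out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self):
        for layer in self.layers:
            yield from layer.params

    def get_weights(self) -> list[np.ndarray]:
        return [p[1].copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (_, value, _), w in zip(self.parameters(), weights):
            value[...] = w


class SGD:
    def __init__(self, network: Network, lr: float, momentum: float = 0.0):
        self.network = network
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p[1]) for p in network.parameters()]

    def step(self) -> None:
        for v, (_, value, grad) in zip(self._velocity, self.network.parameters()):
            if self.momentum:
                v *= self.momentum
                v -= self.lr * grad
                value += v
            else:
                value -= self.lr * grad
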