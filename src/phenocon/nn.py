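"""Minimal numpy neural-network core: layers, backprop, RMSProp.

Channels-first convention: inputs to convolutional stacks are (M, C, H, W)
float32 arrays.  Each layer caches what its backward pass needs; ``Sequential``
chains them.  Deterministic given the generators passed to stochastic layers.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer; parameters and their gradients are parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3×3-style convolution via im2col; stride 1, symmetric zero padding."""

    def __init__(self, cin: int, cout: int, k: int, pad: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k, self.pad = cin, cout, k, pad
        fan_in = cin * k * k
        W = rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, cout)).astype(np.float32)
        b = np.zeros(cout, dtype=np.float32)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (M, C, Ho, Wo, k, k) -> (M, Ho, Wo, C*k*k)
        m, c, ho, wo = win.shape[:4]
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            m, ho, wo, c * k * k
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._xshape = x.shape
        self._cols = self._im2col(x)  # (M, Ho, Wo, fan_in)
        W, b = self.params
        out = self._cols @ W + b  # (M, Ho, Wo, cout)
        return out.transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        W, _ = self.params
        g = gout.transpose(0, 2, 3, 1)  # (M, Ho, Wo, cout)
        m, ho, wo, _ = g.shape
        gf = g.reshape(-1, self.cout)
        cols = self._cols.reshape(-1, W.shape[0])
        self.grads[0][...] = cols.T @ gf
        self.grads[1][...] = gf.sum(axis=0)
        dcols = (gf @ W.T).reshape(m, ho, wo, self.cin, self.k, self.k)
        # col2im: scatter-add the k*k shifted views
        _, c, h, w = self._xshape
        p = self.pad
        dx = np.zeros((m, c, h + 2 * p, w + 2 * p), dtype=gout.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                dx[:, :, di : di + ho, dj : dj + wo] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dx[:, :, p : p + h, p : p + w] if p else dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class AvgPool2(Layer):
    """2×2 average pooling, stride 2; input H, W must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        m, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(m, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        m, c, h, w = self._shape
        g = gout[:, :, :, None, :, None] / 4.0
        return np.broadcast_to(
            g, (m, c, h // 2, 2, w // 2, 2)
        ).reshape(m, c, h, w).copy()


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        W = rng.normal(0, np.sqrt(2.0 / nin), size=(nin, nout)).astype(np.float32)
        b = np.zeros(nout, dtype=np.float32)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        W, b = self.params
        return x @ W + b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        W, _ = self.params
        self.grads[0][...] = self._x.T @ gout
        self.grads[1][...] = gout.sum(axis=0)
        return gout @ W.T


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


class L2Norm(Layer):
    """Row-wise L2 normalization: y = x / ||x||."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._norm = np.linalg.norm(x, axis=1, keepdims=True)
        self._norm = np.maximum(self._norm, 1e-12)
        self._y = x / self._norm
        return self._y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        y = self._y
        return (gout - y * (y * gout).sum(axis=1, keepdims=True)) / self._norm


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads))
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[i]
                i += 1


class RMSProp:
    """Momentum-free adaptive optimizer (gradient-RMS scaling)."""

    def __init__(self, net: Sequential, lr: float, decay: float = 0.9, eps: float = 1e-8):
        self.pairs = net.parameters()
        self.lr, self.decay, self.eps = lr, decay, eps
        self.cache = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self) -> None:
        for (p, g), c in zip(self.pairs, self.cache):
            c *= self.decay
            c += (1 - self.decay) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
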