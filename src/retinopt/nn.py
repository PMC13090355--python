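"""Minimal CPU-native neural-network layers with manual backprop.

Just enough machinery — conv / pool / dense layers, sigmoid and ReLU,
dropout, and the SGD / Adam / RMSprop update rules — to assemble and train
the dual-stream classifier on small inputs without a GPU framework.
Tensors are numpy arrays in NHWC layout; every layer implements
``forward(x, train)`` and ``backward(grad)``, accumulating parameter
gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    trainable = False

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    trainable = False

    def forward(self, x, train=False):
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dropout(Layer):
    trainable = False

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class AvgPool(Layer):
    """Non-overlapping average pooling by an integer factor (NHWC)."""

    trainable = False

    def __init__(self, factor: int):
        super().__init__()
        self.f = factor

    def forward(self, x, train=False):
        b, h, w, c = x.shape
        f = self.f
        h2, w2 = h // f, w // f
        self._shape = x.shape
        x = x[:, : h2 * f, : w2 * f]
        return x.reshape(b, h2, f, w2, f, c).mean(axis=(2, 4))

    def backward(self, grad):
        b, h, w, c = self._shape
        f = self.f
        up = np.repeat(np.repeat(grad, f, axis=1), f, axis=2) / (f * f)
        out = np.zeros(self._shape)
        out[:, : up.shape[1], : up.shape[2]] = up
        return out


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (NHWC)."""

    trainable = False

    def forward(self, x, train=False):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._shape = x.shape
        x = x[:, : h2 * 2, : w2 * 2]
        view = x.reshape(b, h2, 2, w2, 2, c)
        out = view.max(axis=(2, 4))
        self._mask = view == out[:, :, None, :, None, :]
        return out

    def backward(self, grad):
        b, h, w, c = self._shape
        up = self._mask * grad[:, :, None, :, None, :]
        out = np.zeros(self._shape)
        h2, w2 = self._mask.shape[1], self._mask.shape[3]
        out[:, : h2 * 2, : w2 * 2] = up.reshape(b, h2 * 2, w2 * 2, c)
        return out


class Conv3x3(Layer):
    """3x3 same-padding convolution via im2col (NHWC)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (9 * c_in))
        self.params = {
            "W": rng.normal(0.0, scale, size=(9 * c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.c_in, self.c_out = c_in, c_out

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((b, h, w, 9 * c))
        idx = 0
        for di in range(3):
            for dj in range(3):
                cols[..., idx * c : (idx + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
                idx += 1
        return cols

    def forward(self, x, train=False):
        self._xshape = x.shape
        self._cols = self._im2col(x)
        b, h, w, _ = x.shape
        flat = self._cols.reshape(-1, 9 * self.c_in)
        out = flat @ self.params["W"] + self.params["b"]
        return out.reshape(b, h, w, self.c_out)

    def backward(self, grad):
        b, h, w, c = self._xshape
        gflat = grad.reshape(-1, self.c_out)
        cols = self._cols.reshape(-1, 9 * self.c_in)
        self.grads["W"] = cols.T @ gflat
        self.grads["b"] = gflat.sum(axis=0)
        gcols = (gflat @ self.params["W"].T).reshape(b, h, w, 9, c)
        gx = np.zeros((b, h + 2, w + 2, c))
        idx = 0
        for di in range(3):
            for dj in range(3):
                gx[:, di : di + h, dj : dj + w, :] += gcols[:, :, :, idx, :]
                idx += 1
        return gx[:, 1 : 1 + h, 1 : 1 + w, :]


class GlobalAvgPool(Layer):
    trainable = False

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        b, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :], self._shape) / (h * w)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    def __init__(self, layers: list[Layer], lr: float):
        self.layers = [l for l in layers if l.trainable and l.params]
        self.lr = lr
        self.state: dict[int, dict] = {}

    def step(self) -> None:
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                self._update(i, name, p, g)

    def _update(self, i, name, p, g):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, layers, lr, momentum: float = 0.9):
        super().__init__(layers, lr)
        self.momentum = momentum

    def _update(self, i, name, p, g):
        key = (i, name)
        v = self.state.get(key, np.zeros_like(p))
        v = self.momentum * v - self.lr * g
        self.state[key] = v
        p += v


class Adam(Optimizer):
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(layers, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        super().step()

    def _update(self, i, name, p, g):
        key = (i, name)
        m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
        m = self.b1 * m + (1 - self.b1) * g
        v = self.b2 * v + (1 - self.b2) * g * g
        self.state[key] = (m, v)
        mhat = m / (1 - self.b1**self.t)
        vhat = v / (1 - self.b2**self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, layers, lr, rho=0.9, eps=1e-8):
        super().__init__(layers, lr)
        self.rho, self.eps = rho, eps

    def _update(self, i, name, p, g):
        key = (i, name)
        v = self.state.get(key, np.zeros_like(p))
        v = self.rho * v + (1 - self.rho) * g * g
        self.state[key] = v
        p -= self.lr * g / (np.sqrt(v) + self.eps)


OPTIMIZERS = {"Adam": Adam, "SGD": SGD, "RMSprop": RMSprop}


def make_optimizer(name: str, layers: list[Layer], lr: float) -> Optimizer:
    try:
        return OPTIMIZERS[name](layers, lr)
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}") from None
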