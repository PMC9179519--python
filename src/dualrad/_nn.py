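"""Minimal NumPy neural-network layers with manual backpropagation.

Just enough machinery for the convolutional autoencoder: stride-1 SAME
convolutions via im2col, 2x2 max-pooling, nearest-neighbor upsampling, batch
normalization, dense layers, ReLU/sigmoid, and an Adam optimizer with cosine
learning-rate decay.  Everything is float32 and fully deterministic given the
initialization RNG and the data order.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patches of a SAME-padded input."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N,H,W,C,k,k)
    win = win.transpose(0, 1, 2, 4, 5, 3)               # (N,H,W,k,k,C)
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(win).reshape(n * h * w, k * k * x.shape[3])


class Conv2D(Layer):
    """3x3 (odd-k) stride-1 SAME cross-correlation."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = k * k * cin
        w = rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in)
        self.params = [w.astype(F32), np.zeros(cout, dtype=F32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cols: Optional[np.ndarray] = None
        self._shape: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        w, b = self.params
        cols = _im2col(x, self.k)
        if train:
            self._cols = cols
            self._shape = x.shape
        y = cols @ w + b
        return y.reshape(x.shape[0], x.shape[1], x.shape[2], self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w, _ = self.params
        n, h, wd, _ = dout.shape
        dflat = dout.reshape(n * h * wd, self.cout)
        self.grads[0][...] = self._cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        # grad wrt input = correlation of dout with the spatially flipped,
        # channel-transposed kernel
        wk = w.reshape(self.k, self.k, self.cin, self.cout)
        wk = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(self.k * self.k * self.cout,
                                                          self.cin)
        cols = _im2col(dout, self.k)
        dx = cols @ wk
        self._cols = None
        return dx.reshape(self._shape)


class MaxPool2(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._idx: Optional[np.ndarray] = None
        self._shape: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(n, h // 2, w // 2, 4, c)
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dwin = np.zeros((n, h // 2, w // 2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dwin, self._idx[:, :, :, None, :], dout[:, :, :, None, :],
                          axis=3)
        dx = dwin.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(n, h, w, c)


class Upsample2(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = [np.ones(c, dtype=F32), np.zeros(c, dtype=F32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if train:
            self._cache = (xhat, invstd)
        return (gamma * xhat + beta).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        gamma, _ = self.params
        xhat, invstd = self._cache
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.grads[0][...] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * gamma
        dx = (dxhat - dxhat.mean(axis=(0, 1, 2))
              - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))) * invstd
        self._cache = None
        return dx.astype(xhat.dtype)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class Sigmoid(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._out: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = (1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))).astype(x.dtype)
        if train:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._out * (1.0 - self._out)
        self._out = None
        return dx


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.standard_normal((nin, nout)) * np.sqrt(2.0 / nin)
        self.params = [w.astype(F32), np.zeros(nout, dtype=F32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.params[0].T
        self._x = None
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target: Sequence[int]) -> None:
        super().__init__()
        self.target = tuple(target)  # per-sample shape

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(dout.shape[0], -1)


class Adam:
    """Adam with a cosine learning-rate schedule from lr_start to lr_end."""

    def __init__(self, layers: Sequence[Layer], lr_start: float, lr_end: float,
                 total_steps: int, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr_start, self.lr_end = lr_start, lr_end
        self.total_steps = max(total_steps, 1)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def current_lr(self) -> float:
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr_end + 0.5 * (self.lr_start - self.lr_end) * (
            1.0 + np.cos(np.pi * frac))

    def step(self) -> None:
        lr = self.current_lr()
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params):
                g = layer.grads[pi]
                self.m[li][pi] = b1 * self.m[li][pi] + (1 - b1) * g
                self.v[li][pi] = b2 * self.v[li][pi] + (1 - b2) * g * g
                mhat = self.m[li][pi] / bias1
                vhat = self.v[li][pi] / bias2
                p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
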