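"""Layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
exposes its parameters and gradients through ``params()`` as a list of
``(name, weight_array, grad_array)`` tuples.  Setting ``trainable = False``
on a layer keeps its parameters out of the optimizer (used for the
frozen-convolution network variant).
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class Layer:
    trainable = True

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []


class Dense(Layer):
    """Affine layer on the last axis; accepts any leading shape."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        x2 = self._x.reshape(-1, self.W.shape[0])
        g2 = g.reshape(-1, self.W.shape[1])
        self.dW[...] = x2.T @ g2
        self.db[...] = g2.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


#: Dense applied per timestep is the same computation thanks to broadcasting.
TimeDistributedDense = Dense


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Tanh(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Conv2D(Layer):
    """2D convolution, NHWC, 'same'-style symmetric zero padding, square
    stride; implemented as a sum of shifted matrix products (kernel taps)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, pad: int | None = None):
        fan_in = kernel * kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad

    def forward(self, x, train=False, rng=None):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        n, H, W, _ = xp.shape
        oh = (H - k) // s + 1
        ow = (W - k) // s + 1
        out = np.broadcast_to(self.b, (n, oh, ow, self.b.size)).copy()
        for i in range(k):
            for j in range(k):
                patch = xp[:, i : i + s * oh : s, j : j + s * ow : s, :]
                out += patch @ self.W[i, j]
        self._oshape = (oh, ow)
        return out

    def backward(self, g):
        k, s = self.kernel, self.stride
        xp = self._xp
        oh, ow = self._oshape
        dxp = np.zeros_like(xp)
        self.dW[...] = 0.0
        self.db[...] = g.sum(axis=(0, 1, 2))
        g2 = g.reshape(-1, g.shape[-1])
        for i in range(k):
            for j in range(k):
                patch = xp[:, i : i + s * oh : s, j : j + s * ow : s, :]
                self.dW[i, j] = patch.reshape(-1, patch.shape[-1]).T @ g2
                dxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += g @ self.W[i, j].T
        p = self.pad
        return dxp[:, p : xp.shape[1] - p, p : xp.shape[2] - p, :] if p else dxp

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class MaxPool2D(Layer):
    """k×k max pooling with stride k; trailing rows/cols are cropped."""

    trainable = False

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train=False, rng=None):
        k = self.k
        n, H, W, C = x.shape
        H2, W2 = H // k, W // k
        xc = x[:, : H2 * k, : W2 * k, :]
        self._xshape = x.shape
        blocks = xc.reshape(n, H2, k, W2, k, C)
        out = blocks.max(axis=(2, 4))
        self._mask = blocks == out[:, :, None, :, None, :]
        return out

    def backward(self, g):
        k = self.k
        n, H, W, C = self._xshape
        H2, W2 = H // k, W // k
        gb = self._mask * g[:, :, None, :, None, :]
        # split ties evenly so gradient mass is conserved
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        gb = gb / counts
        out = np.zeros((n, H, W, C))
        out[:, : H2 * k, : W2 * k, :] = gb.reshape(n, H2 * k, W2 * k, C)
        return out


class LSTM(Layer):
    """Single-direction LSTM over (batch, time, features), returning the full
    hidden sequence; gradients by backpropagation through time."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        h = n_hidden
        limit = np.sqrt(6.0 / (n_in + 4 * h))
        self.Wx = rng.uniform(-limit, limit, (n_in, 4 * h))
        limit = np.sqrt(6.0 / (h + 4 * h))
        self.Wh = rng.uniform(-limit, limit, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self.h = h

    def forward(self, x, train=False, rng=None):
        n, T, _ = x.shape
        h = self.h
        self._x = x
        self._cache = []
        hs = np.zeros((n, T, h))
        h_t = np.zeros((n, h))
        c_t = np.zeros((n, h))
        for t in range(T):
            z = x[:, t] @ self.Wx + h_t @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tc
            hs[:, t] = h_t
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return hs

    def backward(self, grad_hs):
        x = self._x
        n, T, _ = x.shape
        h = self.h
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            dh = grad_hs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWx += x[:, t].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx

    def params(self):
        return [("Wx", self.Wx, self.dWx), ("Wh", self.Wh, self.dWh),
                ("b", self.b, self.db)]
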