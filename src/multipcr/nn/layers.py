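"""Minimal numpy neural-network layers with manual backpropagation.

Arrays are channels-last: sequence inputs are ``(batch, length, channels)``.
Each layer caches what its backward pass needs; ``backward`` consumes the
upstream gradient and returns the gradient with respect to the layer input,
so a full backward pass also yields input gradients for attribution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[dict]:
        """List of {"value": array, "grad": array} parameter slots."""
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state (e.g. batch-norm running statistics)."""
        return []


class Dense(Layer):
    """Affine map on the last axis; acts per position on (B, L, C) inputs."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x2 = self._x.reshape(-1, self.W.shape[0])
        dy2 = dy.reshape(-1, self.W.shape[1])
        self.dW[...] = x2.T @ dy2
        self.db[...] = dy2.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


class PositionalEncodingAdd(Layer):
    """Adds a fixed sinusoidal positional-encoding matrix (L, d)."""

    def __init__(self, pe: np.ndarray):
        self.pe = pe

    def forward(self, x, train=False):
        if x.shape[1:] != self.pe.shape:
            raise ValueError(
                f"input of shape {x.shape[1:]} does not match PE {self.pe.shape}"
            )
        return x + self.pe

    def backward(self, dy):
        return dy


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding, stride 1."""

    def __init__(self, c_in: int, n_filters: int, k: int, rng: np.random.Generator):
        self.k = k
        self.c_in = c_in
        fan_in = k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, n_filters))
        self.b = np.zeros(n_filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.pad_l = (k - 1) // 2
        self.pad_r = k - 1 - self.pad_l

    def forward(self, x, train=False):
        B, L, C = x.shape
        if self.k > L:
            raise ValueError("filter longer than sequence")
        xp = np.pad(x, ((0, 0), (self.pad_l, self.pad_r), (0, 0)))
        win = sliding_window_view(xp, self.k, axis=1)  # (B, L, C, k)
        win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, self.k * C)
        self._win = win
        self._L = L
        return win @ self.W + self.b

    def backward(self, dy):
        B, L, F = dy.shape
        k, C = self.k, self.c_in
        win2 = self._win.reshape(-1, k * C)
        dy2 = dy.reshape(-1, F)
        self.dW[...] = win2.T @ dy2
        self.db[...] = dy2.sum(axis=0)
        dwin = (dy @ self.W.T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + k - 1, C))
        for t in range(k):
            dxp[:, t : t + L, :] += dwin[:, :, t, :]
        return dxp[:, self.pad_l : self.pad_l + L, :]

    def params(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


class BatchNorm(Layer):
    """Batch normalisation over batch and length axes, per channel."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        self._train = train
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        self._n = int(np.prod(x.shape[:-1]))
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.dgamma[...] = (dy * self._xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        if not self._train:
            return dy * self.gamma * self._istd
        n = self._n
        dxhat = dy * self.gamma
        return (
            self._istd
            / n
            * (n * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )

    def params(self):
        return [
            {"value": self.gamma, "grad": self.dgamma},
            {"value": self.beta, "grad": self.dbeta},
        ]

    def buffers(self):
        return [self.running_mean, self.running_var]


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class GlobalMeanPool(Layer):
    """(B, L, C) -> (B, C) mean over positions."""

    def forward(self, x, train=False):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class GlobalMaxPool(Layer):
    """(B, L, C) -> (B, C) max over positions (first argmax wins ties)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        self._arg = x.argmax(axis=1)
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        np.put_along_axis(dx, self._arg[:, None, :], dy[:, None, :], axis=1)
        return dx


class Squeeze(Layer):
    """(B, 1) -> (B,) final logit squeeze."""

    def forward(self, x, train=False):
        return x[:, 0]

    def backward(self, dy):
        return dy[:, None]


class BiRNN(Layer):
    """Single-layer bidirectional Elman (tanh) recurrent layer.

    Output concatenates forward and backward hidden states: (B, L, 2H).
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.h = hidden
        s = np.sqrt(1.0 / hidden)
        self.p = {}
        for d in ("f", "b"):
            self.p[f"Wx_{d}"] = rng.normal(0, np.sqrt(2.0 / c_in), (c_in, hidden))
            self.p[f"Wh_{d}"] = rng.normal(0, s, (hidden, hidden))
            self.p[f"b_{d}"] = np.zeros(hidden)
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}

    def _run(self, x, d):
        B, L, _ = x.shape
        Wx, Wh, b = self.p[f"Wx_{d}"], self.p[f"Wh_{d}"], self.p[f"b_{d}"]
        hs = np.zeros((B, L, self.h))
        h = np.zeros((B, self.h))
        order = range(L) if d == "f" else range(L - 1, -1, -1)
        for t in order:
            h = np.tanh(x[:, t] @ Wx + h @ Wh + b)
            hs[:, t] = h
        return hs

    def forward(self, x, train=False):
        self._x = x
        self._hf = self._run(x, "f")
        self._hb = self._run(x, "b")
        return np.concatenate([self._hf, self._hb], axis=2)

    def _bptt(self, x, hs, dhs, d):
        B, L, _ = x.shape
        Wx, Wh = self.p[f"Wx_{d}"], self.p[f"Wh_{d}"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(self.h)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, self.h))
        order = range(L - 1, -1, -1) if d == "f" else range(L)
        for t in order:
            dh = dhs[:, t] + dh_next
            da = dh * (1.0 - hs[:, t] ** 2)
            h_prev_t = t - 1 if d == "f" else t + 1
            if 0 <= h_prev_t < L:
                h_prev = hs[:, h_prev_t]
            else:
                h_prev = np.zeros((B, self.h))
            dWx += x[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ Wx.T
            dh_next = da @ Wh.T
        self.g[f"Wx_{d}"][...] = dWx
        self.g[f"Wh_{d}"][...] = dWh
        self.g[f"b_{d}"][...] = db
        return dx

    def backward(self, dy):
        dhf = dy[:, :, : self.h]
        dhb = dy[:, :, self.h :]
        dx = self._bptt(self._x, self._hf, dhf, "f")
        dx += self._bptt(self._x, self._hb, dhb, "b")
        return dx

    def params(self):
        return [
            {"value": self.p[k], "grad": self.g[k]} for k in sorted(self.p)
        ]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def buffers(self):
        out = []
        for layer in self.layers:
            out.extend(layer.buffers())
        return out

    def get_weights(self) -> list[np.ndarray]:
        arrays = [p["value"] for p in self.params()] + self.buffers()
        return [a.copy() for a in arrays]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        arrays = [p["value"] for p in self.params()] + self.buffers()
        for a, w in zip(arrays, weights, strict=True):
            a[...] = w
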