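"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the layer set the sequence-labeling model needs:
same-padded 1-D convolution, batch normalization, ReLU, dropout, dense
layers, bidirectional LSTMs and an Adam optimizer. Every layer caches its
forward activations and exposes ``backward`` returning the gradient with
respect to its input while accumulating parameter gradients; correctness is
pinned by finite-difference checks in the test suite.

Shapes follow the (batch, time, channels) convention.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           dtype: np.dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # stable and branch-free: sigmoid(x) = (1 + tanh(x/2)) / 2
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class Layer:
    def params(self) -> list[Param]:
        return []


class Dense(Layer):
    def __init__(self, rng, d_in: int, d_out: int, dtype=np.float32,
                 name: str = "dense"):
        self.W = Param(f"{name}.W", glorot(rng, (d_in, d_out), dtype))
        self.b = Param(f"{name}.b", np.zeros(d_out, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when ``rate == 0`` or in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class Conv1dSame(Layer):
    """1-D convolution, kernel 3, stride 1, zero same-padding.

    Input (B, L, C_in) -> output (B, L, C_out), computed as an im2col
    matrix product.
    """

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 3,
                 dtype=np.float32, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.c_in = c_in
        self.W = Param(f"{name}.W", glorot(rng, (kernel * c_in, c_out), dtype))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=dtype))

    def _im2col(self, xp: np.ndarray, L: int) -> np.ndarray:
        cols = [xp[:, i : i + L, :] for i in range(self.kernel)]
        return np.concatenate(cols, axis=2)  # (B, L, k*C_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        pad = self.kernel // 2
        xp = np.zeros((B, L + 2 * pad, C), dtype=x.dtype)
        xp[:, pad : pad + L, :] = x
        self._col = self._im2col(xp, L)
        self._shape = (B, L, C)
        return self._col @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, L, C = self._shape
        k, pad = self.kernel, self.kernel // 2
        self.W.grad += self._col.reshape(-1, k * C).T @ g.reshape(-1, g.shape[-1])
        self.b.grad += g.sum(axis=(0, 1))
        dcol = g @ self.W.value.T  # (B, L, k*C)
        dxp = np.zeros((B, L + 2 * pad, C), dtype=g.dtype)
        for i in range(k):
            dxp[:, i : i + L, :] += dcol[:, :, i * C : (i + 1) * C]
        return dxp[:, pad : pad + L, :]

    def params(self):
        return [self.W, self.b]


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch (and time) axes."""

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.9,
                 eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        self._train = train
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._xhat = (x - mu) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * self._xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gx = g * self.gamma.value
        if not self._train:
            return gx * self._inv
        m = np.prod([g.shape[a] for a in axes])
        return (self._inv / m) * (
            m * gx - gx.sum(axis=axes, keepdims=True)
            - self._xhat * (gx * self._xhat).sum(axis=axes, keepdims=True)
        )

    def params(self):
        return [self.gamma, self.beta]


class _LSTMDirection:
    """One direction of an LSTM over (B, T, D) input; tanh activations,
    gate order (input, forget, output, cell) so the three sigmoid gates are
    one contiguous block; forget-gate bias 1."""

    def __init__(self, rng, d_in: int, hidden: int, dtype=np.float32,
                 name: str = "lstm"):
        self.H = hidden
        self.Wx = Param(f"{name}.Wx", glorot(rng, (d_in, 4 * hidden), dtype))
        self.Wh = Param(f"{name}.Wh", glorot(rng, (hidden, 4 * hidden), dtype))
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden : 2 * hidden] = 1.0
        self.b = Param(f"{name}.b", b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.H
        xp = x.reshape(B * T, D) @ self.Wx.value + self.b.value
        xp = xp.reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        out = np.empty((B, T, H), dtype=x.dtype)
        gates = np.empty((B, T, 4 * H), dtype=x.dtype)  # i,f,o sig; g tanh
        cs = np.empty((B, T, H), dtype=x.dtype)   # post-update cell states
        hcs = np.empty((B, T, H), dtype=x.dtype)  # tanh(c)
        for t in range(T):
            z = xp[:, t, :] + h @ self.Wh.value
            sig = _sigmoid(z[:, : 3 * H])
            i = sig[:, :H]
            f = sig[:, H : 2 * H]
            o = sig[:, 2 * H : 3 * H]
            gg = np.tanh(z[:, 3 * H :])
            c = f * c + i * gg
            hc = np.tanh(c)
            h = o * hc
            out[:, t, :] = h
            gates[:, t, : 3 * H] = sig
            gates[:, t, 3 * H :] = gg
            cs[:, t, :] = c
            hcs[:, t, :] = hc
        self._x = x
        self._out = out
        self._gates, self._cs, self._hcs = gates, cs, hcs
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, D = x.shape
        H = self.H
        gates, cs, hcs, out = self._gates, self._cs, self._hcs, self._out
        dZ = np.empty((B, T, 4 * H), dtype=x.dtype)
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        dWh = np.zeros_like(self.Wh.value)
        WhT = self.Wh.value.T
        zero = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            o = gates[:, t, 2 * H : 3 * H]
            gg = gates[:, t, 3 * H :]
            hc = hcs[:, t, :]
            c_prev = cs[:, t - 1, :] if t > 0 else zero
            h_prev = out[:, t - 1, :] if t > 0 else zero
            dh = dout[:, t, :] + dh_next
            dc = dc_next + dh * o * (1.0 - hc * hc)
            dz = dZ[:, t, :]
            dz[:, :H] = dc * gg * i * (1 - i)
            dz[:, H : 2 * H] = dc * c_prev * f * (1 - f)
            dz[:, 2 * H : 3 * H] = dh * hc * o * (1 - o)
            dz[:, 3 * H :] = dc * i * (1 - gg * gg)
            dc_next = dc * f
            if t > 0:
                dWh += h_prev.T @ dz
            dh_next = dz @ WhT
        self.Wh.grad += dWh
        flat = dZ.reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ flat
        self.b.grad += flat.sum(axis=0)
        return (flat @ self.Wx.value.T).reshape(B, T, D)

    def params(self):
        return [self.Wx, self.Wh, self.b]


class BiLSTM(Layer):
    """Bidirectional LSTM; output is the concatenation (B, T, 2H)."""

    def __init__(self, rng, d_in: int, hidden: int, dtype=np.float32,
                 name: str = "bilstm"):
        self.fwd = _LSTMDirection(rng, d_in, hidden, dtype, f"{name}.fwd")
        self.bwd = _LSTMDirection(rng, d_in, hidden, dtype, f"{name}.bwd")

    def forward(self, x: np.ndarray) -> np.ndarray:
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        H = self.fwd.H
        dxf = self.fwd.backward(np.ascontiguousarray(g[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(g[:, ::-1, H:]))[:, ::-1, :]
        return dxf + dxb

    def params(self):
        return self.fwd.params() + self.bwd.params()


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 0.002,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
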