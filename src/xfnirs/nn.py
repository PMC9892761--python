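"""Minimal NumPy neural-network layers sufficient for the 1-D CNN and LSTM
classifiers: forward/backward passes, Adam, and softmax cross-entropy.

Everything is deterministic given the seed of the generator used for
initialization, shuffling and dropout masks. Layers cache what their
backward pass needs; the explanation module reads layer parameters and
recomputes activations on its own, so gradients and attributions never
share state.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer; subclasses fill params/grads with matching array lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution over time, spanning all feature-channels.

    Input (B, T, C); kernel size k, stride 1; padding "same" or "valid".
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: int = 3,
                 padding: str = "same", rng: np.random.Generator | None = None):
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        rng = rng or np.random.default_rng()
        self.k = kernel_size
        self.c = in_channels
        self.f = filters
        self.padding = padding
        fan_in = kernel_size * in_channels
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((fan_in, filters)) * scale).astype(DTYPE)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "same":
            left = (self.k - 1) // 2
            right = self.k - 1 - left
            return np.pad(x, ((0, 0), (left, right), (0, 0)))
        return x

    def _cols(self, x: np.ndarray) -> np.ndarray:
        xp = self._pad(x)
        # (B, T_out, C, k) -> (B, T_out, k*C) matching W's (k*C, F) layout
        win = sliding_window_view(xp, self.k, axis=1)
        win = np.ascontiguousarray(np.swapaxes(win, 2, 3))
        return win.reshape(x.shape[0], -1, self.k * self.c)

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        self._cols_cache = self._cols(x)
        return self._cols_cache @ self.W + self.b

    def backward(self, gy):
        b, t_out, _ = gy.shape
        cols = self._cols_cache.reshape(-1, self.k * self.c)
        self.gW[...] = cols.T @ gy.reshape(-1, self.f)
        self.gb[...] = gy.sum(axis=(0, 1))
        gcols = (gy @ self.W.T).reshape(b, t_out, self.k, self.c)
        t_in = self._x_shape[1]
        if self.padding == "same":
            left = (self.k - 1) // 2
            right = self.k - 1 - left
            gxp = np.zeros((b, t_in + left + right, self.c), dtype=gy.dtype)
        else:
            left = 0
            gxp = np.zeros((b, t_in, self.c), dtype=gy.dtype)
        for j in range(self.k):
            gxp[:, j : j + t_out, :] += gcols[:, :, j, :]
        return gxp[:, left : left + t_in, :] if self.padding == "same" else gxp

    def out_shape(self, in_shape):
        t = in_shape[0] if self.padding == "same" else in_shape[0] - self.k + 1
        if t < 1:
            raise ValueError(f"Conv1D: input length {in_shape[0]} shorter than kernel")
        return (t, self.f)


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; a trailing remainder is dropped."""

    def __init__(self, pool_size: int = 2):
        self.p = pool_size

    def forward(self, x, train=False, rng=None):
        b, t, c = x.shape
        t_out = t // self.p
        xr = x[:, : t_out * self.p].reshape(b, t_out, self.p, c)
        self._argmax = xr.argmax(axis=2)
        self._in_t = t
        return xr.max(axis=2)

    def backward(self, gy):
        b, t_out, c = gy.shape
        gx = np.zeros((b, t_out, self.p, c), dtype=gy.dtype)
        bi, ti, ci = np.ogrid[:b, :t_out, :c]
        gx[bi, ti, self._argmax, ci] = gy
        gx = gx.reshape(b, t_out * self.p, c)
        if t_out * self.p < self._in_t:
            gx = np.pad(gx, ((0, 0), (0, self._in_t - t_out * self.p), (0, 0)))
        return gx

    def out_shape(self, in_shape):
        return (in_shape[0] // self.p, in_shape[1])


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)

    def out_shape(self, in_shape):
        n = 1
        for d in in_shape:
            n *= d
        return (n,)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_dim)
        self.W = (rng.standard_normal((in_dim, out_dim)) * scale).astype(DTYPE)
        self.b = np.zeros(out_dim, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gy):
        self.gW[...] = self._x.T @ gy
        self.gb[...] = gy.sum(axis=0)
        return gy @ self.W.T

    def out_shape(self, in_shape):
        if in_shape[-1] != self.W.shape[0]:
            raise ValueError(
                f"Dense: expected input dim {self.W.shape[0]}, got {in_shape[-1]}"
            )
        return (self.W.shape[1],)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float = 0.5):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training dropout needs a generator")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class LSTM(Layer):
    """Single LSTM layer returning the full hidden sequence (B, T, H).

    Gate layout in the packed weight matrices is [input, forget, cell, output];
    the forget-gate bias starts at 1.
    """

    def __init__(self, in_dim: int, hidden: int = 120,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.d = in_dim
        self.h = hidden
        sw = np.sqrt(1.0 / in_dim)
        su = np.sqrt(1.0 / hidden)
        self.W = (rng.standard_normal((in_dim, 4 * hidden)) * sw).astype(DTYPE)
        self.U = (rng.standard_normal((hidden, 4 * hidden)) * su).astype(DTYPE)
        self.b = np.zeros(4 * hidden, dtype=DTYPE)
        self.b[hidden : 2 * hidden] = 1.0
        self.gW = np.zeros_like(self.W)
        self.gU = np.zeros_like(self.U)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.U, self.b]

    def grads(self):
        return [self.gW, self.gU, self.gb]

    def forward(self, x, train=False, rng=None):
        b, t, _ = x.shape
        h_dim = self.h
        self._x = x
        self._i = np.empty((b, t, h_dim), dtype=x.dtype)
        self._f = np.empty_like(self._i)
        self._g = np.empty_like(self._i)
        self._o = np.empty_like(self._i)
        self._c = np.empty_like(self._i)
        self._tanh_c = np.empty_like(self._i)
        hseq = np.empty_like(self._i)
        h = np.zeros((b, h_dim), dtype=x.dtype)
        c = np.zeros((b, h_dim), dtype=x.dtype)
        xw = x @ self.W  # precompute input projections for all timesteps
        for ti in range(t):
            z = xw[:, ti] + h @ self.U + self.b
            i = sigmoid(z[:, :h_dim])
            f = sigmoid(z[:, h_dim : 2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = sigmoid(z[:, 3 * h_dim :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            self._i[:, ti], self._f[:, ti] = i, f
            self._g[:, ti], self._o[:, ti] = g, o
            self._c[:, ti], self._tanh_c[:, ti] = c, tc
            hseq[:, ti] = h
        self._hseq = hseq
        return hseq

    def backward(self, gy):
        x = self._x
        b, t, _ = x.shape
        h_dim = self.h
        gx = np.zeros_like(x)
        self.gW[...] = 0
        self.gU[...] = 0
        self.gb[...] = 0
        dh_next = np.zeros((b, h_dim), dtype=x.dtype)
        dc_next = np.zeros((b, h_dim), dtype=x.dtype)
        gz_all = np.empty((b, t, 4 * h_dim), dtype=x.dtype)
        for ti in range(t - 1, -1, -1):
            i, f = self._i[:, ti], self._f[:, ti]
            g, o = self._g[:, ti], self._o[:, ti]
            c, tc = self._c[:, ti], self._tanh_c[:, ti]
            c_prev = self._c[:, ti - 1] if ti > 0 else np.zeros_like(c)
            dh = gy[:, ti] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            gz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            gz_all[:, ti] = gz
            dh_next = gz @ self.U.T
            dc_next = dc * f
        gz2 = gz_all.reshape(b * t, 4 * h_dim)
        self.gW[...] = x.reshape(b * t, self.d).T @ gz2
        h_prev = np.concatenate(
            [np.zeros((b, 1, h_dim), dtype=x.dtype), self._hseq[:, :-1]], axis=1
        )
        self.gU[...] = h_prev.reshape(b * t, h_dim).T @ gz2
        self.gb[...] = gz2.sum(axis=0)
        gx[...] = (gz_all @ self.W.T)
        return gx

    def out_shape(self, in_shape):
        return (in_shape[0], self.h)


class Sequential:
    """Plain layer stack with softmax cross-entropy on the final logits."""

    def __init__(self, layers: list[Layer], input_shape: tuple):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        # validate the shape chain eagerly so misconfigurations fail at build
        self.layer_shapes: list[tuple] = []
        shape = self.input_shape
        for li, layer in enumerate(self.layers):
            try:
                shape = layer.out_shape(shape)
            except ValueError as exc:
                raise ValueError(
                    f"layer {li} ({type(layer).__name__}): {exc}"
                ) from exc
            self.layer_shapes.append(shape)
        self.output_shape = shape

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for start in range(0, len(x), batch_size):
            outs.append(self.forward(x[start : start + batch_size].astype(DTYPE)))
        return np.concatenate(outs, axis=0) if outs else np.empty((0,) + self.output_shape)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return softmax(self.predict_logits(x, batch_size))

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    gy = p
    gy[np.arange(n), y] -= 1.0
    return float(loss), (gy / n).astype(logits.dtype)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
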