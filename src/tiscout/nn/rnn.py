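"""LSTM layers with explicit backward-through-time.

Sequences are (T, N, D).  Gate order in the packed weight matrices is
input, forget, cell, output (i, f, g, o).
"""

from __future__ import annotations

import numpy as np

from .core import DEFAULT_DTYPE, Module, Parameter, uniform_init
from .layers import sigmoid


class LSTM(Module):
    """Single-direction LSTM over a full sequence; returns all hidden states."""

    def __init__(self, input_size: int, hidden_size: int, *,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE,
                 reverse: bool = False):
        super().__init__()
        self.input_size, self.hidden_size = input_size, hidden_size
        self.reverse = reverse
        bound = 1.0 / np.sqrt(hidden_size)
        self.w_ih = Parameter(uniform_init(rng, (4 * hidden_size, input_size), bound, dtype))
        self.w_hh = Parameter(uniform_init(rng, (4 * hidden_size, hidden_size), bound, dtype))
        bias = np.zeros(4 * hidden_size, dtype=dtype)
        bias[hidden_size:2 * hidden_size] = 1.0  # forget-gate bias: remember by default
        self.bias = Parameter(bias)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.reverse:
            x = x[::-1]
        t_len, n, _ = x.shape
        hs = self.hidden_size
        h = np.zeros((n, hs), dtype=x.dtype)
        c = np.zeros((n, hs), dtype=x.dtype)
        cache = []
        out = np.empty((t_len, n, hs), dtype=x.dtype)
        for t in range(t_len):
            z = x[t] @ self.w_ih.value.T + h @ self.w_hh.value.T + self.bias.value
            i = sigmoid(z[:, 0 * hs:1 * hs])
            f = sigmoid(z[:, 1 * hs:2 * hs])
            g = np.tanh(z[:, 2 * hs:3 * hs])
            o = sigmoid(z[:, 3 * hs:4 * hs])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[t], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            out[t] = h
        self._cache = cache
        self._x_shape = x.shape
        if self.reverse:
            return out[::-1].copy()
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.reverse:
            dout = dout[::-1]
        t_len, n, _ = self._x_shape
        hs = self.hidden_size
        dx = np.empty(self._x_shape, dtype=dout.dtype)
        dh_next = np.zeros((n, hs), dtype=dout.dtype)
        dc_next = np.zeros((n, hs), dtype=dout.dtype)
        dw_ih = np.zeros_like(self.w_ih.value, dtype=dout.dtype)
        dw_hh = np.zeros_like(self.w_hh.value, dtype=dout.dtype)
        db = np.zeros_like(self.bias.value, dtype=dout.dtype)
        for t in range(t_len - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = self._cache[t]
            dh = dout[t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dw_ih += dz.T @ x_t
            dw_hh += dz.T @ h_prev
            db += dz.sum(axis=0)
            dx[t] = dz @ self.w_ih.value
            dh_next = dz @ self.w_hh.value
            dc_next = dc * f
        if self.w_ih.requires_grad:
            self.w_ih.grad += dw_ih
            self.w_hh.grad += dw_hh
            self.bias.grad += db
        if self.reverse:
            return dx[::-1].copy()
        return dx


class BiLSTM(Module):
    """Bidirectional LSTM: forward and reverse passes concatenated on features."""

    def __init__(self, input_size: int, hidden_size: int, *,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.fwd = LSTM(input_size, hidden_size, rng=rng, dtype=dtype, reverse=False)
        self.bwd = LSTM(input_size, hidden_size, rng=rng, dtype=dtype, reverse=True)
        self.hidden_size = hidden_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([self.fwd.forward(x), self.bwd.forward(x)], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        hs = self.hidden_size
        return self.fwd.backward(dy[:, :, :hs]) + self.bwd.backward(dy[:, :, hs:])
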