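"""Minimal NumPy neural-network engine for the sequence labeler.

Implements exactly what the slice labeler needs — stacked bidirectional
LSTM layers, shared per-timestep dense layers with ReLU, a sigmoid head,
and the Adam optimizer — with hand-derived backpropagation through time.
Everything is float64 and purely deterministic given the initialization
RNG and data order, so training runs are bit-reproducible.

Parameter containers are plain dicts of ndarrays; gradients mirror their
structure.  Gate layout in the fused LSTM weight matrices is
(input, forget, cell, output).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = [
    "init_lstm",
    "lstm_forward",
    "lstm_backward",
    "init_dense",
    "AdamState",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_lstm(rng: np.random.Generator, n_in: int, n_hidden: int) -> dict:
    """Uniform(-k, k) init with k = 1/sqrt(hidden); forget-gate bias 1."""
    k = 1.0 / np.sqrt(n_hidden)
    p = {
        "Wx": rng.uniform(-k, k, size=(n_in, 4 * n_hidden)),
        "Wh": rng.uniform(-k, k, size=(n_hidden, 4 * n_hidden)),
        "b": np.zeros(4 * n_hidden),
    }
    p["b"][n_hidden : 2 * n_hidden] = 1.0  # forget gate bias
    return p


def lstm_forward(params: dict, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run a unidirectional LSTM over ``x`` of shape (B, T, F).

    Returns the hidden sequence (B, T, H) and the cache needed by
    :func:`lstm_backward`.
    """
    B, T, F = x.shape
    H = params["Wh"].shape[0]
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]

    # input contribution for all timesteps at once
    zx = x.reshape(B * T, F) @ Wx
    zx = zx.reshape(B, T, 4 * H) + b

    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    cache_g = np.empty((B, T, 4 * H))  # activated gates i,f,g,o
    cache_c = np.empty((B, T, H))      # cell states
    cache_tc = np.empty((B, T, H))     # tanh(cell)

    for t in range(T):
        z = zx[:, t] + h @ Wh
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t] = h
        cache_g[:, t, :H] = i
        cache_g[:, t, H : 2 * H] = f
        cache_g[:, t, 2 * H : 3 * H] = g
        cache_g[:, t, 3 * H :] = o
        cache_c[:, t] = c
        cache_tc[:, t] = tc

    cache = {"x": x, "hs": hs, "g": cache_g, "c": cache_c, "tc": cache_tc}
    return hs, cache


def lstm_backward(params: dict, cache: dict, dhs: np.ndarray) -> tuple[dict, np.ndarray]:
    """Backpropagate through time given d(loss)/d(hidden sequence).

    Returns (gradients matching ``params``, d(loss)/d(input)).
    """
    x, hs = cache["x"], cache["hs"]
    gates, cs, tcs = cache["g"], cache["c"], cache["tc"]
    B, T, F = x.shape
    H = params["Wh"].shape[0]
    Wx, Wh = params["Wx"], params["Wh"]

    dWh = np.zeros_like(Wh)
    dZ = np.empty((B, T, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))

    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        tc = tcs[:, t]
        c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H))
        h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))

        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i

        dz = np.empty((B, 4 * H))
        dz[:, :H] = di * i * (1.0 - i)
        dz[:, H : 2 * H] = df * f * (1.0 - f)
        dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
        dz[:, 3 * H :] = do * o * (1.0 - o)
        dZ[:, t] = dz

        dWh += h_prev.T @ dz
        dh_next = dz @ Wh.T
        dc_next = dc * f

    dZ_flat = dZ.reshape(B * T, 4 * H)
    grads = {
        "Wx": x.reshape(B * T, F).T @ dZ_flat,
        "Wh": dWh,
        "b": dZ_flat.sum(axis=0),
    }
    dx = (dZ_flat @ Wx.T).reshape(B, T, F)
    return grads, dx


def init_dense(rng: np.random.Generator, n_in: int, n_out: int) -> dict:
    k = 1.0 / np.sqrt(n_in)
    return {
        "W": rng.uniform(-k, k, size=(n_in, n_out)),
        "b": np.zeros(n_out),
    }


class AdamState:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
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
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
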