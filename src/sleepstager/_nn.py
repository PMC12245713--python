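"""Minimal NumPy neural-network primitives used by the stager.

Float32 throughout; convolutions are lowered to BLAS matmuls via im2col.
Each ``*_forward`` returns ``(output, cache)``; the matching ``*_backward``
consumes the upstream gradient and the cache.  Shapes follow the
convention ``(batch, channels, time)`` for convolutional tensors and
``(batch, time, features)`` for the LSTM.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32
LN_EPS = F32(1e-5)


# ---------------------------------------------------------------- conv1d


def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Stride-1 'same' 1-D convolution in channel-first layout.

    x:(Cin,N,L)  W:(Cout,Cin,k)  b:(Cout,) -> y:(Cout,N,L).  The im2col
    buffer is laid out so the contraction is a single large GEMM over all
    segments at once.
    """
    Cin, N, L = x.shape
    Cout, _, k = W.shape
    pl = (k - 1) // 2
    xp = np.zeros((Cin, N, L + k - 1), dtype=x.dtype)
    xp[:, :, pl:pl + L] = x
    cols = np.empty((Cin, k, N, L), dtype=x.dtype)
    for j in range(k):
        cols[:, j] = xp[:, :, j:j + L]
    cols2 = cols.reshape(Cin * k, N * L)
    W2 = W.reshape(Cout, Cin * k)
    y = W2 @ cols2
    y += b[:, None]
    return y.reshape(Cout, N, L), (cols2, x.shape, W)


def conv1d_backward(dy: np.ndarray, cache):
    cols2, x_shape, W = cache
    Cin, N, L = x_shape
    Cout, _, k = W.shape
    W2 = W.reshape(Cout, Cin * k)
    dy2 = dy.reshape(Cout, N * L)
    dW = (dy2 @ cols2.T).reshape(W.shape)
    db = dy2.sum(axis=1)
    dcols = (W2.T @ dy2).reshape(Cin, k, N, L)
    pl = (k - 1) // 2
    dxp = np.zeros((Cin, N, L + k - 1), dtype=dy.dtype)
    for j in range(k):
        dxp[:, :, j:j + L] += dcols[:, j]
    dx = dxp[:, :, pl:pl + L]
    return dx, dW, db


# ------------------------------------------------------------- layer norm


def layernorm_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    """Normalize over the channel axis at every time position.  x:(C,N,L)."""
    mu = x.mean(axis=0)
    xc = x - mu
    var = np.mean(xc * xc, axis=0)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = xc * inv
    y = g[:, None, None] * xhat + b[:, None, None]
    return y.astype(x.dtype, copy=False), (xhat, inv, g)


def layernorm_backward(dy: np.ndarray, cache):
    xhat, inv, g = cache
    C = xhat.shape[0]
    dg = np.sum(dy * xhat, axis=(1, 2))
    db = dy.sum(axis=(1, 2))
    dxhat = dy * g[:, None, None]
    dx = (inv / C) * (
        C * dxhat
        - dxhat.sum(axis=0)
        - xhat * np.sum(dxhat * xhat, axis=0)
    )
    return dx.astype(dy.dtype, copy=False), dg, db


# ------------------------------------------------------------------ relu


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, y


def relu_backward(dy: np.ndarray, y: np.ndarray):
    return dy * (y > 0)


# ------------------------------------------------------------------ lstm


def _sigmoid(z):
    out = np.empty_like(z)
    np.negative(z, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Single-layer unidirectional LSTM; returns the final hidden state.

    x:(B,T,D)  Wx:(D,4H)  Wh:(H,4H)  b:(4H,)  gate order i,f,g,o.
    """
    B, T, D = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    steps = []
    for t in range(T):
        pre = x[:, t, :] @ Wx + h @ Wh + b
        i = _sigmoid(pre[:, :H])
        f = _sigmoid(pre[:, H:2 * H])
        g = np.tanh(pre[:, 2 * H:3 * H])
        o = _sigmoid(pre[:, 3 * H:])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        steps.append((i, f, g, o, c_prev, h_prev, tc))
    return h, (x, Wx, Wh, steps)


def lstm_backward(dh_last: np.ndarray, cache):
    x, Wx, Wh, steps = cache
    B, T, D = x.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=Wx.dtype)
    dx = np.zeros_like(x)
    dh = dh_last.astype(x.dtype, copy=True)
    dc = np.zeros((B, H), dtype=x.dtype)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, h_prev, tc = steps[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dpre = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dWx += x[:, t, :].T @ dpre
        dWh += h_prev.T @ dpre
        db += dpre.sum(axis=0)
        dx[:, t, :] = dpre @ Wx.T
        dh = dpre @ Wh.T
        dc = dc * f
    return dx, dWx, dWh, db


# ---------------------------------------------------------------- linear


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def linear_backward(dy: np.ndarray, x: np.ndarray, W: np.ndarray):
    return dy @ W.T, x.T @ dy, dy.sum(axis=0)


# -------------------------------------------------- softmax cross-entropy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray, class_weights=None):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    logp = np.log(np.clip(p[np.arange(n), y], 1e-30, None))
    if class_weights is None:
        loss = -logp.mean()
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
    else:
        w = np.asarray(class_weights, dtype=np.float64)[y]
        wsum = w.sum()
        loss = -(w * logp).sum() / wsum
        dlogits = p * w[:, None]
        dlogits[np.arange(n), y] -= w
        dlogits /= wsum
    return float(loss), dlogits.astype(logits.dtype)


# ------------------------------------------------------------------ adam


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            gr = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * gr
            v *= b2
            v += (1 - b2) * gr * gr
            p -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)


# ------------------------------------------------------------------ init


def he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> np.ndarray:
    std = np.sqrt(2.0 / (c_in * k))
    return (rng.standard_normal((c_out, c_in, k)) * std).astype(F32)


def lstm_init(rng: np.random.Generator, d: int, h: int):
    bound = 1.0 / np.sqrt(h)
    Wx = rng.uniform(-bound, bound, (d, 4 * h)).astype(F32)
    Wh = rng.uniform(-bound, bound, (h, 4 * h)).astype(F32)
    b = np.zeros(4 * h, dtype=F32)
    b[h:2 * h] = 1.0  # forget-gate bias
    return Wx, Wh, b


def glorot_linear(rng: np.random.Generator, d_in: int, d_out: int):
    bound = np.sqrt(6.0 / (d_in + d_out))
    W = rng.uniform(-bound, bound, (d_in, d_out)).astype(F32)
    return W, np.zeros(d_out, dtype=F32)
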