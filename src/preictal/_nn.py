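"""Minimal numpy neural-network kernels for the segment classifier.

Implements exactly what the encoder/head architecture needs — 3x3
same-padding convolution, batch normalization, ReLU, inverted dropout,
2x2/stride-2 max pooling, dense layers, softmax cross-entropy and Adam —
in float32, single threaded and fully deterministic given a seeded
generator. Convolutions are evaluated as nine shifted BLAS matmuls, which
is considerably faster than im2col for the wide-and-short EEG "images"
(16 x 1280) this package works on.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-5


# ---------------------------------------------------------------------------
# convolution (3x3, stride 1, same padding)

def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x: (N, Cin, H, Wd); W: (Cout, Cin, 3, 3); b: (Cout,)."""
    N, C, H, Wd = x.shape
    Cout = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    acc = np.zeros((Cout, N, H, Wd), dtype=np.float32)
    for dy in range(3):
        for dx in range(3):
            xs = xp[:, :, dy:dy + H, dx:dx + Wd]
            xs = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(C, -1)
            acc += (W[:, :, dy, dx] @ xs).reshape(Cout, N, H, Wd)
    out = acc.transpose(1, 0, 2, 3) + b.reshape(1, -1, 1, 1)
    return np.ascontiguousarray(out)


def conv3x3_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray):
    """Gradients for :func:`conv3x3_forward`; returns (dx, dW, db)."""
    N, C, H, Wd = x.shape
    Cout = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    do = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(Cout, -1)
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for dy in range(3):
        for dx in range(3):
            xs = xp[:, :, dy:dy + H, dx:dx + Wd]
            xs_m = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(C, -1)
            dW[:, :, dy, dx] = do @ xs_m.T
            dxs = (W[:, :, dy, dx].T @ do).reshape(C, N, H, Wd)
            dxp[:, :, dy:dy + H, dx:dx + Wd] += dxs.transpose(1, 0, 2, 3)
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


# ---------------------------------------------------------------------------
# batch normalization

def bn_forward(x, gamma, beta, running_mean, running_var, train, momentum=0.1):
    """Works for 2-D (N, F) and 4-D (N, C, H, W) inputs; returns (out, cache).

    Running statistics are updated in place during training.
    """
    axes = (0,) if x.ndim == 2 else (0, 2, 3)
    shape = (1, -1) if x.ndim == 2 else (1, -1, 1, 1)
    if train:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + EPS)
    xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.reshape(shape) * xhat + beta.reshape(shape)
    cache = (xhat, gamma, inv_std, axes, shape)
    return out.astype(np.float32), cache


def bn_backward(dout, cache):
    xhat, gamma, inv_std, axes, shape = cache
    m = float(np.prod([dout.shape[a] for a in axes]))
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dxhat = dout * gamma.reshape(shape)
    dx = (
        dxhat
        - dxhat.mean(axis=axes).reshape(shape)
        - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
    ) * inv_std.reshape(shape)
    return dx.astype(np.float32), dgamma, dbeta


# ---------------------------------------------------------------------------
# elementwise / pooling

def relu_forward(x):
    out = np.maximum(x, 0.0)
    return out, x > 0.0


def dropout_forward(x, p, train, rng):
    if not train or p <= 0.0:
        return x, None
    mask = (rng.random(x.shape, dtype=np.float32) >= p) / np.float32(1.0 - p)
    return x * mask, mask


def maxpool2x2_forward(x):
    """2x2 max pooling with stride 2; returns (out, argmax cache)."""
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2x2_backward(dout, cache):
    idx, (N, C, H, W) = cache
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(N, C, H, W)


# ---------------------------------------------------------------------------
# dense / loss

def dense_forward(x, W, b):
    return x @ W + b


def dense_backward(x, W, dout):
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


def softmax_xent(logits, y):
    """Mean cross-entropy over the batch; returns (loss, probs, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return loss, p, (d / n).astype(np.float32)


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with per-parameter state, keyed by parameter name."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            p = params[name]
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            mhat = m / (1.0 - b1 ** self.t)
            vhat = v / (1.0 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)
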