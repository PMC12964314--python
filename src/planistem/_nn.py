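"""Minimal NumPy CNN primitives with manual backpropagation.

Stride-1 convolutions are computed as shift-and-tensordot sums, which is
both memory-light and fast for the small channel counts used here.  All
arrays are ``float32``; tensors are laid out ``(batch, channel, H, W)``.
"""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, out_ch: int, in_ch: int,
            kh: int, kw: int) -> np.ndarray:
    std = np.sqrt(2.0 / (in_ch * kh * kw))
    return rng.normal(0.0, std, (out_ch, in_ch, kh, kw)).astype(np.float32)


def conv2d_forward(x, w, b, pad):
    """Same-size stride-1 convolution.  ``pad`` = ((top,bot),(left,right))."""
    _, _, h, wid = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), pad[0], pad[1]))
    kh, kw = w.shape[2], w.shape[3]
    acc = None
    for i in range(kh):
        for j in range(kw):
            t = np.tensordot(xp[:, :, i:i + h, j:j + wid], w[:, :, i, j],
                             axes=([1], [1]))
            acc = t if acc is None else acc + t
    return np.ascontiguousarray(acc.transpose(0, 3, 1, 2)) \
        + b[None, :, None, None]


def conv2d_backward(dy, x, w, pad):
    _, _, h, wid = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), pad[0], pad[1]))
    kh, kw = w.shape[2], w.shape[3]
    dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))  # (B,H,W,O)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i:i + h, j:j + wid]
            dw[:, :, i, j] = np.tensordot(dyt, patch,
                                          axes=([0, 1, 2], [0, 2, 3]))
            dxp[:, :, i:i + h, j:j + wid] += np.tensordot(
                dyt, w[:, :, i, j], axes=([3], [0])).transpose(0, 3, 1, 2)
    db = dy.sum(axis=(0, 2, 3))
    (pt, _), (pl, _) = pad
    dx = dxp[:, :, pt:pt + h, pl:pl + wid]
    return dx, dw, db


def relu_forward(x):
    return np.maximum(x, 0.0)


def relu_backward(dy, y):
    return np.where(y > 0, dy, 0.0)


def maxpool2_forward(x):
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool2_backward(dy, idx, in_shape):
    b, c, h, w = in_shape
    dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dxr = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dxr.reshape(b, c, h, w))


def upsample2_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy):
    b, c, h, w = dy.shape
    return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
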