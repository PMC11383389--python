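"""Spatial primitives (conv / pool / resample / crop) for the autodiff core.

Convolution is im2col + BLAS matmul; col2im runs k*k strided slice-adds, which
keeps the backward pass vectorized without scatter operations.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _node

__all__ = ["conv2d", "maxpool2x2", "upsample2x_nearest", "crop2d", "conv_output_size"]


def conv_output_size(n: int, kernel: int, stride: int, padding: int) -> int:
    """Standard convolution arithmetic: floor((n + 2p - k) / s) + 1."""
    return (n + 2 * padding - kernel) // stride + 1


def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    col = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            col[:, :, i, j] = xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
    return col


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    xd = x.data
    n, c, h, wd = xd.shape
    o, cw, k, _ = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    oh = conv_output_size(h, k, stride, padding)
    ow = conv_output_size(wd, k, stride, padding)
    if oh < 1 or ow < 1:
        raise ValueError(f"conv2d input {h}x{wd} too small for kernel {k}/stride {stride}")
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xd
    col = _im2col(xp, k, stride, oh, ow)
    colm = col.reshape(n, c * k * k, oh * ow)
    wm = w.data.reshape(o, c * k * k)
    y = np.matmul(wm, colm).reshape(n, o, oh, ow)
    if b is not None:
        y += b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)

    def bw(g):
        gm = g.reshape(n, o, oh * ow)
        if w.requires_grad:
            dw = np.tensordot(gm, colm, axes=([0, 2], [0, 2]))
            w.accumulate(dw.reshape(w.shape))
            if b is not None and b.requires_grad:
                b.accumulate(g.sum(axis=(0, 2, 3)))
        if x._wants_grad():
            dcol = np.matmul(wm.T, gm).reshape(n, c, k, k, oh, ow)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcol[
                        :, :, i, j
                    ]
            if padding:
                dxp = dxp[:, :, padding : padding + h, padding : padding + wd]
            x.accumulate(dxp)

    out._backward = bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    h2, w2 = h // 2, w // 2
    v = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = v.argmax(axis=-1)
    out = _node(np.take_along_axis(v, idx[..., None], axis=-1)[..., 0], (x,))

    def bw(g):
        if x._wants_grad():
            dv = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
            np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
            dx = dv.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            x.accumulate(dx)

    out._backward = bw
    return out


def upsample2x_nearest(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = _node(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))

    def bw(g):
        if x._wants_grad():
            x.accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bw
    return out


def crop2d(x: Tensor, top: int, left: int, height: int, width: int) -> Tensor:
    n, c, h, w = x.data.shape
    out = _node(x.data[:, :, top : top + height, left : left + width], (x,))

    def bw(g):
        if x._wants_grad():
            dx = np.zeros((n, c, h, w), dtype=np.float32)
            dx[:, :, top : top + height, left : left + width] = g
            x.accumulate(dx)

    out._backward = bw
    return out
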