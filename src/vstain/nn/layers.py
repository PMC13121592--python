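"""Convolutional and normalization layers with hand-written gradients.

Convolutions use im2col + BLAS matmul; the transposed convolution is the exact
adjoint of the strided convolution (its forward pass is the convolution's
input-gradient pass), so the two share the col2im/im2col kernels below.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter


def _im2col(x: np.ndarray, k: int, stride: int):
    """x: padded (N,C,H,W) -> columns (N, C*k*k, Ho*Wo), plus (Ho, Wo).

    Filled tap-by-tap with contiguous row slices; a single copy of the
    equivalent 6-D strided view is an order of magnitude slower.
    """
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i:i + ho * stride:stride,
                                 j:j + wo * stride:stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int):
    """Adjoint of _im2col: scatter-add columns back into (N,C,H,W)."""
    n, c, h, w = x_shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    dc = dcols.reshape(n, c, k, k, ho, wo)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(k):
        hi = i + stride * ho
        for j in range(k):
            wj = j + stride * wo
            dx[:, :, i:hi:stride, j:wj:stride] += dc[:, :, i, j]
    return dx


def _pad_zeros(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


_COL_BUDGET = 8_000_000  # max elements in one im2col buffer (~32 MB float32)


class Conv2d(Module):
    """2-D convolution via im2col + GEMM, chunked over output rows so the
    column buffer stays bounded (a full-frame 7x7 im2col would be ~1 GB)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, *, bias=True,
                 rng=None, init_std=0.02, dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, init_std, size=(out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def _row_chunks(self, n, ho, wo):
        ckk = self.in_ch * self.kernel * self.kernel
        rows = max(1, _COL_BUDGET // max(1, n * ckk * wo))
        for r0 in range(0, ho, rows):
            yield r0, min(ho, r0 + rows)

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.padding
        xp = _pad_zeros(x, p)
        n, _, hp, wp = xp.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        wmat = self.weight.data.reshape(self.out_ch, -1)
        y = np.empty((n, self.out_ch, ho, wo), dtype=x.dtype)
        for r0, r1 in self._row_chunks(n, ho, wo):
            xc = xp[:, :, r0 * s:(r1 - 1) * s + k, :]
            cols, hc, _ = _im2col(xc, k, s)
            y[:, :, r0:r1, :] = np.matmul(wmat, cols).reshape(
                n, self.out_ch, hc, wo
            )
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        return y, (xp, x.shape)

    def backward(self, cache, dy):
        xp, x_shape = cache
        k, s, p = self.kernel, self.stride, self.padding
        n, _, hp, wp = xp.shape
        ho, wo = dy.shape[2:]
        wmat = self.weight.data.reshape(self.out_ch, -1)
        dw = np.zeros_like(wmat)
        dxp = np.zeros(xp.shape, dtype=dy.dtype)
        for r0, r1 in self._row_chunks(n, ho, wo):
            xc = xp[:, :, r0 * s:(r1 - 1) * s + k, :]
            cols, hc, _ = _im2col(xc, k, s)
            dy_mat = dy[:, :, r0:r1, :].reshape(n, self.out_ch, -1)
            dw += np.matmul(dy_mat, cols.transpose(0, 2, 1)).sum(axis=0)
            dcols = np.matmul(wmat.T, dy_mat)
            dxp[:, :, r0 * s:(r1 - 1) * s + k, :] += _col2im(
                dcols, (n, self.in_ch, (hc - 1) * s + k, wp), k, s
            )
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2d(Module):
    """Stride-``s`` transposed convolution (adjoint of Conv2d).

    Output size: (H-1)*stride - 2*padding + kernel + output_padding.
    """

    def __init__(self, in_ch, out_ch, kernel, stride=2, padding=1,
                 output_padding=1, *, bias=True, rng=None, init_std=0.02,
                 dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding, self.output_padding = padding, output_padding
        if output_padding >= stride:
            raise ValueError("output_padding must be < stride")
        rng = rng or np.random.default_rng(0)
        # stored with the adjoint convolution's layout: (in_ch, out_ch, k, k)
        w = rng.normal(0.0, init_std, size=(in_ch, out_ch, kernel, kernel))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def _full_shape(self, n, h, w):
        k, s = self.kernel, self.stride
        return (n, self.out_ch, (h - 1) * s + k, (w - 1) * s + k)

    def forward(self, x):
        n, _, h, w = x.shape
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        x_mat = x.reshape(n, self.in_ch, -1)
        wmat = self.weight.data.reshape(self.in_ch, -1)  # (in, out*k*k)
        dcols = np.matmul(wmat.T, x_mat)
        y_full = _col2im(dcols, self._full_shape(n, h, w), k, s)
        hf, wf = y_full.shape[2:]
        y = y_full[:, :, p:hf - p + op, p:wf - p + op]
        if self.bias is not None:
            y = y + self.bias.data[None, :, None, None]
        return y, (x, x_mat)

    def backward(self, cache, dy):
        x, x_mat = cache
        n, _, h, w = x.shape
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        # zero-pad dy back to the uncropped (full) size
        full = self._full_shape(n, h, w)
        dy_full = np.zeros(full, dtype=dy.dtype)
        dy_full[:, :, p:full[2] - p + op, p:full[3] - p + op] = dy
        cols, ho, wo = _im2col(dy_full, k, s)  # ho, wo == h, w
        wmat = self.weight.data.reshape(self.in_ch, -1)
        dx = np.matmul(wmat, cols).reshape(x.shape)
        self.weight.grad += np.matmul(
            x_mat, cols.transpose(0, 2, 1)
        ).sum(axis=0).reshape(self.weight.data.shape)
        return dx


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over spatial dims (no affine)."""

    def __init__(self, num_features, eps=1e-5):
        self.num_features = num_features
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = xc * inv
        return y, (y, inv)

    def backward(self, cache, dy):
        y, inv = cache
        m_dy = dy.mean(axis=(2, 3), keepdims=True)
        m_dyy = (dy * y).mean(axis=(2, 3), keepdims=True)
        return inv * (dy - m_dy - y * m_dyy)


class ReflectionPad2d(Module):
    def __init__(self, pad: int):
        self.pad = pad

    def forward(self, x):
        p = self.pad
        y = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")
        return y, x.shape

    def backward(self, cache, dy):
        p = self.pad
        # reflect padding is separable; fold each border back with a flip
        dh = dy[:, :, p:-p, :].copy()
        dh[:, :, 1:p + 1, :] += dy[:, :, p - 1::-1, :]
        dh[:, :, -p - 1:-1, :] += dy[:, :, :-p - 1:-1, :]
        dx = dh[:, :, :, p:-p].copy()
        dx[:, :, :, 1:p + 1] += dh[:, :, :, p - 1::-1]
        dx[:, :, :, -p - 1:-1] += dh[:, :, :, :-p - 1:-1]
        return dx


class ReLU(Module):
    def forward(self, x):
        y = np.maximum(x, 0)
        return y, (x > 0)

    def backward(self, cache, dy):
        return dy * cache


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        y = np.where(mask, x, self.slope * x)
        return y, mask

    def backward(self, cache, dy):
        return np.where(cache, dy, self.slope * dy)


class Tanh(Module):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, cache, dy):
        return dy * (1.0 - cache * cache)


class MaxPool2d(Module):
    """Non-overlapping max pooling (kernel == stride)."""

    def __init__(self, kernel=2):
        self.kernel = kernel

    def forward(self, x):
        k = self.kernel
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        xv = x[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
        idx = xv.argmax(axis=-1)
        y = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]
        return y, (idx, x.shape)

    def backward(self, cache, dy):
        idx, x_shape = cache
        k = self.kernel
        n, c, h, w = x_shape
        ho, wo = h // k, w // k
        dxv = np.zeros((n, c, ho, wo, k * k), dtype=dy.dtype)
        np.put_along_axis(dxv, idx[..., None], dy[..., None], axis=-1)
        dxv = dxv.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, :, :ho * k, :wo * k] = dxv.reshape(n, c, ho * k, wo * k)
        return dx
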