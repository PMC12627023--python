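"""NumPy layers with forward/backward passes.

All image tensors are NCHW float arrays.  Convolutions are implemented via
im2col + BLAS matmul; the col2im scatter in the backward pass loops over the
(small) kernel footprint only, so it stays vectorized over batch and space.
"""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter, current_dtype, he_normal, uniform_fan_in


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, out_h, out_w); cols has shape (N, out_h*out_w, C*kh*kw)."""
    n, c, h, w = x.shape
    if pad > 0:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    out_h = (hp - kh) // stride + 1
    out_w = (wp - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, out_h, out_w),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = view.transpose(0, 4, 5, 1, 2, 3).reshape(n, out_h * out_w, c * kh * kw)
    return np.ascontiguousarray(cols), out_h, out_w


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add column gradients back to input shape (inverse of _im2col)."""
    n, c, h, w = x_shape
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    dpad = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, out_h, out_w, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        hi = i + stride * out_h
        for j in range(kw):
            wj = j + stride * out_w
            dpad[:, :, i:hi:stride, j:wj:stride] += d6[:, :, i, j]
    if pad > 0:
        return dpad[:, :, pad:-pad, pad:-pad]
    return dpad


class Conv2d(Module):
    """2-D convolution (cross-correlation), optional bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = False, *, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_normal(rng, (out_ch, fan_in), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, out_h, out_w = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        out = cols @ self.weight.data.T  # (N, oh*ow, out_ch)
        if self.bias is not None:
            out += self.bias.data
        self._cache = (cols, x.shape, out_h, out_w)
        n = x.shape[0]
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, out_h, out_w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, out_h, out_w = self._cache
        n = dout.shape[0]
        d2 = dout.reshape(n, self.out_ch, out_h * out_w).transpose(0, 2, 1)
        self.weight.grad += np.einsum("npo,npk->ok", d2, cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += d2.sum(axis=(0, 1))
        dcols = d2 @ self.weight.data
        self._cache = None
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_ch = num_ch
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.running_mean = np.zeros(num_ch, dtype=current_dtype())
        self.running_var = np.ones(num_ch, dtype=current_dtype())
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean += self.momentum * (mean - self.running_mean)
            # unbiased variance in the running estimate, biased in the pass
            unbiased = var * (m / max(m - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        out = self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]
        self._cache = (xhat, inv_std)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        axes = (0, 2, 3)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.data[:, None, None]
        if not self.training:
            return dxhat * inv_std[:, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        sum_d = dxhat.sum(axis=axes)
        sum_dx = (dxhat * xhat).sum(axis=axes)
        dx = (dxhat - (sum_d[:, None, None] + xhat * sum_dx[:, None, None]) / m)
        return dx * inv_std[:, None, None]


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, dout, 0.0)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, dout, self.slope * dout)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        xp = x
        if self.pad > 0:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                        constant_values=-np.inf)
        hp, wp = xp.shape[2], xp.shape[3]
        out_h = (hp - k) // self.stride + 1
        out_w = (wp - k) // self.stride + 1
        s0, s1, s2, s3 = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, shape=(n, c, out_h, out_w, k, k),
            strides=(s0, s1, s2 * self.stride, s3 * self.stride, s2, s3),
            writeable=False)
        flat = view.reshape(n, c, out_h, out_w, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, out_h, out_w)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape, out_h, out_w = self._cache
        self._cache = None
        n, c, h, w = x_shape
        k = self.kernel
        dpad = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dout.dtype)
        ki, kj = np.unravel_index(idx, (k, k))
        oi = np.arange(out_h)[None, None, :, None] * self.stride
        oj = np.arange(out_w)[None, None, None, :] * self.stride
        rows = (oi + ki).ravel()
        cols_ = (oj + kj).ravel()
        nn = np.repeat(np.arange(n), c * out_h * out_w)
        cc = np.tile(np.repeat(np.arange(c), out_h * out_w), n)
        np.add.at(dpad, (nn, cc, rows, cols_), dout.ravel())
        if self.pad > 0:
            return dpad[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dpad


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        self._shape = None
        return np.broadcast_to(dout[:, :, None, None] / (h * w), (n, c, h, w)).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True, *,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        if zero_init:
            w = np.zeros((out_dim, in_dim))
        else:
            w = uniform_fan_in(rng, (out_dim, in_dim), in_dim)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_dim)) if bias else None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.weight.grad += dout.T @ x
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        y, self._y = self._y, None
        return dout * y * (1.0 - y)


class ChannelConv1d(Module):
    """1-D convolution along the channel axis of a (N, C) descriptor.

    Single input/output channel, odd kernel, zero padding (K-1)/2, no bias —
    the efficient-channel-attention convention.
    """

    def __init__(self, kernel: int, *, rng: np.random.Generator):
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and positive, got {kernel}")
        self.kernel = kernel
        self.weight = Parameter(uniform_fan_in(rng, (kernel,), kernel))
        self._xpad = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape
        p = (self.kernel - 1) // 2
        xpad = np.pad(x, ((0, 0), (p, p)))
        out = np.zeros_like(x)
        for j in range(self.kernel):
            out += self.weight.data[j] * xpad[:, j:j + c]
        self._xpad = (xpad, c)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xpad, c = self._xpad
        self._xpad = None
        p = (self.kernel - 1) // 2
        dxpad = np.zeros_like(xpad)
        for j in range(self.kernel):
            self.weight.grad[j] += np.sum(dout * xpad[:, j:j + c])
            dxpad[:, j:j + c] += self.weight.data[j] * dout
        return dxpad[:, p:p + c] if p > 0 else dxpad
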