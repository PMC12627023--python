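"""Multi-scale convolutional feature fusion.

The two branches' final feature maps are concatenated along channels (Y,
2C), passed through parallel 3x3 and 5x5 conv + batch-norm + LeakyReLU
branches (Y1, Y2, each 2C), and the concatenation [Y1; Y2] (4C) is squeezed
by global average pooling and a two-layer fully connected bottleneck with
reduction ratio r to a 4C logit vector S'.  A softmax across the two scale
branches turns S' into per-channel convex weights (S1, S2), and the output
is the residual fusion ``O = Y + S1*Y1 + S2*Y2`` (shape preserved at 2C).

Softmax scope: the default ``"pair"`` normalizes each channel's pair of
scale logits (S'[c], S'[c+2C]) so S1 + S2 = 1 channel-wise, giving a true
per-channel competition between scales.  ``"full"`` applies one softmax
over the whole 4C vector before splitting, the literal alternative reading.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np

from . import nn
from .nn.layers import _im2col


def branch_weights(S_prime: np.ndarray, scope: str = "pair"):
    """Split a length-4C logit vector into two length-2C scale weights.

    With ``scope="pair"`` (default) softmax is taken over each channel's
    two scale logits, so ``S1[c] + S2[c] == 1`` exactly.
    """
    S_prime = np.asarray(S_prime, dtype=float)
    if S_prime.ndim != 1 or S_prime.shape[0] % 2 != 0:
        raise ValueError("S_prime must be a 1-D vector of even length")
    half = S_prime.shape[0] // 2
    a, b = S_prime[:half], S_prime[half:]
    if scope == "pair":
        m = np.maximum(a, b)
        ea, eb = np.exp(a - m), np.exp(b - m)
        s1 = ea / (ea + eb)
        return s1, 1.0 - s1  # exact channel-wise normalization
    if scope == "full":
        e = np.exp(S_prime - S_prime.max())
        p = e / e.sum()
        return p[:half], p[half:]
    raise ValueError(f"unknown softmax scope {scope!r}")


@dataclasses.dataclass
class MscffParams:
    """Explicit parameters for the functional fusion op (inference form).

    Batch-norm enters through fixed statistics (gamma, beta, mean, var),
    matching evaluation-mode behaviour.
    """

    conv3_w: np.ndarray            # (2C, 2C, 3, 3)
    bn3: Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    conv5_w: np.ndarray            # (2C, 2C, 5, 5)
    bn5: Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    w1: np.ndarray                 # (4C/r, 4C)
    b1: np.ndarray                 # (4C/r,)
    w2: np.ndarray                 # (4C, 4C/r)
    b2: np.ndarray                 # (4C,)
    r: int = 16
    leaky_slope: float = 0.01
    softmax_scope: str = "pair"
    eps: float = 1e-5


def random_mscff_params(C: int, r: int = 4, *, rng: np.random.Generator,
                        scale: float = 0.3) -> MscffParams:
    """Small random parameters for testing; 4C must be divisible by r."""
    if (4 * C) % r != 0:
        raise ValueError(f"4C = {4 * C} not divisible by r = {r}")
    c2, c4 = 2 * C, 4 * C
    hid = c4 // r
    def bn(c):
        return (rng.uniform(0.5, 1.5, c), rng.normal(0, scale, c),
                rng.normal(0, scale, c), rng.uniform(0.5, 1.5, c))
    return MscffParams(
        conv3_w=rng.normal(0, scale, (c2, c2, 3, 3)),
        bn3=bn(c2),
        conv5_w=rng.normal(0, scale, (c2, c2, 5, 5)),
        bn5=bn(c2),
        w1=rng.normal(0, scale, (hid, c4)), b1=rng.normal(0, scale, hid),
        w2=rng.normal(0, scale, (c4, hid)), b2=rng.normal(0, scale, c4),
        r=r,
    )


def _conv_same(x_hwc: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Spatial-size-preserving conv of an H x W x C array with (Co,Ci,k,k)."""
    co, ci, k, _ = w.shape
    pad = (k - 1) // 2
    x = x_hwc.transpose(2, 0, 1)[None]  # 1,C,H,W
    cols, oh, ow = _im2col(x, k, k, 1, pad)
    out = cols[0] @ w.reshape(co, ci * k * k).T  # (oh*ow, co)
    return out.reshape(oh, ow, co)


def _bn_eval(x_hwc: np.ndarray, stats, eps: float) -> np.ndarray:
    gamma, beta, mean, var = stats
    return gamma * (x_hwc - mean) / np.sqrt(var + eps) + beta


def mscff_forward(Ff: np.ndarray, Fb: np.ndarray, params: MscffParams) -> np.ndarray:
    """Fuse two H x W x C maps into an H x W x 2C output (inference mode)."""
    Ff = np.asarray(Ff, dtype=float)
    Fb = np.asarray(Fb, dtype=float)
    if Ff.shape != Fb.shape or Ff.ndim != 3:
        raise ValueError(f"branch shape mismatch: {Ff.shape} vs {Fb.shape}")
    c2 = 2 * Ff.shape[2]
    if (2 * c2) % params.r != 0:
        raise ValueError(f"4C = {2 * c2} not divisible by r = {params.r}")
    slope = params.leaky_slope

    Y = np.concatenate([Ff, Fb], axis=2)
    def scale_branch(w, bn):
        z = _bn_eval(_conv_same(Y, w), bn, params.eps)
        return np.where(z > 0, z, slope * z)
    Y1 = scale_branch(params.conv3_w, params.bn3)
    Y2 = scale_branch(params.conv5_w, params.bn5)
    Yhat = np.concatenate([Y1, Y2], axis=2)
    S = Yhat.mean(axis=(0, 1))
    h = np.maximum(params.w1 @ S + params.b1, 0.0)
    S_prime = params.w2 @ h + params.b2
    S1, S2 = branch_weights(S_prime, params.softmax_scope)
    return Y + S1 * Y1 + S2 * Y2


class MSCFF(nn.Module):
    """Trainable fusion block on NCHW batches of the two stage-5 maps."""

    def __init__(self, channels: int, r: int = 16, leaky_slope: float = 0.01,
                 softmax_scope: str = "pair", *, rng: np.random.Generator):
        super().__init__()
        c2, c4 = 2 * channels, 4 * channels
        if c4 % r != 0:
            raise ValueError(f"4C = {c4} not divisible by r = {r}")
        if softmax_scope not in ("pair", "full"):
            raise ValueError(f"unknown softmax scope {softmax_scope!r}")
        self.channels = channels
        self.r = r
        self.softmax_scope = softmax_scope
        self.conv3 = nn.Conv2d(c2, c2, 3, pad=1, rng=rng)
        self.bn3 = nn.BatchNorm2d(c2)
        self.act3 = nn.LeakyReLU(leaky_slope)
        self.conv5 = nn.Conv2d(c2, c2, 5, pad=2, rng=rng)
        self.bn5 = nn.BatchNorm2d(c2)
        self.act5 = nn.LeakyReLU(leaky_slope)
        self.fc1 = nn.Linear(c4, c4 // r, rng=rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Linear(c4 // r, c4, rng=rng)
        self._cache = None

    def forward(self, Ff: np.ndarray, Fb: np.ndarray) -> np.ndarray:
        if Ff.shape != Fb.shape:
            raise ValueError(f"branch shape mismatch: {Ff.shape} vs {Fb.shape}")
        n, c, h, w = Ff.shape
        Y = np.concatenate([Ff, Fb], axis=1)
        Y1 = self.act3.forward(self.bn3.forward(self.conv3.forward(Y)))
        Y2 = self.act5.forward(self.bn5.forward(self.conv5.forward(Y)))
        S = np.concatenate([Y1.mean(axis=(2, 3)), Y2.mean(axis=(2, 3))], axis=1)
        S_prime = self.fc2.forward(self.relu.forward(self.fc1.forward(S)))
        S1, S2 = self._softmax(S_prime)
        out = Y + S1[:, :, None, None] * Y1 + S2[:, :, None, None] * Y2
        self._cache = (Y1, Y2, S1, S2, c, h * w)
        return out

    def _softmax(self, S_prime: np.ndarray):
        half = S_prime.shape[1] // 2
        a, b = S_prime[:, :half], S_prime[:, half:]
        if self.softmax_scope == "pair":
            m = np.maximum(a, b)
            ea, eb = np.exp(a - m), np.exp(b - m)
            s1 = ea / (ea + eb)
            return s1, 1.0 - s1
        e = np.exp(S_prime - S_prime.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        return p[:, :half], p[:, half:]

    def _softmax_backward(self, S1, S2, dS1, dS2):
        if self.softmax_scope == "pair":
            # per-channel two-way softmax jacobian
            da = S1 * S2 * (dS1 - dS2)
            return np.concatenate([da, -da], axis=1)
        p = np.concatenate([S1, S2], axis=1)
        dp = np.concatenate([dS1, dS2], axis=1)
        inner = (dp * p).sum(axis=1, keepdims=True)
        return p * (dp - inner)

    def backward(self, dout: np.ndarray):
        Y1, Y2, S1, S2, c, hw = self._cache
        self._cache = None
        dY = dout.copy()
        dY1 = S1[:, :, None, None] * dout
        dY2 = S2[:, :, None, None] * dout
        dS1 = (dout * Y1).sum(axis=(2, 3))
        dS2 = (dout * Y2).sum(axis=(2, 3))
        dS_prime = self._softmax_backward(S1, S2, dS1, dS2)
        dS = self.fc1.backward(self.relu.backward(self.fc2.backward(dS_prime)))
        half = dS.shape[1] // 2
        dY1 += dS[:, :half, None, None] / hw
        dY2 += dS[:, half:, None, None] / hw
        dY += self.conv3.backward(self.bn3.backward(self.act3.backward(dY1)))
        dY += self.conv5.backward(self.bn5.backward(self.act5.backward(dY2)))
        return dY[:, :c], dY[:, c:]
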