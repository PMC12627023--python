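"""Dual efficient channel attention.

Shared channel weights are computed from the element-wise sum of the two
branches' same-stage feature maps: global average pooling gives a channel
descriptor, a bias-free 1-D convolution with an adaptive odd kernel models
local cross-channel interaction, and a sigmoid maps the result into (0, 1).
The same weight vector multiplicatively reweights both branches, so the two
views are modulated identically and can exchange information through the
shared descriptor.

Kernel-size rule: ``K = odd(trunc((log2 C + b) / gamma))`` with gamma=2,
b=1, where ``odd`` bumps an even truncation up by one.  (The alternative
grouping ``log2 C + b/gamma`` is rejected; the adopted reading is the
established efficient-channel-attention convention.)
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import nn


def adaptive_kernel_size(C: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive odd 1-D kernel size for a C-channel feature map."""
    if not isinstance(C, (int, np.integer)) or C < 1:
        raise ValueError(f"channel count must be a positive integer, got {C!r}")
    t = int((math.log2(C) + b) / gamma)  # truncate toward zero
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)


@dataclasses.dataclass
class DecaParams:
    """Explicit parameters for the functional attention op."""

    conv_weights: np.ndarray  # length-K kernel, K odd, no bias
    gamma: int = 2
    b: int = 1

    def __post_init__(self):
        self.conv_weights = np.asarray(self.conv_weights, dtype=float)
        k = self.conv_weights.shape[0]
        if self.conv_weights.ndim != 1 or k < 1 or k % 2 == 0:
            raise ValueError("conv_weights must be a 1-D odd-length vector")

    @property
    def conv_kernel(self) -> int:
        return self.conv_weights.shape[0]


def _conv1d_channels(desc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    c = desc.shape[-1]
    k = weights.shape[0]
    p = (k - 1) // 2
    padded = np.pad(desc, [(0, 0)] * (desc.ndim - 1) + [(p, p)])
    out = np.zeros_like(desc)
    for j in range(k):
        out += weights[j] * padded[..., j:j + c]
    return out


def deca_forward(Ff: np.ndarray, Fb: np.ndarray, params: DecaParams):
    """Apply shared channel attention to a front/back feature-map pair.

    Arguments are H x W x C arrays.  Returns ``(Ff_hat, Fb_hat, w)`` where
    ``w`` is the length-C channel-weight vector, entries strictly in (0, 1).
    """
    Ff = np.asarray(Ff, dtype=float)
    Fb = np.asarray(Fb, dtype=float)
    if Ff.shape != Fb.shape or Ff.ndim != 3:
        raise ValueError(f"branch shape mismatch: {Ff.shape} vs {Fb.shape}")
    c = Ff.shape[2]
    expected = adaptive_kernel_size(c, params.gamma, params.b)
    if params.conv_kernel != expected:
        raise ValueError(
            f"conv kernel {params.conv_kernel} does not match adaptive size "
            f"{expected} for C={c}"
        )
    fused = Ff + Fb
    desc = fused.mean(axis=(0, 1))
    w = 1.0 / (1.0 + np.exp(-_conv1d_channels(desc, params.conv_weights)))
    return Ff * w, Fb * w, w


class DECA(nn.Module):
    """Trainable attention block operating on NCHW batches of both branches."""

    def __init__(self, channels: int, gamma: int = 2, b: int = 1, *,
                 rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.kernel = adaptive_kernel_size(channels, gamma, b)
        self.conv = nn.ChannelConv1d(self.kernel, rng=rng)
        self.sigmoid = nn.Sigmoid()
        self._cache = None

    def forward(self, Ff: np.ndarray, Fb: np.ndarray):
        if Ff.shape != Fb.shape:
            raise ValueError(f"branch shape mismatch: {Ff.shape} vs {Fb.shape}")
        desc = (Ff + Fb).mean(axis=(2, 3))  # (N, C)
        w = self.sigmoid.forward(self.conv.forward(desc))
        w4 = w[:, :, None, None]
        self._cache = (Ff, Fb, w, Ff.shape[2] * Ff.shape[3])
        return Ff * w4, Fb * w4

    def backward(self, dFf_hat: np.ndarray, dFb_hat: np.ndarray):
        Ff, Fb, w, hw = self._cache
        self._cache = None
        w4 = w[:, :, None, None]
        dw = (dFf_hat * Ff + dFb_hat * Fb).sum(axis=(2, 3))
        ddesc = self.conv.backward(self.sigmoid.backward(dw))
        dP = ddesc[:, :, None, None] / hw
        return dFf_hat * w4 + dP, dFb_hat * w4 + dP
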