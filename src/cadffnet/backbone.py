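"""Residual-network feature extractor with per-stage access.

Stage numbering follows the conv2_x..conv5_x convention: the stem (7x7/2
conv + BN + ReLU + 3x3/2 max-pool) is stage 1, and the four residual block
groups are stages 2-5.  A 224 px input therefore yields stage spatial sides
{56, 28, 14, 7} and, for depth 18 at base width 64, channel widths
{64, 128, 256, 512}.  Each stage can be run (and back-propagated)
individually so attention modules can intervene between stages.
"""

from __future__ import annotations

import dataclasses
from typing import List

import numpy as np

from . import nn

BLOCK_COUNTS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3),
                50: (3, 4, 6, 3), 101: (3, 4, 23, 3)}
BASIC_DEPTHS = (18, 34)


@dataclasses.dataclass(frozen=True)
class BackboneConfig:
    depth: int = 18
    base_width: int = 64
    pretrained: bool = False

    def __post_init__(self):
        if self.depth not in BLOCK_COUNTS:
            raise ValueError(f"depth must be one of {sorted(BLOCK_COUNTS)}, "
                             f"got {self.depth}")
        if self.base_width < 1:
            raise ValueError("base_width must be positive")
        if self.pretrained:
            raise ValueError(
                "no bundled pretrained weights are available; load a "
                "checkpoint explicitly instead"
            )

    @property
    def block_kind(self) -> str:
        return "basic" if self.depth in BASIC_DEPTHS else "bottleneck"

    @property
    def expansion(self) -> int:
        return 1 if self.block_kind == "basic" else 4

    def stage_channels(self) -> List[int]:
        return [self.base_width * m * self.expansion for m in (1, 2, 4, 8)]

    @property
    def out_channels(self) -> int:
        return self.stage_channels()[-1]


@dataclasses.dataclass
class FeatureMap:
    """Stage activations in H x W x C layout plus the stage id (2-5)."""

    values: np.ndarray
    stage_id: int

    def __post_init__(self):
        if self.stage_id not in (2, 3, 4, 5):
            raise ValueError(f"stage_id must be in 2..5, got {self.stage_id}")
        if self.values.ndim != 3:
            raise ValueError("values must be H x W x C")


class _BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, in_ch: int, out_ch: int, stride: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, pad=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.relu_out = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        out = self.bn2.forward(self.conv2.forward(out))
        if self.down_conv is not None:
            skip = self.down_bn.forward(self.down_conv.forward(x))
        else:
            skip = x
        return self.relu_out.forward(out + skip)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(dsum)))))
        if self.down_conv is not None:
            dskip = self.down_conv.backward(self.down_bn.backward(dsum))
        else:
            dskip = dsum
        return dmain + dskip


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch: int, width: int, stride: int, *,
                 rng: np.random.Generator):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, pad=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv2d(width, out_ch, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.relu_out = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        out = self.relu2.forward(self.bn2.forward(self.conv2.forward(out)))
        out = self.bn3.forward(self.conv3.forward(out))
        if self.down_conv is not None:
            skip = self.down_bn.forward(self.down_conv.forward(x))
        else:
            skip = x
        return self.relu_out.forward(out + skip)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        d = self.conv3.backward(self.bn3.backward(dsum))
        d = self.conv2.backward(self.bn2.backward(self.relu2.backward(d)))
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))
        if self.down_conv is not None:
            dskip = self.down_conv.backward(self.down_bn.backward(dsum))
        else:
            dskip = dsum
        return dmain + dskip


class ResNetBranch(nn.Module):
    """One backbone branch with independently owned parameters."""

    def __init__(self, cfg: BackboneConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        bw = cfg.base_width
        self.stem_conv = nn.Conv2d(3, bw, 7, stride=2, pad=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(bw)
        self.stem_relu = nn.ReLU()
        self.stem_pool = nn.MaxPool2d(3, 2, 1)

        counts = BLOCK_COUNTS[cfg.depth]
        basic = cfg.block_kind == "basic"
        self.stages: List[List[nn.Module]] = []
        in_ch = bw
        for i, n_blocks in enumerate(counts):
            width = bw * (2 ** i)
            out_ch = width * cfg.expansion
            blocks: List[nn.Module] = []
            for j in range(n_blocks):
                stride = 2 if (i > 0 and j == 0) else 1
                if basic:
                    blocks.append(_BasicBlock(in_ch, out_ch, stride, rng=rng))
                else:
                    blocks.append(_Bottleneck(in_ch, width, stride, rng=rng))
                in_ch = out_ch
            self.stages.append(blocks)

    # -- forward pieces ---------------------------------------------------
    def forward_stem(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[2] != x.shape[3] or x.shape[2] % 32 != 0:
            raise ValueError(
                f"input must be square NCHW with side divisible by 32, "
                f"got shape {x.shape}"
            )
        out = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x)))
        return self.stem_pool.forward(out)

    def forward_stage(self, index: int, x: np.ndarray) -> np.ndarray:
        for block in self.stages[index]:
            x = block.forward(x)
        return x

    # -- backward pieces --------------------------------------------------
    def backward_stage(self, index: int, dout: np.ndarray) -> np.ndarray:
        for block in reversed(self.stages[index]):
            dout = block.backward(dout)
        return dout

    def backward_stem(self, dout: np.ndarray) -> np.ndarray:
        d = self.stem_pool.backward(dout)
        return self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(d)))


def extract_stages(image: np.ndarray, branch: ResNetBranch):
    """Run one H x W x 3 image through the branch; return stage 2-5 maps."""
    x = np.asarray(image, dtype=nn.current_dtype())
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"image must be H x W x 3, got {x.shape}")
    x = x.transpose(2, 0, 1)[None]
    x = branch.forward_stem(x)
    feats = []
    for i in range(4):
        x = branch.forward_stage(i, x)
        feats.append(FeatureMap(values=x[0].transpose(1, 2, 0), stage_id=i + 2))
    return tuple(feats)


def resume_stage(feature: FeatureMap, branch: ResNetBranch) -> FeatureMap:
    """Apply the next stage's blocks to a (possibly reweighted) feature map."""
    if feature.stage_id not in (2, 3, 4):
        raise ValueError(f"cannot resume from stage {feature.stage_id}")
    index = feature.stage_id - 1  # stage s output feeds block group of stage s+1
    expected_c = branch.cfg.stage_channels()[feature.stage_id - 2]
    if feature.values.shape[2] != expected_c:
        raise ValueError(
            f"stage {feature.stage_id} feature has {feature.values.shape[2]} "
            f"channels, expected {expected_c}"
        )
    x = feature.values.transpose(2, 0, 1)[None].astype(nn.current_dtype())
    out = branch.forward_stage(index, x)
    return FeatureMap(values=out[0].transpose(1, 2, 0),
                      stage_id=feature.stage_id + 1)
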