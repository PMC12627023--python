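"""Full dual-branch regression network assembly.

Wiring: two parameter-independent backbone branches process the front and
back views; after each configured intermediate stage (2-4) a shared-weight
channel-attention block reweights both branches before the next stage; the
stage-5 maps are either fused by the multi-scale fusion block or plainly
concatenated; global average pooling and a single affine head produce one
scalar.  Internally the head works on labels scaled by 1/100 — ``forward``
returns predictions back on the percent scale.

Single-branch configurations drop the unused branch, attention and fusion
entirely, but keep the identical head geometry on C channels.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .backbone import BackboneConfig, ResNetBranch
from .deca import DECA
from .mscff import MSCFF

BRANCH_MODES = ("front_only", "back_only", "dual")

#: percent label per unit of raw head output
OUTPUT_SCALE = 100.0


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    depth: int = 18
    base_width: int = 64
    branch_mode: str = "dual"
    deca_stages: Tuple[int, ...] = (2, 3, 4)
    deca_gamma: int = 2
    deca_b: int = 1
    deca_replace: bool = True
    mscff_enabled: bool = True
    mscff_r: int = 16
    mscff_softmax_scope: str = "pair"
    mscff_leaky_slope: float = 0.01
    clip_predictions: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.branch_mode not in BRANCH_MODES:
            raise ConfigError(f"branch_mode must be one of {BRANCH_MODES}, "
                              f"got {self.branch_mode!r}")
        stages = tuple(sorted(set(self.deca_stages)))
        if any(s not in (2, 3, 4) for s in stages):
            raise ConfigError(f"deca_stages must be a subset of {{2,3,4}}, "
                              f"got {self.deca_stages}")
        object.__setattr__(self, "deca_stages", stages)
        if self.branch_mode != "dual" and (stages or self.mscff_enabled):
            raise ConfigError(
                "attention and fusion require branch_mode='dual'"
            )
        BackboneConfig(depth=self.depth, base_width=self.base_width)

    @property
    def backbone(self) -> BackboneConfig:
        return BackboneConfig(depth=self.depth, base_width=self.base_width)

    @property
    def head_input_dim(self) -> int:
        c = self.backbone.out_channels
        return 2 * c if self.branch_mode == "dual" else c

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["deca_stages"] = list(d["deca_stages"])
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "ModelConfig":
        d = dict(d)
        if "deca_stages" in d:
            d["deca_stages"] = tuple(d["deca_stages"])
        return cls(**d)


class CADFFNet(nn.Module):
    """The assembled network.  All randomness comes from ``cfg.seed``."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        bb = cfg.backbone
        self.front = (ResNetBranch(bb, rng=rng)
                      if cfg.branch_mode in ("front_only", "dual") else None)
        self.back = (ResNetBranch(bb, rng=rng)
                     if cfg.branch_mode in ("back_only", "dual") else None)
        self.deca_modules = []
        if cfg.branch_mode == "dual":
            chans = bb.stage_channels()
            for s in cfg.deca_stages:
                self.deca_modules.append(
                    DECA(chans[s - 2], cfg.deca_gamma, cfg.deca_b, rng=rng))
        self._deca_by_stage = dict(zip(cfg.deca_stages, self.deca_modules))
        self.mscff = None
        if cfg.branch_mode == "dual" and cfg.mscff_enabled:
            self.mscff = MSCFF(bb.out_channels, r=cfg.mscff_r,
                               leaky_slope=cfg.mscff_leaky_slope,
                               softmax_scope=cfg.mscff_softmax_scope, rng=rng)
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(cfg.head_input_dim, 1, rng=rng)
        self._split_c = bb.out_channels

    # -- forward/backward on the raw (scaled) output ----------------------
    def forward_raw(self, front: Optional[np.ndarray],
                    back: Optional[np.ndarray]) -> np.ndarray:
        cfg = self.cfg
        f = self.front.forward_stem(front) if self.front is not None else None
        b = self.back.forward_stem(back) if self.back is not None else None
        for i in range(4):
            sid = i + 2
            if f is not None:
                f = self.front.forward_stage(i, f)
            if b is not None:
                b = self.back.forward_stage(i, b)
            deca = self._deca_by_stage.get(sid)
            if deca is not None and cfg.deca_replace:
                f, b = deca.forward(f, b)
        if cfg.branch_mode == "dual":
            if self.mscff is not None:
                fused = self.mscff.forward(f, b)
            else:
                fused = np.concatenate([f, b], axis=1)
        else:
            fused = f if f is not None else b
        pooled = self.gap.forward(fused)
        return self.head.forward(pooled)[:, 0]

    def backward_raw(self, dz: np.ndarray) -> None:
        cfg = self.cfg
        dpooled = self.head.backward(dz[:, None])
        dfused = self.gap.backward(dpooled)
        if cfg.branch_mode == "dual":
            if self.mscff is not None:
                df, db = self.mscff.backward(dfused)
            else:
                df, db = dfused[:, :self._split_c], dfused[:, self._split_c:]
        else:
            df = dfused if self.front is not None else None
            db = dfused if self.back is not None else None
        for i in reversed(range(4)):
            sid = i + 2
            deca = self._deca_by_stage.get(sid)
            if deca is not None and cfg.deca_replace:
                df, db = deca.backward(df, db)
            if self.front is not None:
                df = self.front.backward_stage(i, df)
            if self.back is not None:
                db = self.back.backward_stage(i, db)
        if self.front is not None:
            self.front.backward_stem(df)
        if self.back is not None:
            self.back.backward_stem(db)

    def forward(self, front: Optional[np.ndarray],
                back: Optional[np.ndarray] = None) -> np.ndarray:
        """Predict moisture content in percent for an NCHW batch pair."""
        preds = OUTPUT_SCALE * self.forward_raw(front, back)
        if self.cfg.clip_predictions:
            preds = np.clip(preds, 0.0, 100.0)
        return preds


def mse_loss(y_hat: Sequence[float], y: Sequence[float]) -> float:
    """Mean squared error between predictions and targets."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.size == 0:
        raise ValueError("mse_loss requires at least one prediction")
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    return float(np.mean((y_hat - y) ** 2))


def parameter_count(cfg: ModelConfig) -> Dict[str, int]:
    """Exact trainable-parameter counts, decomposed per component."""
    model = CADFFNet(cfg)
    groups: Dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        key = {"front": "front_branch", "back": "back_branch",
               "deca_modules": "deca", "mscff": "mscff",
               "head": "head"}.get(top, top)
        groups[key] = groups.get(key, 0) + p.size
    groups["total"] = sum(v for k, v in groups.items())
    return groups


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(model: CADFFNet, path) -> Path:
    """Serialize config + weights to a single .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path


def load_checkpoint(path) -> CADFFNet:
    with np.load(Path(path)) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = CADFFNet(cfg)
    model.load_state_dict(state)
    return model
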