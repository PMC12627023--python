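"""Metrics, training loop, cross-validation and experiment grids.

Targets are rescaled by ``target_scale`` (default 0.01, i.e. percent -> unit
interval) for optimization, and predictions are rescaled back to percent
before any metric is computed, so the scale can never leak into reported
numbers.  Validation always runs in evaluation mode (batch-norm running
statistics frozen).
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_manifest import SampleRecord, load_arrays, make_cv_folds
from .model import CADFFNet, ModelConfig, OUTPUT_SCALE
from .nn import Adam

log = logging.getLogger("cadffnet")


# -- metrics (closed forms) -----------------------------------------------

def _check_pair(y, y_hat):
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise ValueError("metrics require at least one sample")
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def r_squared(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Coefficient of determination: 1 - SS_res / SS_tot."""
    y, y_hat = _check_pair(y, y_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined for constant targets")
    ss_res = float(np.sum((y_hat - y) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def mae(y: Sequence[float], y_hat: Sequence[float]) -> float:
    y, y_hat = _check_pair(y, y_hat)
    return float(np.mean(np.abs(y_hat - y)))


@dataclasses.dataclass
class MetricsReport:
    r2: float
    rmse_percent: float
    mae_percent: float
    n: int

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class CvSummary:
    per_fold: List[MetricsReport]
    mean: Dict[str, float]
    std: Dict[str, float]

    def to_dict(self) -> Dict:
        return {
            "per_fold": [m.to_dict() for m in self.per_fold],
            "mean": self.mean,
            "std": self.std,
        }


def summarize_folds(reports: Sequence[MetricsReport]) -> CvSummary:
    """Aggregate fold metrics as mean +/- sample standard deviation."""
    arr = {
        "r2": np.array([m.r2 for m in reports]),
        "rmse_percent": np.array([m.rmse_percent for m in reports]),
        "mae_percent": np.array([m.mae_percent for m in reports]),
    }
    mean = {k: float(v.mean()) for k, v in arr.items()}
    std = {k: float(v.std(ddof=1)) if v.size > 1 else 0.0
           for k, v in arr.items()}
    return CvSummary(per_fold=list(reports), mean=mean, std=std)


# -- training -------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    target_scale: float = 0.01
    checkpoint_policy: str = "best_mae"  # or "last"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.checkpoint_policy not in ("best_mae", "last"):
            raise ValueError(f"unknown checkpoint policy "
                             f"{self.checkpoint_policy!r}")


Arrays = Tuple[np.ndarray, np.ndarray, np.ndarray]  # front, back, labels


def _batched_predict(model: CADFFNet, front, back, batch_size: int = 64):
    """Percent-scale predictions in evaluation mode."""
    was_training = model.training
    model.eval()
    n = front.shape[0] if front is not None else back.shape[0]
    preds = np.empty(n, dtype=float)
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        fb = front[sl] if front is not None else None
        bb = back[sl] if back is not None else None
        preds[sl] = model.forward(fb, bb)
    if was_training:
        model.train()
    return preds


def _branch_inputs(model: CADFFNet, front, back):
    f = front if model.front is not None else None
    b = back if model.back is not None else None
    return f, b


def evaluate(model: CADFFNet, data: Arrays) -> MetricsReport:
    front, back, y = data
    f, b = _branch_inputs(model, front, back)
    preds = _batched_predict(model, f, b)
    return MetricsReport(
        r2=r_squared(y, preds),
        rmse_percent=rmse(y, preds),
        mae_percent=mae(y, preds),
        n=int(np.size(y)),
    )


def train(model: CADFFNet, train_data: Arrays, val_data: Optional[Arrays],
          tc: TrainConfig) -> Tuple[CADFFNet, List[Dict]]:
    """Minimize MSE on scaled targets with Adam; track validation metrics.

    Returns the model holding the checkpoint selected by
    ``tc.checkpoint_policy`` and a per-epoch history list.
    """
    front, back, y = train_data
    n = y.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    y_scaled = np.asarray(y, dtype=float) * tc.target_scale
    # raw head output is on the 1/OUTPUT_SCALE label scale; reconcile
    raw_factor = tc.target_scale * OUTPUT_SCALE

    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.parameters(), lr=tc.learning_rate)
    history: List[Dict] = []
    best_mae = np.inf
    best_state = None

    for epoch in range(tc.epochs):
        model.train()
        perm = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, tc.batch_size):
            idx = perm[start:start + tc.batch_size]
            f, b = _branch_inputs(model, front[idx], back[idx])
            z = model.forward_raw(f, b) * raw_factor
            resid = z - y_scaled[idx]
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            dz = (2.0 / idx.size) * resid * raw_factor
            opt.zero_grad()
            model.backward_raw(dz)
            opt.step()
            losses.append(loss)
            weights.append(idx.size)
        entry = {"epoch": epoch,
                 "train_loss": float(np.average(losses, weights=weights))}
        if val_data is not None:
            report = evaluate(model, val_data)
            entry.update(val_r2=report.r2, val_rmse=report.rmse_percent,
                         val_mae=report.mae_percent)
            if report.mae_percent < best_mae:
                best_mae = report.mae_percent
                best_state = copy.deepcopy(model.state_dict())
        history.append(entry)
        log.info("epoch %d: %s", epoch,
                 {k: round(v, 4) for k, v in entry.items() if k != "epoch"})

    if (tc.checkpoint_policy == "best_mae" and best_state is not None):
        model.load_state_dict(best_state)
    return model, history


# -- cross-validation and grids -------------------------------------------

def records_to_arrays(records: Sequence[SampleRecord], side_px: int) -> Arrays:
    return load_arrays(records, side_px=side_px)


def run_cv(records: Sequence[SampleRecord], model_cfg: ModelConfig,
           tc: TrainConfig, k: int = 5, side_px: int = 224,
           fold_seed: int = 0,
           arrays: Optional[Arrays] = None) -> CvSummary:
    """k-fold cross-validation with seeded folds and per-fold fresh models."""
    folds = make_cv_folds(records, k, seed=fold_seed)
    if arrays is None:
        arrays = records_to_arrays(records, side_px)
    front, back, y = arrays
    reports = []
    for fold_idx, (tr, va) in enumerate(folds):
        cfg = dataclasses.replace(model_cfg, seed=model_cfg.seed + fold_idx)
        model = CADFFNet(cfg)
        fold_tc = dataclasses.replace(tc, seed=tc.seed + fold_idx)
        model, _ = train(model, (front[tr], back[tr], y[tr]),
                         (front[va], back[va], y[va]), fold_tc)
        reports.append(evaluate(model, (front[va], back[va], y[va])))
        log.info("fold %d: %s", fold_idx, reports[-1].to_dict())
    return summarize_folds(reports)


def table2_grid(base: ModelConfig) -> Dict[str, ModelConfig]:
    """Ablation rows: single branches, plain dual, +attention, +fusion, full."""
    rep = dataclasses.replace
    return {
        "front_only": rep(base, branch_mode="front_only", deca_stages=(),
                          mscff_enabled=False),
        "back_only": rep(base, branch_mode="back_only", deca_stages=(),
                         mscff_enabled=False),
        "dual": rep(base, branch_mode="dual", deca_stages=(),
                    mscff_enabled=False),
        "dual_deca": rep(base, branch_mode="dual", deca_stages=(2, 3, 4),
                         mscff_enabled=False),
        "dual_mscff": rep(base, branch_mode="dual", deca_stages=(),
                          mscff_enabled=True),
        "full": rep(base, branch_mode="dual", deca_stages=(2, 3, 4),
                    mscff_enabled=True),
    }


def table3_grid(base: ModelConfig) -> Dict[str, ModelConfig]:
    """Attention-placement rows: all subsets of stages {2, 3, 4}, fusion on."""
    subsets = [(), (2,), (3,), (4,), (2, 3), (3, 4), (2, 4), (2, 3, 4)]
    grid = {}
    for stages in subsets:
        name = "deca_" + ("".join(str(s) for s in stages) or "none")
        grid[name] = dataclasses.replace(
            base, branch_mode="dual", deca_stages=stages, mscff_enabled=True)
    return grid


def run_ablation(records: Sequence[SampleRecord],
                 grid: Dict[str, ModelConfig], tc: TrainConfig, k: int = 5,
                 side_px: int = 224, fold_seed: int = 0,
                 test_records: Optional[Sequence[SampleRecord]] = None,
                 arrays: Optional[Arrays] = None) -> Dict[str, Dict]:
    """Evaluate every variant under byte-identical folds and train settings."""
    if not grid:
        raise ValueError("empty ablation grid")
    if arrays is None:
        arrays = records_to_arrays(records, side_px)
    test_arrays = (records_to_arrays(test_records, side_px)
                   if test_records is not None else None)
    results: Dict[str, Dict] = {}
    for name, cfg in grid.items():
        log.info("ablation variant %s", name)
        summary = run_cv(records, cfg, tc, k=k, side_px=side_px,
                         fold_seed=fold_seed, arrays=arrays)
        entry = {"cv": summary.to_dict()}
        if test_arrays is not None:
            model = CADFFNet(cfg)
            model, _ = train(model, arrays, None,
                             dataclasses.replace(tc, checkpoint_policy="last"))
            entry["independent"] = evaluate(model, test_arrays).to_dict()
        results[name] = entry
    return results
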