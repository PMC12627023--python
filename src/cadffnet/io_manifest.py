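"""Paired-image manifests, moisture labels, image loading, CV folds.

A manifest is a UTF-8 CSV with header ``sample_id,front_path,back_path,
moisture_percent``; relative image paths are resolved against the manifest's
own directory so a dataset folder can be moved as a unit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = ["sample_id", "front_path", "back_path", "moisture_percent"]


class ManifestError(ValueError):
    """Raised for malformed manifests or invalid records."""


@dataclasses.dataclass(frozen=True)
class MoistureMeasurement:
    """Fresh and oven-dry mass of one leaf, in grams."""

    m_fresh: float
    m_dry: float

    def __post_init__(self):
        if not np.isfinite(self.m_fresh) or self.m_fresh <= 0:
            raise ManifestError(f"m_fresh must be positive, got {self.m_fresh}")
        if not np.isfinite(self.m_dry) or self.m_dry < 0:
            raise ManifestError(f"m_dry must be non-negative, got {self.m_dry}")
        if self.m_dry > self.m_fresh:
            raise ManifestError(
                f"m_dry ({self.m_dry}) exceeds m_fresh ({self.m_fresh})"
            )


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """One dual-view sample: two image paths and a moisture label in percent."""

    sample_id: str
    front_path: str
    back_path: str
    moisture_percent: float

    def __post_init__(self):
        m = self.moisture_percent
        if not np.isfinite(m) or not (0.0 <= m <= 100.0):
            raise ManifestError(
                f"moisture_percent must lie in [0, 100], got {m!r} "
                f"(sample {self.sample_id})"
            )


@dataclasses.dataclass
class ImagePair:
    """Decoded front/back images (H x W x 3, values in [0, 1]) plus label."""

    front: np.ndarray
    back: np.ndarray
    label: float


def compute_moisture(meas: MoistureMeasurement) -> float:
    """Moisture content in percent: 100 * (m_fresh - m_dry) / m_fresh.

    The result is clamped to [0, 100] to absorb float round-off at the
    endpoints (the exact value always lies in that interval).
    """
    ratio = (meas.m_fresh - meas.m_dry) / meas.m_fresh
    return float(min(max(100.0 * ratio, 0.0), 100.0))


def load_manifest(path) -> List[SampleRecord]:
    """Read a manifest CSV, validating every row.

    Row order is preserved.  Errors cite the offending 1-based data row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing columns: {missing}")
    base = path.parent
    records: List[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = SampleRecord(
                sample_id=str(row.sample_id),
                front_path=str(base / row.front_path),
                back_path=str(base / row.back_path),
                moisture_percent=float(row.moisture_percent),
            )
        except (ManifestError, TypeError) as exc:
            raise ManifestError(f"manifest {path} row {i}: {exc}") from exc
        records.append(rec)
    return records


def save_manifest(records: Sequence[SampleRecord], path,
                  relative_to: Optional[Path] = None) -> Path:
    """Write records to CSV in the manifest dialect; returns the path."""
    path = Path(path)
    rows = []
    for rec in records:
        front, back = rec.front_path, rec.back_path
        if relative_to is not None:
            front = str(Path(front).relative_to(relative_to))
            back = str(Path(back).relative_to(relative_to))
        rows.append((rec.sample_id, front, back, rec.moisture_percent))
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def _load_image(path: str, side_px: int) -> np.ndarray:
    try:
        with Image.open(path) as img:
            img = img.convert("RGB")
            if img.size != (side_px, side_px):
                img = img.resize((side_px, side_px), Image.BILINEAR)
            arr = np.asarray(img, dtype=np.float32) / 255.0
    except (OSError, SyntaxError) as exc:
        raise ManifestError(f"cannot decode image {path}: {exc}") from exc
    return arr


def load_pair(rec: SampleRecord, side_px: int = 224) -> ImagePair:
    """Decode and bilinearly resize both views to ``side_px`` square RGB."""
    if side_px < 1:
        raise ManifestError(f"side_px must be positive, got {side_px}")
    return ImagePair(
        front=_load_image(rec.front_path, side_px),
        back=_load_image(rec.back_path, side_px),
        label=rec.moisture_percent,
    )


def make_cv_folds(records: Sequence[SampleRecord], k: int = 5, *,
                  seed: int = 0) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Seeded random k-fold partition.

    A uniform shuffle is sliced into k contiguous chunks whose sizes differ
    by at most one (the first ``n % k`` folds take the extra sample).
    Returns ``[(train_idx, val_idx), ...]`` with sorted integer indices.
    """
    n = len(records)
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} records")
    perm = np.random.default_rng(seed).permutation(n)
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    folds = []
    start = 0
    for sz in sizes:
        val = np.sort(perm[start:start + sz])
        train = np.sort(np.concatenate([perm[:start], perm[start + sz:]]))
        folds.append((train, val))
        start += sz
    return folds


def folds_to_json(folds, path) -> Path:
    payload = [
        {"train": f[0].tolist(), "val": f[1].tolist()} for f in folds
    ]
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def load_arrays(records: Sequence[SampleRecord], side_px: int = 224,
                dtype=np.float32):
    """Decode all pairs to model-ready arrays.

    Returns ``(front, back, labels)`` where the image arrays are NCHW
    (N, 3, side, side) and labels are percent.
    """
    n = len(records)
    front = np.empty((n, 3, side_px, side_px), dtype=dtype)
    back = np.empty((n, 3, side_px, side_px), dtype=dtype)
    labels = np.empty(n, dtype=dtype)
    for i, rec in enumerate(records):
        pair = load_pair(rec, side_px)
        front[i] = pair.front.transpose(2, 0, 1)
        back[i] = pair.back.transpose(2, 0, 1)
        labels[i] = pair.label
    return front, back, labels
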