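"""Deterministic synthetic dual-view leaf renderer.

The generator produces paired front/back images of an elliptical "leaf" on a
white background whose appearance statistics are monotone in a latent
moisture value in [0, 1]:

* lamina color interpolates linearly from a dry brown (latent 0) to a wet
  green (latent 1) — so the front green-channel mean rises with moisture;
* the lamina narrows horizontally as the latent falls, mimicking inward
  curl, down to ``curl_min_width_frac`` of the full width;
* the back view shows a lightened lamina crossed by dark veins whose
  contrast against the lamina scales with ``(1 - latent)`` — venation grows
  more exposed as the leaf dries.

In ``joint`` mode both views share one latent equal to ``label / 100``.  In
``split`` mode the two views carry independent latents whose average is the
label; a predictor seeing only one view can then explain at most half the
label variance, while a dual-view model can recover it all.  Every output
byte is a pure function of (arguments, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image

from .io_manifest import SampleRecord, save_manifest


@dataclasses.dataclass(frozen=True)
class LeafRenderParams:
    side_px: int = 224
    color_wet: Tuple[float, float, float] = (0.20, 0.55, 0.18)
    color_dry: Tuple[float, float, float] = (0.45, 0.30, 0.12)
    back_lightening: float = 0.35
    curl_min_width_frac: float = 0.45
    vein_count: int = 6
    vein_contrast_max: float = 0.4
    noise_sd: float = 0.02
    illumination_jitter: float = 0.0
    mode: str = "joint"

    def __post_init__(self):
        for name in ("color_wet", "color_dry"):
            col = getattr(self, name)
            if len(col) != 3 or not all(0.0 <= v <= 1.0 for v in col):
                raise ValueError(f"{name} must be an RGB triple in [0,1]")
        if not (0.0 < self.curl_min_width_frac <= 1.0):
            raise ValueError("curl_min_width_frac must lie in (0, 1]")
        if not (0.0 <= self.back_lightening <= 1.0):
            raise ValueError("back_lightening must lie in [0, 1]")
        if not (0.0 <= self.vein_contrast_max <= 1.0):
            raise ValueError("vein_contrast_max must lie in [0, 1]")
        if self.noise_sd < 0 or self.illumination_jitter < 0:
            raise ValueError("noise_sd and illumination_jitter must be >= 0")
        if self.mode not in ("joint", "split"):
            raise ValueError(f"mode must be 'joint' or 'split', got {self.mode!r}")
        if self.vein_count < 0:
            raise ValueError("vein_count must be >= 0")
        if self.side_px < 16:
            raise ValueError("side_px must be >= 16")


@dataclasses.dataclass
class SyntheticSample:
    """A rendered pair plus the latents and masks used to build it."""

    front: np.ndarray
    back: np.ndarray
    label: float
    latent_front: float
    latent_back: float
    front_mask: np.ndarray = dataclasses.field(repr=False, default=None)
    back_mask: np.ndarray = dataclasses.field(repr=False, default=None)
    vein_mask: np.ndarray = dataclasses.field(repr=False, default=None)


def _leaf_mask(side: int, latent: float, min_width_frac: float) -> np.ndarray:
    """Boolean lamina mask: an ellipse whose width shrinks as latent falls."""
    width_frac = min_width_frac + (1.0 - min_width_frac) * latent
    cy = cx = (side - 1) / 2.0
    semi_h = 0.42 * side
    semi_w = 0.30 * side * width_frac
    yy, xx = np.mgrid[0:side, 0:side]
    return ((xx - cx) / semi_w) ** 2 + ((yy - cy) / semi_h) ** 2 <= 1.0


def _draw_segment(mask: np.ndarray, x0, y0, x1, y1, thickness: int) -> None:
    side = mask.shape[0]
    length = int(np.hypot(x1 - x0, y1 - y0)) * 2 + 2
    ts = np.linspace(0.0, 1.0, length)
    xs = np.clip(np.round(x0 + ts * (x1 - x0)).astype(int), 0, side - 1)
    ys = np.clip(np.round(y0 + ts * (y1 - y0)).astype(int), 0, side - 1)
    for dx in range(thickness):
        mask[ys, np.clip(xs + dx, 0, side - 1)] = True


def _vein_mask(side: int, lamina: np.ndarray, count: int,
               rng: np.random.Generator) -> np.ndarray:
    """Midrib plus symmetric lateral branches, clipped to the lamina."""
    veins = np.zeros((side, side), dtype=bool)
    cx = (side - 1) / 2.0
    rows = np.where(lamina.any(axis=1))[0]
    if rows.size == 0:
        return veins
    top, bottom = rows[0], rows[-1]
    thick = max(1, side // 112)
    _draw_segment(veins, cx, top, cx, bottom, thick)
    for i in range(count):
        frac = (i // 2 + 1) / (count // 2 + 2)
        y0 = top + frac * (bottom - top) + rng.uniform(-2, 2)
        sign = 1 if i % 2 == 0 else -1
        angle = np.deg2rad(35.0 + rng.uniform(-8, 8))
        reach = 0.45 * side
        x1 = cx + sign * reach * np.cos(angle)
        y1 = y0 + reach * np.sin(angle)
        _draw_segment(veins, cx, y0, x1, y1, thick)
    veins &= lamina
    return veins


def _latents_for_label(label: float, mode: str, rng: np.random.Generator,
                       latents: Optional[Tuple[float, float]]):
    m = label / 100.0
    if latents is not None:
        lf, lb = float(latents[0]), float(latents[1])
        if not (0.0 <= lf <= 1.0 and 0.0 <= lb <= 1.0):
            raise ValueError("latents must lie in [0, 1]")
        if abs((lf + lb) / 2.0 - m) > 1e-9:
            raise ValueError("latents must average to label / 100")
        return lf, lb
    if mode == "joint":
        return m, m
    lo, hi = max(0.0, 2.0 * m - 1.0), min(1.0, 2.0 * m)
    lf = rng.uniform(lo, hi)
    return lf, 2.0 * m - lf


def render_pair(label_percent: float, params: LeafRenderParams, seed: int,
                latents: Optional[Tuple[float, float]] = None) -> SyntheticSample:
    """Render one front/back pair; bit-deterministic given (args, seed)."""
    if not (0.0 <= label_percent <= 100.0):
        raise ValueError(f"label must lie in [0, 100], got {label_percent}")
    rng = np.random.default_rng(seed)
    lf, lb = _latents_for_label(label_percent, params.mode, rng, latents)
    side = params.side_px
    wet = np.asarray(params.color_wet)
    dry = np.asarray(params.color_dry)

    front_mask = _leaf_mask(side, lf, params.curl_min_width_frac)
    front = np.ones((side, side, 3))
    front[front_mask] = dry + lf * (wet - dry)

    back_mask = _leaf_mask(side, lb, params.curl_min_width_frac)
    lamina_back = dry + lb * (wet - dry)
    lamina_back = lamina_back + params.back_lightening * (1.0 - lamina_back)
    back = np.ones((side, side, 3))
    back[back_mask] = lamina_back
    veins = _vein_mask(side, back_mask, params.vein_count, rng)
    gap = (1.0 - lb) * params.vein_contrast_max
    back[veins] = np.clip(lamina_back - gap, 0.0, 1.0)

    if params.illumination_jitter > 0:
        factor = 1.0 + params.illumination_jitter * rng.uniform(-1.0, 1.0)
        front = front * factor
        back = back * factor
    if params.noise_sd > 0:
        front = front + rng.normal(0.0, params.noise_sd, front.shape)
        back = back + rng.normal(0.0, params.noise_sd, back.shape)
    front = np.clip(front, 0.0, 1.0)
    back = np.clip(back, 0.0, 1.0)

    return SyntheticSample(
        front=front, back=back, label=float(label_percent),
        latent_front=lf, latent_back=lb,
        front_mask=front_mask, back_mask=back_mask, vein_mask=veins,
    )


def view_information_summary(sample: SyntheticSample) -> Tuple[float, float]:
    """(front green-channel mean over the lamina, back vein-vs-lamina gap).

    The gap is the mean absolute grayscale difference between vein pixels
    and the surrounding (non-vein) lamina pixels on the back view.
    """
    green_mean = float(sample.front[..., 1][sample.front_mask].mean())
    lamina_only = sample.back_mask & ~sample.vein_mask
    if sample.vein_mask.any() and lamina_only.any():
        vein_i = sample.back[sample.vein_mask].mean()
        lamina_i = sample.back[lamina_only].mean()
        gap = float(abs(lamina_i - vein_i))
    else:
        gap = 0.0
    return green_mean, gap


def _save_png(arr: np.ndarray, path: Path) -> None:
    img = Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="RGB")
    img.save(path, format="PNG")


def generate_dataset(n: int, params: LeafRenderParams, label_range=(0.0, 100.0),
                     out_dir=".", seed: int = 0) -> Path:
    """Render n samples to PNG plus a manifest CSV; returns the manifest path.

    In joint mode labels are drawn uniformly on ``label_range``.  In split
    mode the two per-view latents are drawn i.i.d. uniform on
    ``label_range / 100`` and the label is their average in percent, which
    caps any single view's explainable label variance at one half.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = float(label_range[0]), float(label_range[1])
    if not (0.0 <= lo < hi <= 100.0):
        raise ValueError(f"label_range must satisfy 0 <= lo < hi <= 100, got {label_range}")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    records = []
    width = len(str(n))
    for i in range(n):
        if params.mode == "split":
            lf = rng.uniform(lo / 100.0, hi / 100.0)
            lb = rng.uniform(lo / 100.0, hi / 100.0)
            label = 50.0 * (lf + lb)
            latents = (lf, lb)
        else:
            label = rng.uniform(lo, hi)
            latents = None
        sample_seed = int(rng.integers(0, 2**31 - 1))
        sample = render_pair(label, params, sample_seed, latents=latents)
        sid = f"leaf_{i:0{width}d}"
        front_path = img_dir / f"{sid}_front.png"
        back_path = img_dir / f"{sid}_back.png"
        _save_png(sample.front, front_path)
        _save_png(sample.back, back_path)
        records.append(SampleRecord(
            sample_id=sid,
            front_path=str(front_path),
            back_path=str(back_path),
            moisture_percent=float(label),
        ))
    manifest = out_dir / "manifest.csv"
    save_manifest(records, manifest, relative_to=out_dir)
    return manifest
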