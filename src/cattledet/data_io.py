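"""YOLO-format dataset I/O, dataset splitting and standard augmentation.

Label files carry one ``class cx cy w h`` line per box (normalized
center-size).  The augmentation pipeline implements the five standard
transforms used for this detector: random cropping, HSV color jitter,
Gaussian noise, horizontal flip and scaling.  Geometric transforms remap
box coordinates consistently; photometric ones leave them untouched.
Boxes whose surviving visible area falls below ``min_visibility`` of the
original are dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

from .boxes import CLASS_NAMES, Box, LabeledImage


class LabelParseError(ValueError):
    pass


def read_yolo_labels(path, image_size: tuple[int, int] | None = None, n_classes: int = 4) -> list[Box]:
    """Parse one YOLO label file into Boxes; validates ranges per line."""
    boxes: list[Box] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            try:
                cls_f, cx, cy, w, h = (float(p) for p in parts)
            except ValueError as e:
                raise LabelParseError(f"{path}:{ln}: non-numeric field ({e})") from None
            cls_i = int(cls_f)
            if cls_i != cls_f or not (0 <= cls_i < n_classes):
                raise LabelParseError(f"{path}:{ln}: class {parts[0]} outside 0..{n_classes - 1}")
            try:
                boxes.append(Box(cls_i, cx, cy, w, h))
            except ValueError as e:
                raise LabelParseError(f"{path}:{ln}: {e}") from None
    return boxes


def write_yolo_labels(boxes: list[Box], path) -> None:
    """Write boxes in 6-decimal fixed format; round-trips with
    :func:`read_yolo_labels` to 1e-6."""
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.cls} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}\n")


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(pixels: np.ndarray, path) -> None:
    Image.fromarray(pixels).save(path)


def write_dataset_yaml(root, names=CLASS_NAMES, splits=("train", "val", "test"), path=None):
    """Dataset config: split image directories plus the class list."""
    root = Path(root)
    cfg = {s: str(root / "images" / s) for s in splits}
    cfg["names"] = list(names)
    cfg["nc"] = len(names)
    out = path or root / "data.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out


# ------------------------------------------------------------------- splits
@dataclass
class SplitSpec:
    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(items: list, spec: SplitSpec | None = None):
    """Deterministic random partition into (train, val, test).

    Sizes are the rounded fractions with the remainder absorbed by the
    training split; disjoint and exhaustive by construction.
    """
    spec = spec or SplitSpec()
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_val = int(round(spec.val_frac * n))
    n_test = int(round(spec.test_frac * n))
    n_train = n - n_val - n_test
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train : n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val :]]
    return train, val, test


# -------------------------------------------------------------- augmentation
@dataclass
class AugmentConfig:
    p_crop: float = 0.5
    crop_min_frac: float = 0.6  # crop window side as fraction of image side
    p_hsv: float = 0.5
    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    p_noise: float = 0.25
    noise_sigma_max: float = 0.05  # of dynamic range
    p_flip: float = 0.5
    p_scale: float = 0.5
    scale_range: tuple[float, float] = (0.75, 1.25)
    min_visibility: float = 0.2  # of original box area
    min_crop_px: int = 32


def _remap_boxes_crop(boxes, x0, y0, cw, ch, W, H, min_vis):
    out = []
    for b in boxes:
        x1, y1, x2, y2 = b.to_xyxy(W, H)
        area0 = (x2 - x1) * (y2 - y1)
        nx1, ny1 = max(x1 - x0, 0.0), max(y1 - y0, 0.0)
        nx2, ny2 = min(x2 - x0, float(cw)), min(y2 - y0, float(ch))
        if nx2 <= nx1 or ny2 <= ny1:
            continue
        if (nx2 - nx1) * (ny2 - ny1) < min_vis * area0:
            continue
        out.append(Box.from_xyxy(b.cls, nx1, ny1, nx2, ny2, cw, ch, score=b.score))
    return out


def resize_labeled(img: LabeledImage, size: tuple[int, int]) -> LabeledImage:
    """Resize pixels to (H, W); normalized boxes are unchanged."""
    H, W = size
    if (img.height, img.width) == (H, W):
        return img
    px = np.asarray(Image.fromarray(img.pixels).resize((W, H), Image.BILINEAR))
    return LabeledImage(px, list(img.boxes), img.source_id)


def augment(img: LabeledImage, rng: np.random.Generator, cfg: AugmentConfig | None = None) -> LabeledImage:
    """Apply the five-transform pipeline; boxes stay consistent with pixels."""
    cfg = cfg or AugmentConfig()
    px = img.pixels
    boxes = list(img.boxes)
    H, W = px.shape[:2]

    if rng.random() < cfg.p_crop:
        cw = int(rng.uniform(cfg.crop_min_frac, 1.0) * W)
        ch = int(rng.uniform(cfg.crop_min_frac, 1.0) * H)
        if cw < cfg.min_crop_px or ch < cfg.min_crop_px:
            raise ValueError(f"crop window {cw}x{ch} smaller than {cfg.min_crop_px} px")
        x0 = int(rng.integers(0, W - cw + 1))
        y0 = int(rng.integers(0, H - ch + 1))
        px = px[y0 : y0 + ch, x0 : x0 + cw]
        boxes = _remap_boxes_crop(boxes, x0, y0, cw, ch, W, H, cfg.min_visibility)
        H, W = ch, cw

    if rng.random() < cfg.p_scale:
        s = rng.uniform(*cfg.scale_range)
        nw, nh = max(32, int(W * s)), max(32, int(H * s))
        px = np.asarray(Image.fromarray(px).resize((nw, nh), Image.BILINEAR))
        H, W = nh, nw  # normalized boxes are scale-invariant

    if rng.random() < cfg.p_flip:
        px = px[:, ::-1].copy()
        boxes = [Box(b.cls, 1.0 - b.cx, b.cy, b.w, b.h, b.score) for b in boxes]

    if rng.random() < cfg.p_hsv:
        hsv = rgb_to_hsv(px.astype(np.float64) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hsv_h, cfg.hsv_h)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-cfg.hsv_s, cfg.hsv_s)), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-cfg.hsv_v, cfg.hsv_v)), 0, 1)
        px = (hsv_to_rgb(hsv) * 255).round().astype(np.uint8)

    if rng.random() < cfg.p_noise:
        sigma = rng.uniform(0, cfg.noise_sigma_max) * 255.0
        px = np.clip(px.astype(np.float64) + rng.normal(0, sigma, px.shape), 0, 255).astype(np.uint8)

    return LabeledImage(np.ascontiguousarray(px), boxes, img.source_id)
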