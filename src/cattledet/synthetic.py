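"""Synthetic pasture scenes for offline testing and smoke training.

Each scene is a textured background with ``n_instances`` textured
"animal" blobs, one of four behavior classes, each with a distinctive
silhouette template:

* standing — tall body on visible legs,
* walking  — body with legs offset fore/aft,
* eating   — body with the head lowered to the ground,
* lying    — low, wide ellipse without legs.

Ground-truth boxes are tight around the rendered silhouette.  With
probability ``occlusion_prob`` a blob is placed to overlap the previous
one by at least 30% of the smaller box, emulating partial body occlusion
in dense pens.  Purely procedural: no external assets, fully seeded.
"""

from __future__ import annotations

import numpy as np

from .boxes import Box, LabeledImage


def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / max(ry, 1)) ** 2 + ((xx - cx) / max(rx, 1)) ** 2 <= 1.0


def _animal_mask(cls: int, bh: int, bw: int) -> np.ndarray:
    """Binary silhouette on a (bh, bw) canvas for behavior class ``cls``."""
    m = np.zeros((bh, bw), dtype=bool)
    if cls == 3:  # lying: single low ellipse filling the canvas
        m |= _ellipse_mask(bh, bw, bh * 0.55, bw * 0.5, bh * 0.42, bw * 0.48)
        return m
    body_h = int(bh * 0.55)
    m |= _ellipse_mask(bh, bw, body_h * 0.55, bw * 0.5, body_h * 0.5, bw * 0.44)
    leg_w = max(2, bw // 10)
    leg_top = int(body_h * 0.8)
    if cls == 1:  # walking: legs offset fore/aft
        xs = [int(bw * 0.18), int(bw * 0.38), int(bw * 0.62), int(bw * 0.86)]
    else:  # standing / eating: paired legs
        xs = [int(bw * 0.22), int(bw * 0.34), int(bw * 0.68), int(bw * 0.8)]
    for x in xs:
        m[leg_top:bh, max(0, x - leg_w // 2) : min(bw, x + leg_w - leg_w // 2)] = True
    if cls == 2:  # eating: head-down wedge at the front reaching the ground
        m |= _ellipse_mask(bh, bw, bh * 0.78, bw * 0.88, bh * 0.3, bw * 0.12)
    else:  # raised head
        m |= _ellipse_mask(bh, bw, body_h * 0.3, bw * 0.9, body_h * 0.35, bw * 0.12)
    return m


def _tight_bbox(mask: np.ndarray):
    ys, xs = np.where(mask)
    return xs.min(), ys.min(), xs.max() + 1, ys.max() + 1


def generate_synthetic_scene(
    rng: np.random.Generator,
    n_instances: int = 3,
    occlusion_prob: float = 0.3,
    image_size: tuple[int, int] = (160, 160),
    source_id: str = "",
    size_range: tuple[float, float] = (0.22, 0.42),
) -> LabeledImage:
    """Render one labeled scene; boxes are tight on the blob silhouettes."""
    H, W = image_size
    # low-frequency grass-like background texture
    base = rng.uniform(60, 110)
    coarse = rng.normal(0, 12, (H // 8 + 1, W // 8 + 1))
    bg = np.kron(coarse, np.ones((8, 8)))[:H, :W]
    px = np.zeros((H, W, 3))
    px[..., 0] = base * 0.7 + bg
    px[..., 1] = base + bg
    px[..., 2] = base * 0.55 + bg
    px += rng.normal(0, 4, (H, W, 3))

    boxes: list[Box] = []
    prev_span = None
    for i in range(n_instances):
        cls = int(rng.integers(0, 4))
        bw = int(rng.uniform(*size_range) * min(H, W))
        aspect = rng.uniform(0.55, 0.8) if cls != 3 else rng.uniform(0.4, 0.55)
        bh = max(12, int(bw * aspect))
        bw = max(12, bw)
        mask = _animal_mask(cls, bh, bw)
        mx0, my0, mx1, my1 = _tight_bbox(mask)
        wt, ht = mx1 - mx0, my1 - my0
        occlude = prev_span is not None and rng.random() < occlusion_prob
        if occlude:
            # constructive overlap: tight boxes share >= 0.8*min-extent per
            # axis, hence intersection >= 30% of the smaller box area
            ox0, oy0, ox1, oy1 = prev_span
            dx = 0.8 * min(ox1 - ox0, wt)
            dy = 0.8 * min(oy1 - oy0, ht)
            gx0 = max(0.0, min(ox1 - dx, W - bw + mx0))
            gy0 = max(0.0, min(oy1 - dy, H - bh + my0))
            x0 = int(np.clip(round(gx0 - mx0), 0, max(W - bw, 0)))
            y0 = int(np.clip(round(gy0 - my0), 0, max(H - bh, 0)))
        else:
            x0 = int(rng.integers(0, max(W - bw, 1)))
            y0 = int(rng.integers(0, max(H - bh, 1)))
        coat = rng.uniform(25, 70) if rng.random() < 0.7 else rng.uniform(150, 220)
        tex = rng.normal(0, 10, (bh, bw))
        region = px[y0 : y0 + bh, x0 : x0 + bw]
        for c, tint in enumerate((1.0, 0.92, 0.85)):
            chan = region[..., c]
            chan[mask] = coat * tint + tex[mask]
        gx0, gy0, gx1, gy1 = x0 + mx0, y0 + my0, x0 + mx1, y0 + my1
        boxes.append(Box.from_xyxy(cls, gx0, gy0, gx1, gy1, W, H))
        prev_span = (gx0, gy0, gx1, gy1)
    return LabeledImage(np.clip(px, 0, 255).astype(np.uint8), boxes, source_id)


def tight_box_from_pixels(img: LabeledImage, box: Box, coat_tol: float = 18.0) -> tuple[float, float, float, float] | None:
    """Re-derive a blob's tight pixel box by thresholding around its median
    coat color inside the labeled region (augmentation-consistency probe)."""
    H, W = img.height, img.width
    x1, y1, x2, y2 = (int(round(v)) for v in box.to_xyxy(W, H))
    pad = 4
    x1p, y1p = max(0, x1 - pad), max(0, y1 - pad)
    x2p, y2p = min(W, x2 + pad), min(H, y2 + pad)
    patch = img.pixels[y1p:y2p, x1p:x2p].astype(np.float64)
    inner = img.pixels[y1:y2, x1:x2].astype(np.float64)
    if inner.size == 0:
        return None
    coat = np.median(inner.reshape(-1, 3), axis=0)
    dist = np.abs(patch - coat).sum(axis=2)
    mask = dist < coat_tol * 3
    if not mask.any():
        return None
    bx0, by0, bx1, by1 = _tight_bbox(mask)
    return (x1p + bx0, y1p + by0, x1p + bx1, y1p + by1)
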