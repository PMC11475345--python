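"""Bounding-box regression losses and the full detection training criterion.

The IoU family implemented here:

* ``iou`` — plain intersection-over-union on continuous areas.
* ``ciou`` — complete IoU (center distance over enclosing diagonal plus an
  aspect-ratio consistency term), the YOLOv8 default.
* ``inner_iou`` — IoU of center-preserving auxiliary boxes whose width and
  height are scaled by ``ratio``; ``ratio < 1`` concentrates the gradient
  on the box core, ``ratio > 1`` on its surroundings.
* ``mpdiou`` — IoU minus the squared top-left and bottom-right corner
  distances, each normalized by ``w**2 + h**2`` of the frame:

      MPDIoU = IoU - d1^2 / (w^2 + h^2) - d2^2 / (w^2 + h^2)

  with ``d1^2 = (x1_prd - x1_gt)^2 + (y1_prd - y1_gt)^2`` and ``d2^2`` the
  same for the bottom-right corners.
* ``inner_mpdiou`` — MPDIoU with the IoU term replaced by the Inner-IoU of
  the ratio-scaled auxiliary boxes; corner distances stay on the original
  boxes.  With ``ratio = 1`` it reduces exactly to MPDIoU.  The training
  loss is ``1 - inner_mpdiou``.

``w, h`` default to the input-image (frame) dimensions; ``norm='gtbox'``
normalizes by the ground-truth box diagonal instead.

All functions exist in two forms: plain NumPy scalars/arrays (analysis,
evaluation) and autodiff ``Tensor`` versions (suffix ``_t``) used inside
``detection_loss``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .boxes import Box
from .head import RawPrediction
from .nn import Tensor, bce_with_logits, concat, maximum, minimum, stack

__all__ = [
    "InnerConfig", "LossConfig", "iou", "inner_box", "inner_iou", "ciou",
    "mpdiou", "inner_mpdiou", "iou_t", "box_similarity_t", "detection_loss",
]


@dataclass
class InnerConfig:
    """Auxiliary-box scale for the Inner-IoU family."""

    ratio: float = 0.7

    def __post_init__(self):
        if not (0.5 <= self.ratio <= 1.5):
            raise ValueError("inner ratio must lie in [0.5, 1.5]")


@dataclass
class LossConfig:
    kind: str = "inner_mpdiou"  # ciou | inner_iou | mpdiou | inner_mpdiou
    inner_ratio: float = 0.7
    mpd_norm: str = "image"  # image | gtbox
    lambda_box: float = 7.5
    lambda_cls: float = 0.5
    lambda_dfl: float = 1.5
    assigner_topk: int = 10
    tal_alpha: float = 0.5
    tal_beta: float = 6.0


# ------------------------------------------------------------- NumPy family
def _area(b) -> np.ndarray:
    return np.maximum(0.0, b[..., 2] - b[..., 0]) * np.maximum(0.0, b[..., 3] - b[..., 1])


def _check(b, name):
    b = np.asarray(b, dtype=np.float64)
    if np.any(b[..., 2] < b[..., 0]) or np.any(b[..., 3] < b[..., 1]):
        raise ValueError(f"{name} has inverted corners")
    return b


def iou(a, b) -> np.ndarray | float:
    """IoU of xyxy boxes (broadcastable ``(..., 4)``); 0 for disjoint or
    degenerate zero-area pairs (with a warning for the latter)."""
    a, b = _check(a, "a"), _check(b, "b")
    x1 = np.maximum(a[..., 0], b[..., 0])
    y1 = np.maximum(a[..., 1], b[..., 1])
    x2 = np.minimum(a[..., 2], b[..., 2])
    y2 = np.minimum(a[..., 3], b[..., 3])
    inter = np.maximum(0.0, x2 - x1) * np.maximum(0.0, y2 - y1)
    union = _area(a) + _area(b) - inter
    if np.any(union <= 0):
        warnings.warn("zero-area box in IoU; returning 0 for those pairs")
    out = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def inner_box(b, ratio: float):
    """Center-preserving rescale of an xyxy box by ``ratio``."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    b = np.asarray(b, dtype=np.float64)
    cx = (b[..., 0] + b[..., 2]) / 2
    cy = (b[..., 1] + b[..., 3]) / 2
    hw = (b[..., 2] - b[..., 0]) * ratio / 2
    hh = (b[..., 3] - b[..., 1]) * ratio / 2
    return np.stack([cx - hw, cy - hh, cx + hw, cy + hh], axis=-1)


def inner_iou(pred, gt, ratio: float = 0.7):
    if ratio == 1.0:  # identity transform: bitwise-exact reduction to IoU
        return iou(pred, gt)
    return iou(inner_box(pred, ratio), inner_box(gt, ratio))


def _corner_penalty(pred, gt, frame_w, frame_h, norm: str):
    pred, gt = np.asarray(pred, np.float64), np.asarray(gt, np.float64)
    d1sq = (pred[..., 0] - gt[..., 0]) ** 2 + (pred[..., 1] - gt[..., 1]) ** 2
    d2sq = (pred[..., 2] - gt[..., 2]) ** 2 + (pred[..., 3] - gt[..., 3]) ** 2
    if norm == "image":
        diag = float(frame_w) ** 2 + float(frame_h) ** 2
    elif norm == "gtbox":
        diag = (gt[..., 2] - gt[..., 0]) ** 2 + (gt[..., 3] - gt[..., 1]) ** 2
    else:
        raise ValueError(f"unknown mpd_norm {norm!r}")
    if np.any(np.asarray(diag) <= 0):
        raise ValueError("MPDIoU normalization requires positive frame dimensions")
    return (d1sq + d2sq) / diag


def mpdiou(pred, gt, frame_w: float, frame_h: float, norm: str = "image"):
    """MPDIoU in (-2, 1]; 1 iff the boxes coincide."""
    out = iou(pred, gt) - _corner_penalty(pred, gt, frame_w, frame_h, norm)
    return float(out) if np.ndim(out) == 0 else out


def inner_mpdiou(pred, gt, frame_w: float, frame_h: float, ratio: float = 0.7, norm: str = "image"):
    """MPDIoU with the overlap term computed on ratio-scaled inner boxes."""
    out = inner_iou(pred, gt, ratio) - _corner_penalty(pred, gt, frame_w, frame_h, norm)
    return float(out) if np.ndim(out) == 0 else out


def ciou(pred, gt):
    """Complete IoU: IoU - center-distance/enclosing-diagonal - alpha*v."""
    pred, gt = _check(pred, "pred"), _check(gt, "gt")
    base = iou(pred, gt)
    cw = np.maximum(pred[..., 2], gt[..., 2]) - np.minimum(pred[..., 0], gt[..., 0])
    ch = np.maximum(pred[..., 3], gt[..., 3]) - np.minimum(pred[..., 1], gt[..., 1])
    c2 = cw**2 + ch**2 + 1e-12
    rho2 = ((pred[..., 0] + pred[..., 2] - gt[..., 0] - gt[..., 2]) ** 2 + (pred[..., 1] + pred[..., 3] - gt[..., 1] - gt[..., 3]) ** 2) / 4
    wp, hp = pred[..., 2] - pred[..., 0], pred[..., 3] - pred[..., 1]
    wg, hg = gt[..., 2] - gt[..., 0], gt[..., 3] - gt[..., 1]
    v = (4 / np.pi**2) * (np.arctan(wg / (hg + 1e-12)) - np.arctan(wp / (hp + 1e-12))) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = v / (1.0 - base + v + 1e-12)
    out = base - rho2 / c2 - alpha * v
    return float(out) if np.ndim(out) == 0 else out


# ----------------------------------------------------------- Tensor family
def _cols(b: Tensor):
    bt = b.reshape(-1, 4).transpose(1, 0)  # (4, M)
    rows = []
    for i in range(4):
        rows.append(bt.take_rows(np.array([i])).reshape(-1))
    return rows


def iou_t(a: Tensor, b: Tensor, eps: float = 1e-9) -> Tensor:
    """Differentiable IoU for (M, 4) xyxy tensors."""
    ax1, ay1, ax2, ay2 = _cols(a)
    bx1, by1, bx2, by2 = _cols(b)
    iw = maximum(minimum(ax2, bx2) - maximum(ax1, bx1), 0.0)
    ih = maximum(minimum(ay2, by2) - maximum(ay1, by1), 0.0)
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter + eps
    return inter / union


def _inner_t(b: Tensor, ratio: float) -> Tensor:
    if ratio == 1.0:
        return b
    x1, y1, x2, y2 = _cols(b)
    cx, cy = (x1 + x2) * 0.5, (y1 + y2) * 0.5
    hw, hh = (x2 - x1) * (ratio / 2), (y2 - y1) * (ratio / 2)
    return stack([cx - hw, cy - hh, cx + hw, cy + hh], axis=1)


def box_similarity_t(pred: Tensor, gt: Tensor, cfg: LossConfig, frame_w: float, frame_h: float) -> Tensor:
    """Selected IoU-family similarity, differentiable, shape (M,)."""
    kind = cfg.kind
    if kind == "ciou":
        px1, py1, px2, py2 = _cols(pred)
        gx1, gy1, gx2, gy2 = _cols(gt)
        base = iou_t(pred, gt)
        cw = maximum(px2, gx2) - minimum(px1, gx1)
        ch = maximum(py2, gy2) - minimum(py1, gy1)
        c2 = cw * cw + ch * ch + 1e-9
        rho2 = ((px1 + px2 - gx1 - gx2) ** 2.0 + (py1 + py2 - gy1 - gy2) ** 2.0) * 0.25
        v = ((gx2 - gx1) / (gy2 - gy1 + 1e-9)).atan() - ((px2 - px1) / (py2 - py1 + 1e-9)).atan()
        v = v * v * (4.0 / np.pi**2)
        alpha = Tensor(v.data / (1.0 - base.data + v.data + 1e-9))  # detached, as in CIoU practice
        return base - rho2 / c2 - alpha * v
    if kind == "inner_iou":
        return iou_t(_inner_t(pred, cfg.inner_ratio), _inner_t(gt, cfg.inner_ratio))
    if kind in ("mpdiou", "inner_mpdiou"):
        px1, py1, px2, py2 = _cols(pred)
        gx1, gy1, gx2, gy2 = _cols(gt)
        if cfg.mpd_norm == "image":
            diag = frame_w**2 + frame_h**2
            pen = ((px1 - gx1) ** 2.0 + (py1 - gy1) ** 2.0 + (px2 - gx2) ** 2.0 + (py2 - gy2) ** 2.0) * (1.0 / diag)
        else:
            diag = (gx2 - gx1) ** 2.0 + (gy2 - gy1) ** 2.0
            pen = ((px1 - gx1) ** 2.0 + (py1 - gy1) ** 2.0 + (px2 - gx2) ** 2.0 + (py2 - gy2) ** 2.0) / diag
        if kind == "mpdiou":
            return iou_t(pred, gt) - pen
        return iou_t(_inner_t(pred, cfg.inner_ratio), _inner_t(gt, cfg.inner_ratio)) - pen
    raise ValueError(f"unknown loss kind {kind!r}")


# -------------------------------------------------- task-aligned assignment
def _flatten_raw(raw: RawPrediction):
    """Per-level maps -> (N, cells, C) tensors + cell centers and strides."""
    box_flat, cls_flat, centers, strides = [], [], [], []
    for bt, ct, s in zip(raw.box, raw.cls, raw.strides):
        N, Cb, H, W = bt.shape
        box_flat.append(bt.reshape(N, Cb, H * W).transpose(0, 2, 1))
        cls_flat.append(ct.reshape(N, ct.shape[1], H * W).transpose(0, 2, 1))
        yy, xx = np.mgrid[0:H, 0:W]
        centers.append(np.stack([(xx.ravel() + 0.5) * s, (yy.ravel() + 0.5) * s], axis=1))
        strides.append(np.full(H * W, s, dtype=np.float64))
    return (
        concat(box_flat, axis=1),
        concat(cls_flat, axis=1),
        np.concatenate(centers),
        np.concatenate(strides),
    )


def task_aligned_assign(pred_xyxy: np.ndarray, cls_prob: np.ndarray, centers: np.ndarray, gts: list[Box], img_size, cfg: LossConfig):
    """YOLOv8-style TAL for one image.

    Returns (fg_idx, gt_idx, target_scores) where target_scores are the
    IoU-calibrated alignment weights of the assigned cells.
    """
    H, W = img_size
    if not gts:
        return np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)
    gt_xyxy = np.array([g.to_xyxy(W, H) for g in gts])
    gt_cls = np.array([g.cls for g in gts])
    M = len(gts)
    inside = (
        (centers[None, :, 0] > gt_xyxy[:, None, 0])
        & (centers[None, :, 0] < gt_xyxy[:, None, 2])
        & (centers[None, :, 1] > gt_xyxy[:, None, 1])
        & (centers[None, :, 1] < gt_xyxy[:, None, 3])
    )  # (M, cells)
    ious = iou(gt_xyxy[:, None, :], pred_xyxy[None, :, :])  # (M, cells)
    align = (cls_prob[:, gt_cls].T ** cfg.tal_alpha) * (ious**cfg.tal_beta)
    align = np.where(inside, align, 0.0)
    # top-k candidates per gt
    k = min(cfg.assigner_topk, align.shape[1])
    cand = np.zeros_like(align, dtype=bool)
    topk = np.argpartition(-align, k - 1, axis=1)[:, :k]
    for m in range(M):
        sel = topk[m][align[m, topk[m]] > 0]
        cand[m, sel] = True
    # resolve cells claimed by several gts: keep the highest alignment
    claimed = cand.sum(axis=0)
    if np.any(claimed > 1):
        multi = np.where(claimed > 1)[0]
        best = align[:, multi].argmax(axis=0)
        cand[:, multi] = False
        cand[best, multi] = True
    gt_idx_full = np.where(cand.any(axis=0), align.argmax(axis=0), -1)
    fg = np.where(cand.any(axis=0))[0]
    gt_idx = gt_idx_full[fg]
    # normalize: each gt's best aligned cell gets its best IoU as target score
    scores = np.zeros(len(fg))
    for m in range(M):
        mine = np.where(gt_idx == m)[0]
        if mine.size == 0:
            continue
        a = align[m, fg[mine]]
        scores[mine] = a / (a.max() + 1e-9) * ious[m, fg[mine]].max()
    return fg, gt_idx, scores


def detection_loss(raw: RawPrediction, targets: list[list[Box]], img_size: tuple[int, int], cfg: LossConfig | None = None):
    """Full criterion: lambda_box*(1 - similarity) + lambda_cls*BCE +
    lambda_dfl*distribution-focal, normalized by total target score.

    Returns (total_loss Tensor, components dict of floats).
    """
    cfg = cfg or LossConfig()
    H, W = img_size
    box_t, cls_t, centers, strides = _flatten_raw(raw)  # (N,cells,4R), (N,cells,nc)
    N, cells, nc = cls_t.shape
    R = raw.reg_max
    if not (np.isfinite(box_t.data).all() and np.isfinite(cls_t.data).all()):
        raise FloatingPointError("non-finite values in raw predictions")

    # differentiable decode: softmax expectation over bins -> distances -> xyxy
    dist_logits = box_t.reshape(N * cells, 4, R)
    probs = dist_logits.softmax(axis=2)
    bins = np.arange(R, dtype=np.float64).reshape(1, 1, R)
    dist = (probs * bins).sum(axis=2)  # (N*cells, 4) in stride units
    ctr = np.tile(centers, (N, 1))
    stile = np.tile(strides[:, None], (N, 1))
    # xyxy = [cx - l*s, cy - t*s, cx + r*s, cy + b*s]
    sign = np.array([-1.0, -1.0, 1.0, 1.0]).reshape(1, 4)
    offs = np.concatenate([ctr, ctr], axis=1)  # (N*cells, 4) => cx,cy,cx,cy
    pred_xyxy = dist * (stile * sign) + offs

    cls_flat = cls_t.reshape(N * cells, nc)
    cls_prob_np = 1.0 / (1.0 + np.exp(-cls_flat.data))
    pred_xyxy_np = pred_xyxy.data

    target_cls = np.zeros((N * cells, nc))
    fg_rows, fg_gt_boxes, fg_scores, fg_dist_targets = [], [], [], []
    total_score = 0.0
    for n in range(N):
        sl = slice(n * cells, (n + 1) * cells)
        fg, gt_idx, scores = task_aligned_assign(pred_xyxy_np[sl], cls_prob_np[sl], centers, targets[n], img_size, cfg)
        if fg.size == 0:
            continue
        gts = targets[n]
        gt_xyxy = np.array([g.to_xyxy(W, H) for g in gts])
        gt_cls = np.array([g.cls for g in gts])
        rows = fg + n * cells
        target_cls[rows, gt_cls[gt_idx]] = scores
        fg_rows.append(rows)
        fg_gt_boxes.append(gt_xyxy[gt_idx])
        fg_scores.append(scores)
        # DFL targets: distances from cell center to gt sides, stride units
        c = centers[fg]
        s = strides[fg]
        g = gt_xyxy[gt_idx]
        d = np.stack([c[:, 0] - g[:, 0], c[:, 1] - g[:, 1], g[:, 2] - c[:, 0], g[:, 3] - c[:, 1]], axis=1) / s[:, None]
        fg_dist_targets.append(np.clip(d, 0.0, R - 1 - 1e-3))
        total_score += scores.sum()

    denom = max(total_score, 1.0)
    cls_loss = bce_with_logits(cls_flat, target_cls) * (1.0 / denom)

    if fg_rows:
        rows = np.concatenate(fg_rows)
        gt_all = np.concatenate(fg_gt_boxes)
        w_all = np.concatenate(fg_scores)
        pred_fg = pred_xyxy.take_rows(rows)
        sim = box_similarity_t(pred_fg, Tensor(gt_all), cfg, float(W), float(H))
        box_loss = ((1.0 - sim) * w_all).sum() * (1.0 / denom)
        # distribution-focal: CE against the two bins bracketing the target
        d_t = np.concatenate(fg_dist_targets)  # (F,4)
        F = rows.shape[0]
        logp = (probs.reshape(N * cells, 4 * R).take_rows(rows).reshape(F * 4, R) + 1e-9).log()
        lo = np.floor(d_t).astype(np.int64).reshape(-1)
        hi = np.minimum(lo + 1, R - 1)
        w_hi = d_t.reshape(-1) - lo
        w_lo = 1.0 - w_hi
        soft = np.zeros((F * 4, R))
        soft[np.arange(F * 4), lo] = w_lo
        soft[np.arange(F * 4), hi] += w_hi
        wexp = np.repeat(w_all, 4)[:, None]
        dfl_loss = (logp * (-soft * wexp)).sum() * (1.0 / (4.0 * denom))
    else:
        box_loss = Tensor(np.zeros(()))
        dfl_loss = Tensor(np.zeros(()))

    total = cls_loss * cfg.lambda_cls + box_loss * cfg.lambda_box + dfl_loss * cfg.lambda_dfl
    comps = {"box": float(box_loss.data), "cls": float(cls_loss.data), "dfl": float(dfl_loss.data)}
    if not np.isfinite(float(total.data)):
        raise FloatingPointError(f"non-finite loss: {comps}")
    return total, comps
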