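"""Lightweight Multi-Scale Feature Fusion Detection head (LMFD) and the
anchor-free decode shared by all heads.

Per level, features pass through a level-specific 1x1 Conv+GN+SiLU, then a
3x3 Conv+GN+SiLU whose weights are *shared* across the three levels, and
finally shared 1x1 classification (``n_classes`` logits) and regression
(``4 * reg_max`` distribution-focal bins) convolutions.  A per-level
learnable Scale scalar on the regression branch absorbs the differing
distance statistics of the three strides, FCOS-style.  Group normalization
keeps the head batch-size independent.

Decoding follows the YOLOv8 convention: each cell predicts four discrete
distance distributions over ``reg_max`` bins; the expectation of each
distribution, times the level stride, gives the left/top/right/bottom
distances from the cell center; class scores are sigmoids of the logits
and per-class NMS prunes overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import Box
from .nn import Conv2d, ConvGNAct, Module, ModuleList, Scale
from .nn.autograd import Tensor


@dataclass
class RawPrediction:
    """Per-level raw head outputs (before sigmoid / DFL expectation)."""

    box: list[Tensor]  # each (N, 4*reg_max, H, W)
    cls: list[Tensor]  # each (N, n_classes, H, W)
    strides: tuple[int, ...] = (8, 16, 32)
    reg_max: int = 16


@dataclass
class LMFDConfig:
    in_channels: int = 76  # = MCFP neck width
    hidden: int = 96
    gn_groups: int = 16
    reg_max: int = 16
    n_classes: int = 4

    def __post_init__(self):
        if self.hidden % self.gn_groups:
            raise ValueError("hidden must be divisible by gn_groups")


class LMFDHead(Module):
    def __init__(self, cfg: LMFDConfig | None = None, in_channels=None, rng=None):
        super().__init__()
        self.cfg = cfg or LMFDConfig()
        c = self.cfg
        if in_channels is None:
            in_channels = (c.in_channels,) * 3
        self.in_channels = tuple(in_channels)
        rng = rng or np.random.default_rng(0)
        h = c.hidden
        self.stems = ModuleList([ConvGNAct(ci, h, 1, c.gn_groups, rng=rng) for ci in self.in_channels])
        self.shared = ConvGNAct(h, h, 3, c.gn_groups, rng=rng)
        self.conv_reg = Conv2d(h, 4 * c.reg_max, 1, rng=rng)
        self.conv_cls = Conv2d(h, c.n_classes, 1, rng=rng)
        # bias prior so that initial objectness is low (stable early training)
        self.conv_cls.bias.data[:] = -4.59  # sigmoid ~ 0.01
        self.scales = ModuleList([Scale(1.0) for _ in range(3)])

    def forward(self, feats) -> RawPrediction:
        box_out, cls_out = [], []
        for feat, stem, scale, ci in zip(feats, self.stems, self.scales, self.in_channels):
            if feat.shape[1] != ci:
                raise ValueError(f"head expected {ci} channels, got {feat.shape[1]}")
            y = self.shared(stem(feat))
            box_out.append(scale(self.conv_reg(y)))
            cls_out.append(self.conv_cls(y))
        return RawPrediction(box=box_out, cls=cls_out, reg_max=self.cfg.reg_max)


def lmfd_param_count(cfg: LMFDConfig | None = None, in_channels=None) -> int:
    """Closed-form LMFD parameter count (symbolic audit of the builder)."""
    cfg = cfg or LMFDConfig()
    ins = in_channels if in_channels is not None else (cfg.in_channels,) * 3
    h = cfg.hidden
    stems = sum(ci * h + 2 * h for ci in ins)  # bias-free 1x1 + GN affine
    shared = 9 * h * h + 2 * h
    reg = h * 4 * cfg.reg_max + 4 * cfg.reg_max
    cls = h * cfg.n_classes + cfg.n_classes
    scales = 3
    return stems + shared + reg + cls + scales


# ---------------------------------------------------------------- decoding
def dfl_expectation(box_dist: np.ndarray, reg_max: int) -> np.ndarray:
    """(N, 4*reg_max, H, W) distribution logits -> (N, 4, H, W) distances
    in stride units (softmax expectation over bins)."""
    N, C, H, W = box_dist.shape
    x = box_dist.reshape(N, 4, reg_max, H, W)
    x = x - x.max(axis=2, keepdims=True)
    e = np.exp(x)
    p = e / e.sum(axis=2, keepdims=True)
    bins = np.arange(reg_max, dtype=p.dtype).reshape(1, 1, reg_max, 1, 1)
    return (p * bins).sum(axis=2)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    """Greedy NMS on (M,4) xyxy boxes; returns kept indices (score order)."""
    order = np.argsort(-scores)
    keep: list[int] = []
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        xx1 = np.maximum(boxes[i, 0], boxes[rest, 0])
        yy1 = np.maximum(boxes[i, 1], boxes[rest, 1])
        xx2 = np.minimum(boxes[i, 2], boxes[rest, 2])
        yy2 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.maximum(0.0, xx2 - xx1) * np.maximum(0.0, yy2 - yy1)
        iou = inter / np.maximum(areas[i] + areas[rest] - inter, 1e-12)
        order = rest[iou <= iou_thr]
    return keep


def decode(raw: RawPrediction, img_size: tuple[int, int], conf_thr: float = 0.25, nms_iou: float = 0.45, batch_index: int = 0) -> list[Box]:
    """Raw predictions -> scored, NMS-pruned pixel boxes for one image."""
    H_img, W_img = img_size
    all_xyxy, all_scores, all_cls = [], [], []
    for box_t, cls_t, stride in zip(raw.box, raw.cls, raw.strides):
        bd = box_t.data[batch_index : batch_index + 1]
        cl = cls_t.data[batch_index : batch_index + 1]
        dist = dfl_expectation(bd, raw.reg_max)[0] * stride  # (4,H,W)
        _, H, W = cl[0].shape[0], cl.shape[2], cl.shape[3]
        cy, cx = np.mgrid[0 : cl.shape[2], 0 : cl.shape[3]].astype(np.float64)
        cx = (cx + 0.5) * stride
        cy = (cy + 0.5) * stride
        x1 = cx - dist[0]
        y1 = cy - dist[1]
        x2 = cx + dist[2]
        y2 = cy + dist[3]
        from .nn.autograd import _stable_sigmoid

        probs = _stable_sigmoid(cl[0].astype(np.float64))  # (nc,H,W)
        cls_id = probs.argmax(axis=0)
        score = probs.max(axis=0)
        m = score >= conf_thr
        if not m.any():
            continue
        xyxy = np.stack([x1[m], y1[m], x2[m], y2[m]], axis=1)
        all_xyxy.append(xyxy)
        all_scores.append(score[m])
        all_cls.append(cls_id[m])
    if not all_xyxy:
        return []
    xyxy = np.concatenate(all_xyxy)
    scores = np.concatenate(all_scores)
    cls_ids = np.concatenate(all_cls)
    xyxy[:, 0::2] = np.clip(xyxy[:, 0::2], 0, W_img)
    xyxy[:, 1::2] = np.clip(xyxy[:, 1::2], 0, H_img)
    out: list[Box] = []
    for c in np.unique(cls_ids):
        sel = np.where(cls_ids == c)[0]
        keep = nms(xyxy[sel], scores[sel], nms_iou)
        for i in sel[keep]:
            b = xyxy[i]
            if b[2] <= b[0] or b[3] <= b[1]:
                continue
            out.append(Box.from_xyxy(int(c), b[0], b[1], b[2], b[3], W_img, H_img, score=float(scores[i])))
    out.sort(key=lambda b: -b.score)
    return out
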