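"""Detection evaluation: precision, recall, per-class AP and mAP@0.5.

Matching is greedy one-to-one per class: detections in descending score
order claim the unmatched ground truth of highest IoU >= the threshold
(ties broken by ground-truth index).  AP is the area under the
all-point-interpolated precision-recall curve (precision envelope), the
COCO/YOLO convention.  mAP@0.5 is the unweighted mean of the per-class
APs; classes with no ground truth and no detections are excluded.

The single-operating-point precision/recall pair is reported at the
confidence threshold maximizing F1 over pooled detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import Box, LabeledImage
from .losses import iou


@dataclass
class EvalReport:
    precision: float
    recall: float
    ap_per_class: dict[int, float]
    map50: float
    tp: dict[int, int]
    fp: dict[int, int]
    fn: dict[int, int]
    operating_conf: float = 0.0

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "ap_per_class": {int(k): float(v) for k, v in self.ap_per_class.items()},
            "map50": self.map50,
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "operating_conf": self.operating_conf,
        }


def match_detections(dets: list[Box], gts: list[Box], image_size: tuple[int, int], iou_thr: float = 0.5):
    """Greedy one-to-one matching within one image.

    ``dets`` must be sorted by descending score.  Returns (tp_flags,
    fp_flags, fn_count, matched_gt_index per det or -1).
    """
    H, W = image_size
    scores = [d.score if d.score is not None else 1.0 for d in dets]
    assert all(a >= b for a, b in zip(scores, scores[1:])), "detections must be score-sorted"
    gt_xyxy = np.array([g.to_xyxy(W, H) for g in gts]).reshape(-1, 4)
    taken = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    match = np.full(len(dets), -1, dtype=int)
    for i, d in enumerate(dets):
        best_iou, best_j = 0.0, -1
        dx = np.array(d.to_xyxy(W, H))
        for j, g in enumerate(gts):
            if taken[j] or g.cls != d.cls:
                continue
            v = iou(dx, gt_xyxy[j])
            if v >= iou_thr and v > best_iou:  # strict > ties to lowest gt index
                best_iou, best_j = v, j
        if best_j >= 0:
            taken[best_j] = True
            tp[i] = True
            match[i] = best_j
    fn = int(len(gts) - taken.sum())
    return tp, ~tp, fn, match


def average_precision(tp_flags: np.ndarray, fp_flags: np.ndarray, n_gt: int) -> float | None:
    """All-point-interpolated AP from score-ordered TP/FP flags.

    Returns None when undefined (no ground truth and no detections).
    """
    tp_flags = np.asarray(tp_flags, dtype=np.float64)
    fp_flags = np.asarray(fp_flags, dtype=np.float64)
    if n_gt == 0:
        return None if tp_flags.size == 0 else 0.0
    if tp_flags.size == 0:
        return 0.0
    ctp = np.cumsum(tp_flags)
    cfp = np.cumsum(fp_flags)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # precision envelope + rectangle integration over recall increments
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def evaluate_detections(per_image: list[tuple[list[Box], list[Box], tuple[int, int]]], iou_thr: float = 0.5, n_classes: int = 4) -> EvalReport:
    """Aggregate (detections, ground truths, image size) triples."""
    if not per_image:
        raise ValueError("empty dataset")
    recs: dict[int, list[tuple[float, bool]]] = {c: [] for c in range(n_classes)}
    n_gt = {c: 0 for c in range(n_classes)}
    for dets, gts, size in per_image:
        dets = sorted(dets, key=lambda b: -(b.score if b.score is not None else 1.0))
        tp, fp, fn, _ = match_detections(dets, gts, size, iou_thr)
        for g in gts:
            n_gt[g.cls] += 1
        for d, is_tp in zip(dets, tp):
            recs[d.cls].append((d.score if d.score is not None else 1.0, bool(is_tp)))

    ap: dict[int, float] = {}
    for c in range(n_classes):
        rows = sorted(recs[c], key=lambda r: -r[0])
        flags = np.array([r[1] for r in rows], dtype=bool)
        v = average_precision(flags, ~flags, n_gt[c])
        if v is not None:
            ap[c] = v
    map50 = float(np.mean(list(ap.values()))) if ap else 0.0

    # operating point: confidence maximizing F1 over pooled detections
    pooled = sorted([(s, t, c) for c in recs for (s, t) in recs[c]], key=lambda r: -r[0])
    total_gt = sum(n_gt.values())
    best = (0.0, 0.0, 0.0, 0.0)  # f1, precision, recall, conf
    tp_run = fp_run = 0
    for s, is_tp, _ in pooled:
        tp_run += is_tp
        fp_run += not is_tp
        prec = tp_run / (tp_run + fp_run)
        rec = tp_run / total_gt if total_gt else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if f1 > best[0]:
            best = (f1, prec, rec, s)
    _, precision, recall, conf = best

    tp_c, fp_c, fn_c = {}, {}, {}
    for c in range(n_classes):
        t = sum(1 for s, flag in recs[c] if flag and s >= conf)
        f = sum(1 for s, flag in recs[c] if not flag and s >= conf)
        tp_c[c], fp_c[c], fn_c[c] = t, f, n_gt[c] - t
    return EvalReport(precision, recall, ap, map50, tp_c, fp_c, fn_c, conf)


def evaluate(model, dataset: list[LabeledImage], conf_thr: float = 0.001, iou_thr: float = 0.5, nms_iou: float = 0.45, n_classes: int = 4) -> EvalReport:
    """Run a detector over labeled images and score it at IoU ``iou_thr``."""
    from .head import decode
    from .nn.autograd import Tensor

    model.eval()
    per_image = []
    for img in dataset:
        x = img.pixels.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
        raw = model(Tensor(x))
        dets = decode(raw, (img.height, img.width), conf_thr=conf_thr, nms_iou=nms_iou)
        per_image.append((dets, img.boxes, (img.height, img.width)))
    return evaluate_detections(per_image, iou_thr, n_classes)
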