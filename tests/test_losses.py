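"""IoU-family regression losses: hand values, reduction cases, oracle
agreement and gradient checks; plus the assembled detection criterion."""

import numpy as np
import pytest

from cattledet.losses import (
    LossConfig,
    box_similarity_t,
    ciou,
    detection_loss,
    inner_box,
    inner_iou,
    inner_mpdiou,
    iou,
    iou_t,
    mpdiou,
)
from cattledet.nn.autograd import Tensor
from conftest import random_xyxy


def rasterized_iou(a, b, step=0.01):
    """Counting oracle: IoU from grid-cell membership at `step` pitch.

    Cell centers (i + 0.5) * step inside an interval [lo, hi) are counted
    per axis; areas and intersections are products of 1-D counts, so no
    grid is materialized.
    """

    def count(lo, hi):
        first = np.ceil(lo / step - 0.5)
        last = np.floor(hi / step - 0.5)
        return max(0.0, last - first + 1)

    na = count(a[0], a[2]) * count(a[1], a[3])
    nb = count(b[0], b[2]) * count(b[1], b[3])
    ni = count(max(a[0], b[0]), min(a[2], b[2])) * count(max(a[1], b[1]), min(a[3], b[3]))
    if max(a[0], b[0]) >= min(a[2], b[2]) or max(a[1], b[1]) >= min(a[3], b[3]):
        ni = 0.0
    union = na + nb - ni
    return ni / union if union else 0.0


def reference_ciou(p, g):
    """Independent scalar CIoU transcription (the published formula)."""
    import math

    inter = max(0, min(p[2], g[2]) - max(p[0], g[0])) * max(0, min(p[3], g[3]) - max(p[1], g[1]))
    union = (p[2] - p[0]) * (p[3] - p[1]) + (g[2] - g[0]) * (g[3] - g[1]) - inter
    i = inter / union
    cw = max(p[2], g[2]) - min(p[0], g[0])
    ch = max(p[3], g[3]) - min(p[1], g[1])
    rho2 = ((p[0] + p[2]) / 2 - (g[0] + g[2]) / 2) ** 2 + ((p[1] + p[3]) / 2 - (g[1] + g[3]) / 2) ** 2
    v = 4 / math.pi**2 * (math.atan((g[2] - g[0]) / (g[3] - g[1])) - math.atan((p[2] - p[0]) / (p[3] - p[1]))) ** 2
    alpha = v / (1 - i + v + 1e-12)
    return i - rho2 / (cw**2 + ch**2 + 1e-12) - alpha * v


class TestIoUFamily:
    def test_identical_boxes_are_fixpoints(self):
        b = [3.0, 4.0, 50.0, 80.0]
        assert iou(b, b) == 1.0
        assert ciou(b, b) == pytest.approx(1.0)
        assert mpdiou(b, b, 640, 640) == 1.0
        assert inner_mpdiou(b, b, 640, 640, ratio=1.3) == 1.0

    def test_hand_values(self):
        assert iou([0, 0, 10, 10], [5, 0, 15, 10]) == pytest.approx(1 / 3)
        assert iou([0, 0, 10, 10], [20, 20, 30, 30]) == 0.0
        # direct substitution: IoU = 64/136, d1^2 = d2^2 = 8, frame 100x100
        val = mpdiou([0, 0, 10, 10], [2, 2, 12, 12], 100, 100)
        assert val == pytest.approx(64 / 136 - 16 / 20000, abs=1e-12)
        assert val == pytest.approx(0.46979, abs=1e-4)

    def test_inner_box_scaling(self):
        assert inner_box([0, 0, 10, 10], 0.5).tolist() == [2.5, 2.5, 7.5, 7.5]
        assert inner_box([3, 4, 9, 10], 1.0).tolist() == [3, 4, 9, 10]
        b = inner_box([0, 0, 8, 6], 1.25)
        area = (b[2] - b[0]) * (b[3] - b[1])
        assert area == pytest.approx(48 * 1.25**2)

    def test_translation_invariance(self, rng):
        p, g = [0, 0, 10, 10], [2, 2, 12, 12]
        for d in (5.0, -3.0, 17.5):
            shifted = mpdiou([c + d for c in p], [c + d for c in g], 100, 100)
            assert shifted == pytest.approx(mpdiou(p, g, 100, 100))

    def test_symmetry_of_iou_and_corner_penalty(self, rng):
        a = random_xyxy(rng, 20)
        b = random_xyxy(rng, 20)
        assert np.allclose(iou(a, b), iou(b, a))
        pen_ab = iou(a, b) - mpdiou(a, b, 200, 200)
        pen_ba = iou(b, a) - mpdiou(b, a, 200, 200)
        assert np.allclose(pen_ab, pen_ba)

    def test_inner_ratio_one_reduces_to_mpdiou_exactly(self, rng):
        a = random_xyxy(rng, 200)
        b = random_xyxy(rng, 200)
        assert np.array_equal(inner_mpdiou(a, b, 640, 640, 1.0), mpdiou(a, b, 640, 640))

    def test_values_bounded_above_by_one(self, rng):
        a = random_xyxy(rng, 300)
        b = random_xyxy(rng, 300)
        for v in (iou(a, b), ciou(a, b), mpdiou(a, b, 100, 100), inner_mpdiou(a, b, 100, 100)):
            assert np.all(v <= 1.0 + 1e-12)

    def test_zero_area_box_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero-area"):
            assert iou([0, 0, 0, 0], [0, 0, 0, 0]) == 0.0

    def test_gtbox_normalization_variant(self):
        p, g = [0, 0, 10, 10], [2, 2, 12, 12]
        v = mpdiou(p, g, 640, 640, norm="gtbox")
        assert v == pytest.approx(64 / 136 - 16 / 200)


class TestOracles:
    def test_iou_matches_rasterization_on_1000_pairs(self, rng):
        a = random_xyxy(rng, 1000, 0, 60, min_side=5.0)
        b = random_xyxy(rng, 1000, 0, 60, min_side=5.0)
        for i in range(1000):
            assert iou(a[i], b[i]) == pytest.approx(rasterized_iou(a[i], b[i]), abs=1e-3)

    def test_inner_mpdiou_against_rasterized_inner_overlap(self, rng):
        # inner-box IoU by the counting oracle + corner penalty by hand
        a = random_xyxy(rng, 50, 0, 60, min_side=6.0)
        b = random_xyxy(rng, 50, 0, 60, min_side=6.0)
        for i in range(50):
            ref = rasterized_iou(inner_box(a[i], 0.75), inner_box(b[i], 0.75))
            d1 = (a[i, 0] - b[i, 0]) ** 2 + (a[i, 1] - b[i, 1]) ** 2
            d2 = (a[i, 2] - b[i, 2]) ** 2 + (a[i, 3] - b[i, 3]) ** 2
            ref -= (d1 + d2) / (100**2 + 100**2)
            assert inner_mpdiou(a[i], b[i], 100, 100, 0.75) == pytest.approx(ref, abs=1e-3)

    def test_ciou_matches_independent_reference(self, rng):
        a = random_xyxy(rng, 200)
        b = random_xyxy(rng, 200)
        vals = ciou(a, b)
        for i in range(200):
            assert vals[i] == pytest.approx(reference_ciou(a[i], b[i]), abs=1e-6)

    def test_concentric_same_aspect_reduces_to_diou(self):
        # v = 0 -> CIoU equals IoU - rho^2/c^2 (here centers coincide too)
        p, g = [10, 10, 30, 30], [0, 0, 40, 40]
        assert ciou(p, g) == pytest.approx(iou(p, g))


class TestTensorGradients:
    @pytest.mark.parametrize("kind", ["ciou", "inner_iou", "mpdiou", "inner_mpdiou"])
    def test_similarity_gradient_matches_finite_differences(self, kind, rng):
        cfg = LossConfig(kind=kind)
        a = random_xyxy(rng, 6, 5, 90, min_side=8.0)
        b = random_xyxy(rng, 6, 5, 90, min_side=8.0)
        at = Tensor(a, requires_grad=True)
        box_similarity_t(at, Tensor(b), cfg, 100, 100).sum().backward()

        def ciou_frozen_alpha(alpha_const):
            # alpha is treated as a constant in the backward pass (standard
            # CIoU practice), so the FD reference freezes it per pair
            def f(p, g):
                base = iou(p, g)
                cw = max(p[2], g[2]) - min(p[0], g[0])
                ch = max(p[3], g[3]) - min(p[1], g[1])
                rho2 = ((p[0] + p[2] - g[0] - g[2]) ** 2 + (p[1] + p[3] - g[1] - g[3]) ** 2) / 4
                v = 4 / np.pi**2 * (np.arctan((g[2] - g[0]) / (g[3] - g[1])) - np.arctan((p[2] - p[0]) / (p[3] - p[1]))) ** 2
                return base - rho2 / (cw**2 + ch**2 + 1e-9) - alpha_const * v

            return f

        def alpha_at(p, g):
            base = iou(p, g)
            v = 4 / np.pi**2 * (np.arctan((g[2] - g[0]) / (g[3] - g[1])) - np.arctan((p[2] - p[0]) / (p[3] - p[1]))) ** 2
            return v / (1 - base + v + 1e-9)

        ref_for_pair = {
            "ciou": lambda p, g: ciou_frozen_alpha(alpha_at(p, g)),
            "inner_iou": lambda p, g: (lambda pp, gg: inner_iou(pp, gg, cfg.inner_ratio)),
            "mpdiou": lambda p, g: (lambda pp, gg: mpdiou(pp, gg, 100, 100)),
            "inner_mpdiou": lambda p, g: (lambda pp, gg: inner_mpdiou(pp, gg, 100, 100, cfg.inner_ratio)),
        }[kind]
        eps = 1e-5
        for i in range(6):
            ref = ref_for_pair(a[i], b[i])
            for j in range(4):
                ap, am = a.copy(), a.copy()
                ap[i, j] += eps
                am[i, j] -= eps
                num = (ref(ap[i], b[i]) - ref(am[i], b[i])) / (2 * eps)
                assert at.grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_tensor_and_numpy_paths_agree(self, rng):
        a = random_xyxy(rng, 100)
        b = random_xyxy(rng, 100)
        t = iou_t(Tensor(a), Tensor(b)).data
        assert np.allclose(t, iou(a, b), atol=1e-6)


class TestDetectionLoss:
    def _toy_raw(self, rng, n_classes=4, reg_max=16):
        from cattledet.head import RawPrediction

        levels = [(8, 8), (4, 4), (2, 2)]
        box = [Tensor(rng.normal(0, 0.1, (1, 4 * reg_max, h, w)).astype(np.float32), requires_grad=True) for h, w in levels]
        cls = [Tensor(rng.normal(-4, 0.1, (1, n_classes, h, w)).astype(np.float32), requires_grad=True) for h, w in levels]
        return RawPrediction(box=box, cls=cls, reg_max=reg_max)

    def test_empty_image_has_only_background_cls_term(self, rng):
        raw = self._toy_raw(rng)
        total, comps = detection_loss(raw, [[]], (64, 64), LossConfig())
        assert comps["box"] == 0.0 and comps["dfl"] == 0.0
        assert comps["cls"] > 0.0 and np.isfinite(float(total.data))

    def test_nan_predictions_raise_with_diagnostics(self, rng):
        raw = self._toy_raw(rng)
        raw.cls[0].data[0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            detection_loss(raw, [[]], (64, 64), LossConfig())

    def test_loss_kinds_give_different_gradients(self, rng):
        from cattledet.boxes import Box

        target = [[Box(0, 0.5, 0.5, 0.6, 0.6)]]
        grads = {}
        for kind in ("ciou", "inner_mpdiou"):
            raw = self._toy_raw(np.random.default_rng(0))
            total, _ = detection_loss(raw, target, (64, 64), LossConfig(kind=kind))
            total.backward()
            grads[kind] = raw.box[0].grad.copy()
        assert not np.allclose(grads["ciou"], grads["inner_mpdiou"])

    def test_loss_decreases_under_gradient_descent(self, rng):
        # 50 SGD steps on one fixed toy batch: trend must be downward
        from cattledet.boxes import Box
        from cattledet.nn import SGD

        raw = self._toy_raw(np.random.default_rng(1))
        params = raw.box + raw.cls
        opt = SGD(params, lr=0.5, momentum=0.9, weight_decay=0.0)
        target = [[Box(1, 0.5, 0.5, 0.7, 0.7)]]
        values = []
        for _ in range(50):
            for p in params:
                p.grad = None
            total, _ = detection_loss(raw, target, (64, 64), LossConfig())
            values.append(float(total.data))
            total.backward()
            opt.step()
        assert np.mean(values[-10:]) < 0.2 * np.mean(values[:5])
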