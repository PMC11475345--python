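"""Reference YOLOv8n detector (CSP/C2f backbone, SPPF, FPN-PAN neck,
decoupled head, reg_max=16) used as the comparison baseline.

Widths/depths follow the nano scaling (width x0.25, depth x0.33 of the
base architecture): stages 16/32/64/128/256 channels with C2f repeats
(1, 2, 2, 1) and single-repeat C2f blocks in the neck.
"""

from __future__ import annotations

import numpy as np

from .head import RawPrediction
from .nn import Conv2d, ConvBNAct, MaxPool2d, Module, ModuleList, Sequential, concat, upsample_nearest2
from .nn.autograd import Tensor


class Bottleneck(Module):
    def __init__(self, c_in, c_out, shortcut=True, e=1.0, rng=None):
        super().__init__()
        c_mid = int(c_out * e)
        self.cv1 = ConvBNAct(c_in, c_mid, 3, rng=rng)
        self.cv2 = ConvBNAct(c_mid, c_out, 3, rng=rng)
        self.add = shortcut and c_in == c_out

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage partial block with split + cascaded bottlenecks."""

    def __init__(self, c_in, c_out, n=1, shortcut=False, e=0.5, rng=None):
        super().__init__()
        self.c_mid = int(c_out * e)
        self.cv1 = ConvBNAct(c_in, 2 * self.c_mid, 1, rng=rng)
        self.blocks = ModuleList([Bottleneck(self.c_mid, self.c_mid, shortcut, 1.0, rng=rng) for _ in range(n)])
        self.cv2 = ConvBNAct((2 + n) * self.c_mid, c_out, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        c = self.c_mid
        a = Tensor(y.data[:, :c], _prev=(y,))
        b = Tensor(y.data[:, c:], _prev=(y,))

        def _bw_a(g, y=y, c=c):
            if y.requires_grad:
                full = np.zeros_like(y.data)
                full[:, :c] = g
                y._accum(full)

        def _bw_b(g, y=y, c=c):
            if y.requires_grad:
                full = np.zeros_like(y.data)
                full[:, c:] = g
                y._accum(full)

        a._backward, b._backward = _bw_a, _bw_b
        outs = [a, b]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(concat(outs, axis=1))


class SPPF(Module):
    def __init__(self, c_in, c_out, k=5, rng=None):
        super().__init__()
        self.cv1 = ConvBNAct(c_in, c_in // 2, 1, rng=rng)
        self.pool = MaxPool2d(k, 1)
        self.cv2 = ConvBNAct(2 * c_in, c_out, 1, rng=rng)

    def forward(self, x):
        y1 = self.cv1(x)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        y4 = self.pool(y3)
        return self.cv2(concat([y1, y2, y3, y4], axis=1))


class V8Backbone(Module):
    """Stem + 4 stages; returns (P3, P4, P5) before SPPF."""

    def __init__(self, rng=None):
        super().__init__()
        self.stem = ConvBNAct(3, 16, 3, 2, rng=rng)
        self.down1 = ConvBNAct(16, 32, 3, 2, rng=rng)
        self.c2f1 = C2f(32, 32, 1, True, rng=rng)
        self.down2 = ConvBNAct(32, 64, 3, 2, rng=rng)
        self.c2f2 = C2f(64, 64, 2, True, rng=rng)
        self.down3 = ConvBNAct(64, 128, 3, 2, rng=rng)
        self.c2f3 = C2f(128, 128, 2, True, rng=rng)
        self.down4 = ConvBNAct(128, 256, 3, 2, rng=rng)
        self.c2f4 = C2f(256, 256, 1, True, rng=rng)

    def forward(self, x):
        x = self.c2f1(self.down1(self.stem(x)))
        p3 = self.c2f2(self.down2(x))
        p4 = self.c2f3(self.down3(p3))
        p5 = self.c2f4(self.down4(p4))
        return p3, p4, p5


class V8Neck(Module):
    """FPN-PAN: top-down then bottom-up C2f fusion; (64, 128, 256) out."""

    def __init__(self, in_channels=(64, 128, 256), rng=None):
        super().__init__()
        c3, c4, c5 = in_channels
        self.c2f_td1 = C2f(c5 + c4, 128, 1, False, rng=rng)
        self.c2f_td2 = C2f(128 + c3, 64, 1, False, rng=rng)
        self.down1 = ConvBNAct(64, 64, 3, 2, rng=rng)
        self.c2f_bu1 = C2f(64 + 128, 128, 1, False, rng=rng)
        self.down2 = ConvBNAct(128, 128, 3, 2, rng=rng)
        self.c2f_bu2 = C2f(128 + c5, 256, 1, False, rng=rng)

    def forward(self, feats):
        p3, p4, p5 = feats
        t4 = self.c2f_td1(concat([upsample_nearest2(p5), p4], axis=1))
        t3 = self.c2f_td2(concat([upsample_nearest2(t4), p3], axis=1))
        b4 = self.c2f_bu1(concat([self.down1(t3), t4], axis=1))
        b5 = self.c2f_bu2(concat([self.down2(b4), p5], axis=1))
        return t3, b4, b5

    out_channels = (64, 128, 256)


class V8Detect(Module):
    """YOLOv8 decoupled head: per-level regression and classification
    towers (two 3x3 convs each) with 1x1 prediction layers."""

    def __init__(self, n_classes=4, in_channels=(64, 128, 256), reg_max=16, rng=None):
        super().__init__()
        self.n_classes, self.reg_max = n_classes, reg_max
        c2 = max(16, in_channels[0] // 4, reg_max * 4)
        c3 = max(in_channels[0], min(n_classes, 100))
        self.cv2 = ModuleList(
            [Sequential([ConvBNAct(c, c2, 3, rng=rng), ConvBNAct(c2, c2, 3, rng=rng), Conv2d(c2, 4 * reg_max, 1, rng=rng)]) for c in in_channels]
        )
        self.cv3 = ModuleList(
            [Sequential([ConvBNAct(c, c3, 3, rng=rng), ConvBNAct(c3, c3, 3, rng=rng), Conv2d(c3, n_classes, 1, rng=rng)]) for c in in_channels]
        )
        for branch in self.cv3:
            branch[-1].bias.data[:] = -4.59

    def forward(self, feats) -> RawPrediction:
        box_out = [cv2(f) for cv2, f in zip(self.cv2, feats)]
        cls_out = [cv3(f) for cv3, f in zip(self.cv3, feats)]
        return RawPrediction(box=box_out, cls=cls_out, reg_max=self.reg_max)
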