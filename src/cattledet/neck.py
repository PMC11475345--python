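"""Multi-Convolutional Focused Pyramid (MCFP) neck.

The three backbone levels are first aligned to a common channel width by
1x1 convolutions.  Semantic information flows top-down (nearest x2
up-sampling, add, 3x3 refine).  The aligned trio is then fused at the
middle (stride-16) scale — the P3 path through ADown down-sampling, the
P5 path through up-sampling — and passed through an inception-style set
of parallel depthwise convolutions whose pointwise aggregation captures
multi-scale context.  Finally the contextualized map is *diffused* back
onto every level through residual connections with level-specific 1x1
projections, so each output N3/N4/N5 sees information from every input
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, ConvBNAct, Module, ModuleList, avg_pool2d, concat, max_pool2d, upsample_nearest2
from .nn.autograd import Tensor


@dataclass
class MCFPConfig:
    neck_width: int = 76  # common channel count after 1x1 alignment
    band_kernel: int = 7  # 1xk / kx1 depthwise band pair in the context block
    use_adown: bool = True


class ADown(Module):
    """Dual-branch halving: avg-pool context + 3x3 s2 conv on one channel
    half, max-pool + 1x1 conv on the other.  Cheaper than a plain 3x3
    stride-2 convolution while mixing pooled and learned sub-sampling."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        super().__init__()
        if c_in % 2 or c_out % 2:
            raise ValueError("ADown channel counts must be even")
        self.c_in, self.c_out = c_in, c_out
        h_in, h_out = c_in // 2, c_out // 2
        rng = rng or np.random.default_rng(0)
        self.conv_a = ConvBNAct(h_in, h_out, 3, 2, rng=rng)
        self.conv_b = ConvBNAct(h_in, h_out, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"ADown needs even spatial dims, got {x.shape[2:]}")
        x = avg_pool2d(x, 2, 1) if min(x.shape[2], x.shape[3]) > 1 else x
        h = self.c_in // 2
        xa = Tensor(x.data[:, :h], _prev=(x,))
        xb = Tensor(x.data[:, h:], _prev=(x,))

        def _bw_a(g, x=x, h=h):
            if x.requires_grad:
                full = np.zeros_like(x.data)
                full[:, :h] = g
                x._accum(full)

        def _bw_b(g, x=x, h=h):
            if x.requires_grad:
                full = np.zeros_like(x.data)
                full[:, h:] = g
                x._accum(full)

        xa._backward, xb._backward = _bw_a, _bw_b
        a = self.conv_a(xa)
        b = self.conv_b(max_pool2d(xb, 3, 2, 1))
        return concat([a, b], axis=1)


def adown_param_count(c_in: int, c_out: int) -> int:
    h_in, h_out = c_in // 2, c_out // 2
    return (9 * h_in * h_out + 2 * h_out) + (h_in * h_out + 2 * h_out)


class InceptionContext(Module):
    """Parallel depthwise branches (identity, 3x3, 1xk + kx1 bands) summed,
    pointwise aggregation, residual add."""

    def __init__(self, width: int, band_kernel: int = 7, rng=None):
        super().__init__()
        c, k = width, band_kernel
        rng = rng or np.random.default_rng(0)
        self.dw_square = Conv2d(c, c, 3, groups=c, rng=rng)
        self.dw_band_h = Conv2d(c, c, (1, k), groups=c, rng=rng)
        self.dw_band_v = Conv2d(c, c, (k, 1), groups=c, rng=rng)
        self.pw = Conv2d(c, c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = x + self.dw_square(x) + self.dw_band_v(self.dw_band_h(x))
        return x + self.pw(y)


class MCFP(Module):
    """pyramid (P3,P4,P5) -> (N3,N4,N5) at strides 8/16/32, common width."""

    def __init__(self, in_channels: tuple[int, int, int], cfg: MCFPConfig | None = None, rng=None):
        super().__init__()
        self.cfg = cfg or MCFPConfig()
        w = self.cfg.neck_width
        rng = rng or np.random.default_rng(0)
        self.align = ModuleList([ConvBNAct(c, w, 1, rng=rng) for c in in_channels])
        self.refine4 = ConvBNAct(w, w, 3, rng=rng)
        self.refine3 = ConvBNAct(w, w, 3, rng=rng)
        if self.cfg.use_adown:
            self.down3 = ADown(w, w, rng=rng)
            self.down_ctx = ADown(w, w, rng=rng)
        else:
            self.down3 = ConvBNAct(w, w, 3, 2, rng=rng)
            self.down_ctx = ConvBNAct(w, w, 3, 2, rng=rng)
        self.context = InceptionContext(w, self.cfg.band_kernel, rng=rng)
        self.diffuse = ModuleList([ConvBNAct(w, w, 1, act="none", rng=rng) for _ in range(3)])

    def forward(self, pyramid: tuple[Tensor, Tensor, Tensor]) -> tuple[Tensor, Tensor, Tensor]:
        p3, p4, p5 = pyramid
        a3, a4, a5 = (align(p) for align, p in zip(self.align, pyramid))
        # top-down pathway
        t4 = self.refine4(a4 + upsample_nearest2(a5))
        t3 = self.refine3(a3 + upsample_nearest2(t4))
        # multi-scale fusion at the middle scale + inception context
        fused = self.down3(t3) + t4 + upsample_nearest2(a5)
        ctx = self.context(fused)
        # residual diffusion back to every level
        n3 = t3 + self.diffuse[0](upsample_nearest2(ctx))
        n4 = t4 + self.diffuse[1](ctx)
        n5 = a5 + self.diffuse[2](self.down_ctx(ctx))
        return n3, n4, n5

    @property
    def out_channels(self) -> tuple[int, int, int]:
        w = self.cfg.neck_width
        return (w, w, w)
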