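"""StarNet backbone: a four-stage hierarchy of star-operation blocks.

Each stage is a stride-2 3x3 convolution followed by ``depths[i]`` star
blocks.  A star block lifts the features with two parallel pointwise
expansions and multiplies them elementwise (the "star" operation), which
implicitly spans a high-dimensional polynomial feature space at the cost
of a product; depthwise 7x7 convolutions carry spatial context and batch
normalization follows each depthwise layer so the pair can be fused at
inference time.  Channel width doubles each stage; the last three stages
are emitted as the P3/P4/P5 pyramid (strides 8/16/32).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import ConvBNAct, Conv2d, BatchNorm2d, Module, ModuleList, ReLU6, Sequential
from .nn.autograd import Tensor


@dataclass
class StarNetConfig:
    base_width: int = 20  # stage-1 width; doubles each stage
    depths: tuple[int, int, int, int] = (2, 1, 1, 2)
    expansion: int = 4
    dw_kernel: int = 7
    down_kernel: int = 3

    @property
    def stage_widths(self) -> tuple[int, int, int, int]:
        return tuple(self.base_width * (2**i) for i in range(4))

    @property
    def pyramid_channels(self) -> tuple[int, int, int]:
        """Channels of P3/P4/P5 (last three stages)."""
        return self.stage_widths[1:]


class StarBlock(Module):
    """dw7x7+BN -> two parallel 1x1 expansions -> elementwise product ->
    1x1 projection -> dw7x7+BN(zero-init) -> residual."""

    def __init__(self, width: int, expansion: int = 4, dw_kernel: int = 7, rng=None, star: bool = True):
        super().__init__()
        e = expansion * width
        self.dw1 = Conv2d(width, width, dw_kernel, 1, None, 1, groups=width, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(width)
        self.f1 = Conv2d(width, e, 1, rng=rng)
        self.f2 = Conv2d(width, e, 1, rng=rng)
        self.g = Conv2d(e, width, 1, rng=rng)
        self.dw2 = Conv2d(width, width, dw_kernel, 1, None, 1, groups=width, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(width, zero_init=True)
        self.act = ReLU6()
        self.star = star  # False swaps the product for a sum (ablation probe)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.dw1(x))
        a = self.act(self.f1(y))
        b = self.f2(y)
        y = a * b if self.star else a + b
        y = self.bn2(self.dw2(self.g(y)))
        return x + y


class StarNet(Module):
    """Backbone producing (P3, P4, P5) at strides 8/16/32."""

    def __init__(self, cfg: StarNetConfig | None = None, rng=None):
        super().__init__()
        self.cfg = cfg or StarNetConfig()
        c = self.cfg
        rng = rng or np.random.default_rng(0)
        w = c.stage_widths
        self.stem = ConvBNAct(3, w[0], c.down_kernel, 2, act="relu6", rng=rng)
        downs, stages = [], []
        c_prev = w[0]
        for i in range(4):
            downs.append(ConvBNAct(c_prev, w[i], c.down_kernel, 2, act="relu6", rng=rng))
            stages.append(
                Sequential([StarBlock(w[i], c.expansion, c.dw_kernel, rng=rng) for _ in range(c.depths[i])])
            )
            c_prev = w[i]
        self.downs = ModuleList(downs)
        self.stages = ModuleList(stages)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial size {x.shape[2:]} not divisible by 32")
        x = self.stem(x)  # stride 2
        feats = []
        for down, stage in zip(self.downs, self.stages):
            x = stage(down(x))
            feats.append(x)
        return feats[1], feats[2], feats[3]  # strides 8, 16, 32


def star_block_param_count(width: int, expansion: int = 4, dw_kernel: int = 7) -> int:
    """Closed-form parameter count of one star block (symbolic audit)."""
    e = expansion * width
    k2 = dw_kernel * dw_kernel
    dw = 2 * (k2 * width)  # two depthwise convs, no bias
    bn = 2 * (2 * width)
    pw = 2 * (width * e + e) + (e * width + width)  # f1, f2, g with bias
    return dw + bn + pw
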