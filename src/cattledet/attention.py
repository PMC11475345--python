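"""SPPF with Large Separable Kernel Attention (LSKA).

LSKA factors a large k x k depthwise kernel into four 1-D depthwise
convolutions: a plain horizontal/vertical pair of size 2d-1 capturing
local structure, then a dilated pair of size k//d with dilation d
extending the receptive field to exactly k, followed by a 1x1 convolution
that forms the attention map A; the output is the Hadamard product A * F.
The parameter cost is linear in the channel count except for the final
1x1.

``SPPFLSKA`` is the YOLO SPPF layer (1x1 reduce, serial 5x5 max-pools,
concatenation) with LSKA applied to the concatenated map before the final
1x1 projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, ConvBNAct, MaxPool2d, Module, ModuleList, concat
from .nn.autograd import Tensor


@dataclass
class LSKAConfig:
    k: int = 11  # effective large-kernel size
    d: int = 3  # dilation of the long-range pair

    @property
    def k_local(self) -> int:
        return 2 * self.d - 1

    @property
    def k_dilated(self) -> int:
        # floor keeps the kernel odd and the cascade support exactly k
        kd = self.k // self.d
        if kd % 2 == 0:
            kd -= 1
        return kd

    @property
    def receptive_field(self) -> int:
        return self.k_local + self.d * (self.k_dilated - 1)


class LSKA(Module):
    def __init__(self, channels: int, cfg: LSKAConfig | None = None, rng=None):
        super().__init__()
        self.cfg = cfg or LSKAConfig()
        c, k1, kd, d = channels, self.cfg.k_local, self.cfg.k_dilated, self.cfg.d
        self.channels = channels
        rng = rng or np.random.default_rng(0)
        self.conv_h = Conv2d(c, c, (1, k1), groups=c, rng=rng)
        self.conv_v = Conv2d(c, c, (k1, 1), groups=c, rng=rng)
        self.conv_h_d = Conv2d(c, c, (1, kd), d=(1, d), groups=c, rng=rng)
        self.conv_v_d = Conv2d(c, c, (kd, 1), d=(d, 1), groups=c, rng=rng)
        self.proj = Conv2d(c, c, 1, rng=rng)

    def attention(self, f: Tensor) -> Tensor:
        z_bar = self.conv_v(self.conv_h(f))
        z = self.conv_v_d(self.conv_h_d(z_bar))
        return self.proj(z)

    def forward(self, f: Tensor) -> Tensor:
        if f.shape[1] != self.channels:
            raise ValueError(f"LSKA expects {self.channels} channels, got {f.shape[1]}")
        return self.attention(f) * f


def lska_param_count(channels: int, cfg: LSKAConfig | None = None) -> int:
    """Closed-form parameter count (depthwise pairs + 1x1), symbolic audit."""
    cfg = cfg or LSKAConfig()
    c = channels
    dw = c * (2 * cfg.k_local + 2 * cfg.k_dilated) + 4 * c  # kernels + biases
    pw = c * c + c
    return dw + pw


class SPPFLSKA(Module):
    """SPPF augmented with LSKA on the concatenated pyramid features."""

    def __init__(self, c_in: int, c_out: int, pool_k: int = 5, n_pools: int = 3, lska_cfg: LSKAConfig | None = None, use_lska: bool = True, rng=None):
        super().__init__()
        if n_pools not in (2, 3):
            raise ValueError("n_pools must be 2 or 3")
        c_mid = c_in // 2
        rng = rng or np.random.default_rng(0)
        self.cv1 = ConvBNAct(c_in, c_mid, 1, rng=rng)
        self.pools = ModuleList([MaxPool2d(pool_k, 1) for _ in range(n_pools)])
        c_cat = c_mid * (n_pools + 1)
        self.lska = LSKA(c_cat, lska_cfg, rng=rng) if use_lska else None
        self.cv2 = ConvBNAct(c_cat, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        outs = [y]
        for pool in self.pools:
            outs.append(pool(outs[-1]))
        cat = concat(outs, axis=1)
        if self.lska is not None:
            cat = self.lska(cat)
        return self.cv2(cat)
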