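"""Model assembly: compose backbone, SPPF(-LSKA), neck and head into a
detector; count parameters and FLOPs; construct every ablation variant.

The default configuration is the full lightweight cattle detector
(StarNet backbone, SPPF-LSKA, MCFP neck, LMFD head); with every flag off
and ``backbone='yolov8n-csp'`` the graph is the standard YOLOv8n
reference.  Default widths were calibrated once so that the assembled
models reproduce the published structural budgets (1.40e6 parameters /
5.2 GFLOPs for the full model, 3.01e6 / 8.7 GFLOPs for the baseline,
7.52e5 vs 1.12e5 head parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attention import LSKAConfig, SPPFLSKA
from .backbone import StarNet, StarNetConfig
from .baseline import SPPF, V8Backbone, V8Detect, V8Neck
from .head import LMFDConfig, LMFDHead, RawPrediction
from .neck import MCFP, MCFPConfig
from .nn import Module
from .nn.profile import ParamFlopReport, count_flops as _count_flops, count_params as _count_params


@dataclass
class ModelConfig:
    img_size: int = 640
    n_classes: int = 4
    backbone: str = "starnet"  # 'starnet' | 'yolov8n-csp'
    use_lska: bool = True
    use_mcfp: bool = True
    use_lmfd: bool = True
    loss: str = "inner_mpdiou"  # 'ciou' | 'inner_iou' | 'mpdiou' | 'inner_mpdiou'
    inner_ratio: float = 0.7
    mpd_norm: str = "image"  # 'image' | 'gtbox'
    starnet: StarNetConfig = field(default_factory=StarNetConfig)
    lska: LSKAConfig = field(default_factory=LSKAConfig)
    mcfp: MCFPConfig = field(default_factory=MCFPConfig)
    lmfd: LMFDConfig = field(default_factory=LMFDConfig)
    seed: int = 0

    def __post_init__(self):
        if self.img_size % 32:
            raise ValueError("img_size must be divisible by 32")
        if self.backbone not in ("starnet", "yolov8n-csp"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    @classmethod
    def ablation_row(cls, starnet=False, lska=False, mcfp=False, lmfd=False, loss_inner_mpdiou=True, **kw) -> "ModelConfig":
        """One row of the module-ablation matrix."""
        return cls(
            backbone="starnet" if starnet else "yolov8n-csp",
            use_lska=lska,
            use_mcfp=mcfp,
            use_lmfd=lmfd,
            loss="inner_mpdiou" if loss_inner_mpdiou else "ciou",
            **kw,
        )


class Detector(Module):
    """backbone -> SPPF(-LSKA) on P5 -> neck -> head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.backbone == "starnet":
            self.backbone = StarNet(cfg.starnet, rng=rng)
            c3, c4, c5 = cfg.starnet.pyramid_channels
        else:
            self.backbone = V8Backbone(rng=rng)
            c3, c4, c5 = 64, 128, 256
        if cfg.use_lska:
            self.sppf = SPPFLSKA(c5, c5, lska_cfg=cfg.lska, rng=rng)
        else:
            self.sppf = SPPF(c5, c5, rng=rng)
        if cfg.use_mcfp:
            self.neck = MCFP((c3, c4, c5), cfg.mcfp, rng=rng)
            neck_out = self.neck.out_channels
        else:
            self.neck = V8Neck((c3, c4, c5), rng=rng)
            neck_out = V8Neck.out_channels
        if cfg.use_lmfd:
            lmfd_cfg = replace(cfg.lmfd, n_classes=cfg.n_classes)
            self.head = LMFDHead(lmfd_cfg, in_channels=neck_out, rng=rng)
        else:
            self.head = V8Detect(cfg.n_classes, in_channels=neck_out, rng=rng)

    def forward(self, x) -> RawPrediction:
        p3, p4, p5 = self.backbone(x)
        p5 = self.sppf(p5)
        n3, n4, n5 = self.neck((p3, p4, p5))
        return self.head((n3, n4, n5))

    @property
    def module_groups(self) -> dict[str, Module]:
        return {"backbone": self.backbone, "sppf": self.sppf, "neck": self.neck, "head": self.head}


def build_model(cfg: ModelConfig | None = None) -> Detector:
    return Detector(cfg or ModelConfig())


def build_yolov8n_baseline(n_classes: int = 4) -> Detector:
    """The reference YOLOv8n graph (all custom modules off)."""
    return Detector(ModelConfig(n_classes=n_classes, backbone="yolov8n-csp", use_lska=False, use_mcfp=False, use_lmfd=False, loss="ciou"))


def count_params(model: Detector, per_module: bool = True) -> ParamFlopReport:
    groups = model.module_groups if isinstance(model, Detector) else None
    return _count_params(model, per_module=per_module, groups=groups)


def count_flops(model: Module, img_size: int = 640, convention: str = "table") -> float:
    """Total FLOPs at ``img_size``; see :mod:`cattledet.nn.profile`."""
    return _count_flops(model, img_size=img_size, convention=convention)


def param_flop_report(model: Detector, img_size: int = 640) -> ParamFlopReport:
    rep = count_params(model)
    rep.flops_table = count_flops(model, img_size, "table")
    rep.flops_per_layer = count_flops(model, img_size, "per_layer")
    rep.img_size = img_size
    return rep
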