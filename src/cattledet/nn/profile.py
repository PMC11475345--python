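"""Parameter and FLOP accounting.

Two FLOP conventions are exposed:

``per_layer``
    The per-convolution sum ``Cin/g * Cout * Kh * Kw * Hout * Wout``
    (multiply-accumulates counted once) plus one add per output element
    for the bias / folded-normalization term.

``table``
    The whole-network 2-ops-per-multiply-accumulate convention used by
    mainstream YOLO profilers when quoting model cards (convolutions only,
    normalization folded): ``2 * sum(MACs)``.

FLOPs are measured by running the model's forward graph in trace mode:
convolutions record their MAC counts from real propagated shapes and skip
the arithmetic, so profiling a 640x640 input costs milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Module


@dataclass
class ParamFlopReport:
    """Per-module parameter counts and whole-model FLOPs."""

    total_params: int
    per_module: dict[str, int] = field(default_factory=dict)
    flops_per_layer: float | None = None  # 1xMAC + bias adds
    flops_table: float | None = None  # 2xMAC
    img_size: int | None = None

    def gflops(self, convention: str = "table") -> float:
        v = self.flops_table if convention == "table" else self.flops_per_layer
        if v is None:
            raise ValueError("report carries no FLOP measurement")
        return v / 1e9


def count_params(model: Module, per_module: bool = False, groups: dict[str, Module] | None = None) -> ParamFlopReport:
    """Count trainable parameters; optionally break down by top-level child."""
    total = model.num_params()
    per: dict[str, int] = {}
    if per_module:
        children = groups if groups is not None else model._modules
        for name, m in children.items():
            per[name] = m.num_params()
    return ParamFlopReport(total_params=total, per_module=per)


def trace_flops(forward_fn, input_shape) -> tuple[int, int]:
    """Run ``forward_fn`` on a zero input in trace mode; return (macs, adds)."""
    trace: list = []
    ag._TRACE = trace
    try:
        x = Tensor(np.zeros(input_shape, dtype=np.float32))
        forward_fn(x)
    finally:
        ag._TRACE = None
    macs = sum(t[1] for t in trace)
    adds = sum(t[2] for t in trace)
    return macs, adds


def count_flops(model: Module, img_size: int = 640, convention: str = "table", batch: int = 1) -> float:
    """FLOPs of ``model`` at ``img_size`` (square input), per image."""
    if img_size % 32:
        raise ValueError("img_size must be divisible by 32")
    macs, adds = trace_flops(model, (batch, 3, img_size, img_size))
    macs, adds = macs / batch, adds / batch
    if convention == "table":
        return 2.0 * macs
    if convention == "per_layer":
        return float(macs + adds)
    raise ValueError(f"unknown FLOP convention {convention!r}")
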