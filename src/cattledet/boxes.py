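"""Bounding-box and labeled-image containers.

Labels follow the YOLO convention (normalized center/size); internal
geometry uses continuous 0-based pixel corners (x1, y1, x2, y2) with
x1 < x2, y1 < y2, because the IoU family is evaluated on continuous
coordinates.

Behavior classes: 0=standing, 1=walking, 2=eating, 3=lying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_NAMES = ("standing", "walking", "eating", "lying")


@dataclass
class Box:
    """One detection or ground-truth box (normalized center-size)."""

    cls: int
    cx: float
    cy: float
    w: float
    h: float
    score: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside [0,1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box size ({self.w}, {self.h}) outside (0,1]")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0,1]")

    def to_xyxy(self, img_w: int, img_h: int, clip: bool = True) -> tuple[float, float, float, float]:
        x1 = (self.cx - self.w / 2) * img_w
        y1 = (self.cy - self.h / 2) * img_h
        x2 = (self.cx + self.w / 2) * img_w
        y2 = (self.cy + self.h / 2) * img_h
        if clip:
            x1, x2 = max(0.0, x1), min(float(img_w), x2)
            y1, y2 = max(0.0, y1), min(float(img_h), y2)
        return (x1, y1, x2, y2)

    @classmethod
    def from_xyxy(cls, cls_id: int, x1: float, y1: float, x2: float, y2: float, img_w: int, img_h: int, score: float | None = None) -> "Box":
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"degenerate corner box ({x1},{y1},{x2},{y2})")
        return cls(
            cls=cls_id,
            cx=min(1.0, max(0.0, (x1 + x2) / 2 / img_w)),
            cy=min(1.0, max(0.0, (y1 + y2) / 2 / img_h)),
            w=min(1.0, (x2 - x1) / img_w),
            h=min(1.0, (y2 - y1) / img_h),
            score=score,
        )


@dataclass
class LabeledImage:
    """H x W x 3 uint8 image plus its ground-truth boxes."""

    pixels: np.ndarray
    boxes: list[Box] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be HxWx3 uint8")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError("image smaller than 32 px")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]
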