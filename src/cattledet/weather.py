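"""Weather-synthesis augmentation by atmospheric blending.

A weathered image is the per-pixel convex combination

    I(x) = J(x) * t(x) + A * (1 - t(x))

where ``J`` is the clean image (normalized to [0, 1]), ``t(x)`` in [0, 1]
is the transmittance map (fraction of scene radiance surviving the
atmosphere) and ``A`` is the atmospheric light value.  Five kinds are
synthesized, each driven by a single ``intensity`` in [0, 1] with random
location:

* fog — smooth low-frequency field, mean transmittance 1 - 0.6*intensity,
  A near 0.9;
* rain — elongated angled streaks where t drops, A near 1.0;
* snow — round flakes where t drops, A near 0.95;
* flare — radial falloff around a random sun center, A = 1.0;
* overexposure — spatially uniform t = 1 - 0.5*intensity, A = 1.0.

Geometry is untouched, so labels transfer unchanged to weathered copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .boxes import LabeledImage

KINDS = ("rain", "fog", "flare", "overexposure", "snow")

# per-kind atmospheric-light sampling ranges
_A_RANGE = {"fog": (0.8, 1.0), "rain": (0.85, 1.0), "snow": (0.9, 1.0), "flare": (1.0, 1.0), "overexposure": (1.0, 1.0)}


@dataclass
class WeatherParams:
    kind: str
    A: float
    t: np.ndarray  # (H, W) in [0, 1]
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.A <= 1.0):
            raise ValueError("atmospheric light A outside [0,1]")
        if self.t.min() < 0 or self.t.max() > 1:
            raise ValueError("transmittance outside [0,1]")


def make_transmittance(kind: str, image_size: tuple[int, int], intensity: float, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Build (t map, A) for one weather kind at the given intensity."""
    if kind not in KINDS:
        raise ValueError(f"unknown weather kind {kind!r}; choose from {KINDS}")
    if not (0.0 <= intensity <= 1.0):
        raise ValueError("intensity must lie in [0,1]")
    H, W = image_size
    A = float(rng.uniform(*_A_RANGE[kind]))
    if intensity == 0.0:
        return np.ones((H, W)), A

    if kind == "fog":
        field = rng.normal(0.0, 1.0, (H, W))
        field = gaussian_filter(field, sigma=max(H, W) / 8.0, mode="reflect")
        sd = field.std() or 1.0
        field = (field - field.mean()) / sd  # zero-mean, unit-var smooth field
        t = 1.0 - 0.6 * intensity + 0.08 * intensity * field
        A = float(rng.uniform(0.85, 0.95))  # "near 0.9"
    elif kind == "overexposure":
        t = np.full((H, W), 1.0 - 0.5 * intensity)
    elif kind == "flare":
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        yy, xx = np.mgrid[0:H, 0:W]
        r = np.hypot(yy - cy, xx - cx) / (0.6 * np.hypot(H, W))
        t = 1.0 - 0.85 * intensity * np.exp(-(r**2) / 0.08)
    else:  # rain / snow particle masks
        t = np.ones((H, W))
        drop = 0.75 * intensity
        n = int(20 + 180 * intensity)
        for _ in range(n):
            y0, x0 = rng.uniform(0, H), rng.uniform(0, W)
            if kind == "rain":  # elongated angled streak
                length = rng.uniform(0.05, 0.15) * H
                angle = rng.uniform(np.deg2rad(60), np.deg2rad(120))
                steps = max(int(length), 2)
                ys = (y0 + np.sin(angle) * np.linspace(0, length, steps)).astype(int)
                xs = (x0 + np.cos(angle) * np.linspace(0, length, steps)).astype(int)
                ok = (ys >= 0) & (ys < H) & (xs >= 0) & (xs < W)
                t[ys[ok], xs[ok]] = 1.0 - drop
            else:  # round flake
                rad = rng.uniform(1.0, 2.5)
                yy, xx = np.mgrid[max(0, int(y0 - 3)) : min(H, int(y0 + 4)), max(0, int(x0 - 3)) : min(W, int(x0 + 4))]
                m = (yy - y0) ** 2 + (xx - x0) ** 2 <= rad**2
                t[yy[m], xx[m]] = 1.0 - drop
        t = gaussian_filter(t, sigma=0.6)
    return np.clip(t, 0.0, 1.0), A


def blend(J: np.ndarray, t: np.ndarray, A: float) -> np.ndarray:
    """Atmospheric blending I = J*t + A*(1-t) on [0,1] images."""
    J = np.asarray(J, dtype=np.float64)
    if J.ndim == 3:
        if t.shape != J.shape[:2]:
            raise ValueError(f"shape mismatch: J {J.shape[:2]} vs t {t.shape}")
        t = t[..., None]
    elif t.shape != J.shape:
        raise ValueError(f"shape mismatch: J {J.shape} vs t {t.shape}")
    if J.min() < 0 or J.max() > 1:
        raise ValueError("J must be normalized to [0,1]")
    if not (0.0 <= A <= 1.0):
        raise ValueError("A outside [0,1]")
    return J * t + A * (1.0 - t)


def apply_weather(img: LabeledImage, kind: str, intensity: float, rng: np.random.Generator) -> LabeledImage:
    """Weathered copy of a labeled image; boxes are carried over as-is."""
    t, A = make_transmittance(kind, (img.height, img.width), intensity, rng)
    J = img.pixels.astype(np.float64) / 255.0
    I = blend(J, t, A)
    return LabeledImage((I * 255).round().astype(np.uint8), list(img.boxes), f"{img.source_id}+{kind}")


def weatherize_split(
    images: list[LabeledImage],
    fraction: float = 0.5,
    kinds: tuple[str, ...] = KINDS,
    rng: np.random.Generator | None = None,
    intensity_range: tuple[float, float] = (0.3, 0.8),
    mode: str = "extend",
) -> list[LabeledImage]:
    """Weather a seeded random subset of round(fraction*N) images.

    ``mode='extend'`` (default) appends the weathered copies to the input
    set; ``mode='replace'`` substitutes them in place.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0,1]")
    if not kinds:
        raise ValueError("kinds list is empty")
    for k in kinds:
        if k not in KINDS:
            raise ValueError(f"unknown weather kind {k!r}")
    rng = rng or np.random.default_rng(0)
    n = int(round(fraction * len(images)))
    picks = rng.choice(len(images), size=n, replace=False) if n else np.array([], dtype=int)
    out = list(images)
    for i in picks:
        kind = kinds[int(rng.integers(0, len(kinds)))]
        intensity = float(rng.uniform(*intensity_range))
        weathered = apply_weather(images[int(i)], kind, intensity, rng)
        if mode == "replace":
            out[int(i)] = weathered
        else:
            out.append(weathered)
    return out
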