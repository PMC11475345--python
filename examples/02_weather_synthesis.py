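"""Weather-synthesis augmentation: I(x) = J(x) t(x) + A (1 - t(x)).

Builds each weather kind's transmittance map at moderate intensity and
blends it into a synthetic scene; the output stays a per-pixel convex
combination of the clean image and the atmospheric light A, so labels
carry over unchanged.
"""

import numpy as np

from cattledet import generate_synthetic_scene
from cattledet.weather import KINDS, apply_weather, make_transmittance

rng = np.random.default_rng(0)
scene = generate_synthetic_scene(rng, 2, 0.3, (96, 96))

print("kind          mean t   A      mean |I-J| (8-bit)")
for kind in KINDS:
    t, A = make_transmittance(kind, (96, 96), intensity=0.6, rng=np.random.default_rng(1))
    out = apply_weather(scene, kind, 0.6, np.random.default_rng(1))
    delta = np.abs(out.pixels.astype(int) - scene.pixels.astype(int)).mean()
    print(f"{kind:12s}  {t.mean():.3f}   {A:.2f}   {delta:6.1f}")
    assert out.boxes == scene.boxes  # photometric only

# fog at full intensity is calibrated to mean transmittance 0.4
t, _ = make_transmittance("fog", (96, 96), 1.0, np.random.default_rng(2))
print(f"fog @ intensity 1.0: mean t = {t.mean():.3f} (rule: 1 - 0.6*intensity = 0.4)")
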