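"""Generate labeled synthetic pasture scenes and inspect their annotations.

Each scene contains textured animal blobs with behavior-specific
silhouettes (standing/walking/eating/lying) and tight YOLO-format boxes;
occluded pairs overlap by at least 30% of the smaller box.
"""

import numpy as np

from cattledet import CLASS_NAMES, generate_synthetic_scene
from cattledet.losses import iou

rng = np.random.default_rng(0)
scene = generate_synthetic_scene(rng, n_instances=3, occlusion_prob=1.0, image_size=(160, 160))

print(f"scene: {scene.width}x{scene.height}, {len(scene.boxes)} animals")
for b in scene.boxes:
    x1, y1, x2, y2 = b.to_xyxy(scene.width, scene.height)
    print(f"  {CLASS_NAMES[b.cls]:9s} box=({x1:5.1f},{y1:5.1f})-({x2:5.1f},{y2:5.1f})")

a, b = scene.boxes[0].to_xyxy(160, 160), scene.boxes[1].to_xyxy(160, 160)
print(f"IoU of the first occluded pair: {iou(a, b):.3f}")
# boxes are tight on the rendered silhouettes and always inside the frame
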