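# Methods

This note records how the detector is built, which choices were open and
how they were fixed, what the synthetic data does and does not emulate,
and the numerical conventions used throughout.

## Architecture and calibration

The published description of this detector fixes the module *types* —
star-operation backbone blocks (expansion 4, depthwise 7×7, ordinary 3×3
stride-2 convs, width doubling per stage), SPPF with large-separable-
kernel attention, the focused-pyramid neck, the GN-based shared head —
but leaves the concrete widths and depths open. What it does publish are
structural budgets: 1.40×10⁶ total parameters and 5.2 GFLOPs for the full
model, 1.12×10⁵ parameters for the head, 3.00–3.01×10⁶ / 7.52×10⁵ for the
YOLOv8n baseline and its decoupled head. We therefore treat width/depth
selection as an explicit calibration step with the budget checks as its
oracle. The calibrated defaults are:

| knob | value | note |
|---|---|---|
| StarNet `base_width` | 20 | stage widths 20/40/80/160 |
| StarNet `depths` | (2, 1, 1, 2) | blocks per stage |
| LSKA `k, d` | 11, 3 | 1-D kernels 5 and 3 (dilated ×3), support = 11 |
| MCFP `neck_width` | 76 | common channel count at all three scales |
| LMFD `hidden`, `gn_groups` | 96, 16 | bias-free convs before GN |
| `reg_max` | 16 | distribution-focal bins, YOLOv8 convention |
| Inner ratio | 0.7 | auxiliary-box scale, valid range [0.5, 1.5] |

With these defaults the builders produce 1,395,863 total parameters
(929,260 backbone / 173,600 SPPF-LSKA / 180,804 neck / 112,199 head),
5.19 GFLOPs at 640², and the baseline numbers above — each locked by a
test, so a config drift that silently breaks a budget fails fast.
Closed-form parameter formulas (`star_block_param_count`,
`lska_param_count`, `lmfd_param_count`, `adown_param_count`) audit the
framework counts symbolically.

Design points that the source description leaves genuinely open, and how
we fixed them:

- **LSKA kernel split.** The dilated 1-D kernel is ⌊k/d⌋ rounded down to
  odd (k=11, d=3 → kernels 5 and 3), which keeps all kernels odd and
  makes the cascade's receptive field exactly k; a ceiling split would
  produce an even kernel and overshoot the target support.
- **SPPF pools.** The verbal description mentions two serial max-pools;
  standard SPPF uses three, and the layer is presented as an SPPF
  modification, so three is the default with `n_pools=2` available.
- **MCFP wiring.** The exact graph of the fusion/diffusion figures is not
  fully recoverable; our committed reading (top-down refine, stride-16
  fusion with ADown/up-sampling, inception context, level-specific 1×1
  diffusion projections) lives in one place (`MCFP.forward`) so
  alternates are swappable. Diffusion uses level-specific projections
  rather than one shared map.
- **Head sharing.** The 3×3 Conv+GN and both prediction layers are shared
  across levels; the per-level Scale (init 1.0, regression branch only)
  absorbs level differences, FCOS-style.
- **MPDIoU normalization.** The corner distances are normalized by the
  input-frame diagonal `w² + h²` (the original MPDIoU convention);
  `mpd_norm="gtbox"` exposes the alternative reading that normalizes by
  the ground-truth box diagonal.
- **Inner scaling scope.** Only the overlap term switches to the
  ratio-scaled auxiliary boxes; corner distances and the
  distribution-focal term stay on the original boxes.
- **Criterion gains.** λ_box=7.5, λ_cls=0.5, λ_dfl=1.5 with a
  task-aligned assigner (top-k 10, α=0.5, β=6) — the YOLOv8 defaults,
  which the description inherits implicitly.

## FLOP conventions

Two conventions coexist because a single-MAC per-layer count cannot
reproduce published YOLO model-card figures:

- `per_layer`: Σ over convolutions of `Cin/g·Cout·Kh·Kw·Hout·Wout +
  Cout·Hout·Wout` (MACs once, plus one add per output element for the
  bias / folded normalization).
- `table` (default for reporting): `2 × Σ MACs`, convolutions only — the
  convention under which the stock 80-class YOLOv8n measures 8.74 G at
  640², matching its published 8.7 G. A faithful 4-class baseline
  measures 8.08 G under the same convention (the classification tower
  shrinks with the class count); swapping its decoupled head for the
  lightweight shared head brings it to 6.76 G.

FLOPs are measured by running the real forward graph in a trace mode that
records MAC counts from propagated shapes while skipping the arithmetic,
so there is one source of truth for shapes and no separate shape
calculator to drift.

## Training

Defaults follow the study protocol: SGD, lr₀ 0.01, momentum 0.937, weight
decay 5·10⁻⁴ (convolution weights only), batch 32 at 640². The schedule —
not published — is a 3-epoch linear warmup then linear decay to 0.01·lr₀;
the epoch default is 300 for full runs. Weather augmentation is applied
offline to a seeded 50% subset of the training split, with weathered
copies *added* to the set; the five standard transforms (crop, HSV
jitter, Gaussian noise, horizontal flip, scale) run online. Magnitudes
not published: HSV fractions 0.015/0.7/0.4, noise σ ≤ 0.05 of dynamic
range, crop ≥ 0.6 of each side with `min_visibility` 0.2 for surviving
boxes. Mosaic is deliberately absent (only the five transforms are
specified). Everything is seeded: init, data order, augmentation; two
runs with one seed reproduce per-epoch losses bit-for-bit.

The **smoke preset** (`smoke_dataset` / `smoke_train_config`) is the
desk-scale capacity check: 8 single-animal 64² scenes, batch 4, no
augmentation, 150 epochs (~40 s on one CPU) to train-set mAP@0.5 ≥ 0.9.
The fixture uses subjects filling 55–80% of the frame deliberately: a
freshly initialized distribution-focal head predicts boxes near half its
range (expectation ≈ 7.5 bins), so tiny objects give the task-aligned
assigner near-zero initial overlap and the classifier can collapse to
"all background" before the box branch catches up. Large subjects give a
usable overlap signal from the first step; this is a property of
overfit-scale training, not of the full-scale protocol.

## Synthetic scenes

The generator emulates what matters to the pipeline: multi-instance
scenes, four behavior classes with distinct silhouettes (standing/walking
with legs, eating with a lowered head, lying as a low ellipse), textured
coats on textured backgrounds, tight boxes, and constructive partial
occlusion (consecutive blobs overlap ≥ 30% of the smaller box on
demand). It does **not** emulate perspective, articulated pose, herd
density gradients, motion blur, or real coat patterns — so green tests
demonstrate that the code implements the method correctly, not that the
trained detector's accuracy transfers to real cattle imagery. The
published headline accuracy (mAP 90.2% on the study's partly private
cattle dataset, GPU-trained) is out of desk scope by design; what is
reproduced are the structural budgets and the method's behavioral
properties.

## Numerical notes

- IoU family on continuous coordinates; zero-area boxes return IoU 0 with
  a warning. `ratio = 1` short-circuits the inner transform so the
  reduction to MPDIoU is bitwise exact.
- CIoU's aspect weight α is treated as a constant in the backward pass
  (standard practice); gradient tests freeze it accordingly.
- AP uses all-point interpolation (precision envelope); classes with
  neither ground truth nor detections are excluded from mAP. The single
  operating point for P/R is the F1-maximizing confidence, since the
  source does not state one.
- Dataset splits: rounded fractions with the remainder absorbed by the
  training split (5051 items at 8:1:1 → 4041/505/505); the published
  3805/621/625 table reflects a grouping constraint on recording
  environments that is not reproducible from counts alone, so splitting
  is i.i.d. here.
- BatchNorm eps 1e-3 / momentum 0.03 (YOLO convention); GN eps 1e-5;
  classification bias init −4.59 (prior probability ≈ 0.01).
- The engine is float32 in training; float64 paths exist for the
  finite-difference test harness.

## Known limitations

Single-process CPU execution only (no GPU, no multi-worker loading, no
EMA or mixed precision); NMS and assignment are O(n²) per image, fine at
desk scale; the weather model is photometric (no depth-dependent
transmittance — no depth maps exist for this data); video decoding and
frame extraction are out of scope (fixtures are images).
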