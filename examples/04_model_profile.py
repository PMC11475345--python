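"""Parameter and FLOP accounting of the assembled detectors.

Profiles the lightweight cattle detector and the YOLOv8n baseline at
640x640 under the 2-ops-per-multiply-accumulate convention used by YOLO
model cards, plus the per-layer convention
Cin*Cout*Kh*Kw*Hout*Wout + Cout*Hout*Wout (MACs counted once, bias adds
included).
"""

from cattledet import build_model, build_yolov8n_baseline, param_flop_report

for name, model in (
    ("cattle detector (StarNet + SPPF-LSKA + MCFP + LMFD)", build_model()),
    ("YOLOv8n baseline, 4 classes", build_yolov8n_baseline(4)),
):
    rep = param_flop_report(model, img_size=640)
    print(f"\n{name}")
    print(f"  total parameters: {rep.total_params:,}")
    for mod, n in rep.per_module.items():
        print(f"    {mod:9s} {n:9,}  ({100 * n / rep.total_params:4.1f}%)")
    print(f"  FLOPs @640 (2xMAC):     {rep.gflops('table'):.2f} G")
    print(f"  FLOPs @640 (per-layer): {rep.gflops('per_layer'):.2f} G")
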