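"""Detector training: SGD with warmup + linear decay, Inner-MPDIoU box
regression, seeded end-to-end (init, data order, augmentation).

Defaults follow the study protocol: SGD, initial learning rate 0.01,
momentum 0.937, weight decay 0.0005, batch size 32 at 640 px.  The
``smoke`` preset scales the same graph down to a handful of small
synthetic scenes so an overfit sanity run completes in minutes on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .assembly import Detector, ModelConfig, build_model
from .boxes import LabeledImage
from .data_io import AugmentConfig, augment, resize_labeled
from .losses import LossConfig, detection_loss
from .metrics import evaluate
from .nn import SGD
from .nn.autograd import Tensor


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    lr0: float = 0.01
    lrf: float = 0.01  # final lr = lrf * lr0
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch: int = 32
    workers: int = 12  # dataloader parallelism hint (single-process here)
    img_size: int = 640
    epochs: int = 300
    warmup_epochs: int = 3
    optimizer: str = "sgd"
    loss: str = "inner_mpdiou"
    seed: int = 0
    augment: bool = True
    val_every: int = 10

    def __post_init__(self):
        for name in ("lr0", "momentum", "weight_decay", "batch", "img_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Linear warmup over ``warmup_epochs`` then linear decay to lrf*lr0."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    w = cfg.warmup_epochs
    if w > 0 and epoch < w:
        return cfg.lr0 * (0.1 + 0.9 * epoch / w)
    span = max(cfg.epochs - 1 - w, 1)
    frac = min((epoch - w) / span, 1.0)
    return cfg.lr0 * (1.0 - frac * (1.0 - cfg.lrf))


def _batch_tensor(images: list[LabeledImage]) -> Tensor:
    x = np.stack([im.pixels for im in images]).astype(np.float32).transpose(0, 3, 1, 2) / 255.0
    return Tensor(x)


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    dataset: list[LabeledImage],
    val_dataset: list[LabeledImage] | None = None,
    checkpoint_path: str | Path | None = None,
    model: Detector | None = None,
    log_fn=print,
) -> tuple[Detector, list[dict]]:
    """Train a detector; returns (model-with-best-weights, per-epoch log)."""
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(train_cfg.seed)
    model = model or build_model(model_cfg)
    loss_cfg = LossConfig(kind=train_cfg.loss, inner_ratio=model_cfg.inner_ratio, mpd_norm=model_cfg.mpd_norm)
    decay = [p for name, p in model.named_parameters() if name.endswith("weight")]
    opt = SGD(model.parameters(), lr=train_cfg.lr0, momentum=train_cfg.momentum, weight_decay=train_cfg.weight_decay, decay_params=decay)
    aug_cfg = AugmentConfig()
    img_size = (dataset[0].height, dataset[0].width)

    log: list[dict] = []
    best = {"map50": -1.0, "state": None, "epoch": -1}
    last_good = model.state_dict()
    for epoch in range(train_cfg.epochs):
        model.train()
        opt.lr = lr_schedule(epoch, train_cfg)
        order = rng.permutation(len(dataset))
        comps_sum = {"box": 0.0, "cls": 0.0, "dfl": 0.0}
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch):
            idx = order[start : start + train_cfg.batch]
            imgs = [dataset[i] for i in idx]
            if train_cfg.augment:
                imgs = [resize_labeled(augment(im, rng, aug_cfg), img_size) for im in imgs]
            x = _batch_tensor(imgs)
            raw = model(x)
            try:
                loss, comps = detection_loss(raw, [im.boxes for im in imgs], img_size, loss_cfg)
            except FloatingPointError as e:
                if checkpoint_path:
                    _save_checkpoint(last_good, model_cfg, train_cfg, epoch, checkpoint_path)
                raise TrainingError(f"aborting at epoch {epoch}: {e}") from e
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k in comps_sum:
                comps_sum[k] += comps[k]
            n_batches += 1
        entry = {"epoch": epoch, "lr": opt.lr, **{k: v / n_batches for k, v in comps_sum.items()}}
        entry["loss"] = entry["box"] * loss_cfg.lambda_box + entry["cls"] * loss_cfg.lambda_cls + entry["dfl"] * loss_cfg.lambda_dfl
        last_good = model.state_dict()
        if val_dataset and ((epoch + 1) % train_cfg.val_every == 0 or epoch == train_cfg.epochs - 1):
            rep = evaluate(model, val_dataset)
            entry["val_map50"] = rep.map50
            if rep.map50 > best["map50"]:
                best = {"map50": rep.map50, "state": model.state_dict(), "epoch": epoch}
        log.append(entry)
        if log_fn:
            msg = f"epoch {epoch:3d} lr {entry['lr']:.5f} box {entry['box']:.4f} cls {entry['cls']:.4f} dfl {entry['dfl']:.4f}"
            if "val_map50" in entry:
                msg += f" val_mAP50 {entry['val_map50']:.3f}"
            log_fn(msg)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    if checkpoint_path:
        _save_checkpoint(model.state_dict(), model_cfg, train_cfg, train_cfg.epochs - 1, checkpoint_path)
    return model, log


def smoke_dataset(seed: int = 0, n: int = 8, image_size: tuple[int, int] = (64, 64)) -> list[LabeledImage]:
    """Tiny overfit fixture: one large animal per small scene.

    Object scale matters here: a freshly initialized head predicts boxes of
    roughly half the distribution-regression range, so the fixture uses
    subjects filling most of the frame to give the assigner a usable
    overlap signal from step one.
    """
    from .synthetic import generate_synthetic_scene

    rng = np.random.default_rng(seed)
    return [generate_synthetic_scene(rng, 1, 0.0, image_size, f"smoke{i}", size_range=(0.55, 0.8)) for i in range(n)]


def smoke_train_config(seed: int = 0, epochs: int = 150) -> TrainConfig:
    """Desk-scale preset: 8 small scenes, batch 4, no augmentation."""
    return TrainConfig(batch=4, img_size=64, epochs=epochs, augment=False, val_every=10_000, seed=seed)


def _save_checkpoint(state: dict, model_cfg: ModelConfig, train_cfg: TrainConfig, epoch: int, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **{f"w/{k}": v for k, v in state.items()})
    meta = {"epoch": epoch, "train": asdict(train_cfg), "model": {
        "backbone": model_cfg.backbone, "n_classes": model_cfg.n_classes,
        "use_lska": model_cfg.use_lska, "use_mcfp": model_cfg.use_mcfp,
        "use_lmfd": model_cfg.use_lmfd, "loss": model_cfg.loss, "seed": model_cfg.seed}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(model: Detector, path) -> Detector:
    data = np.load(Path(path), allow_pickle=False)
    model.load_state_dict({k[2:]: data[k] for k in data.files if k.startswith("w/")})
    return model
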