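"""Training recipe: SGD with momentum, per-epoch validation mAP50, early
stopping on a patience counter, seeded reproducibility, and run logging.

Defaults mirror the study protocol: 640x640 inputs, 200 epochs, batch size
8, SGD with initial learning rate 0.001, momentum 0.937, weight decay
0.0005, early-stop patience 50 epochs, random seed 0.  The learning rate is
constant by default (only the initial rate is part of the protocol); a
cosine decay can be switched on.  The monitored quantity is validation
mAP50 and the best checkpoint is kept.
"""
from __future__ import annotations

import csv
import math
import os
from dataclasses import asdict, dataclass

import numpy as np

from .data import BoxLabel, read_yolo_labels
from .head import assign_and_loss, decode
from .metrics import detections_to_gts, map50, map50_95, class_ap_table, \
    match_detections, precision_recall, ConfusionCounts
from .model import Detector, ModelConfig, preprocess
from .nn import SGD, Adam


@dataclass
class TrainConfig:
    image_size: int = 640
    epochs: int = 200
    batch_size: int = 8
    seed: int = 0
    lr: float = 0.001
    momentum: float = 0.937
    weight_decay: float = 0.0005
    patience: int = 50
    model: str = "alpd-net"
    lr_schedule: str = "constant"        # constant | cosine
    clip_norm: float = 10.0              # global gradient-norm ceiling
    conf_thresh: float = 0.25
    nms_iou: float = 0.5

    def validate(self):
        for name in ("image_size", "epochs", "batch_size", "lr", "momentum",
                     "weight_decay", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        return self


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -math.inf
        self.bad_epochs = 0
        self.improved = False

    def update(self, metric: float) -> bool:
        """Record an epoch metric; returns True when training should stop."""
        self.improved = metric > self.best
        if self.improved:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def records_from_manifest(manifest_path: str) -> list[tuple[str, str]]:
    pairs = []
    with open(manifest_path) as f:
        for line in f:
            if line.strip():
                ip, lp = line.rstrip("\n").split("\t")
                pairs.append((ip, lp))
    return pairs


def load_samples(pairs: list[tuple[str, str]]) -> list[tuple[np.ndarray, list[BoxLabel]]]:
    from PIL import Image
    out = []
    for ip, lp in pairs:
        img = np.asarray(Image.open(ip).convert("RGB"))
        out.append((img, read_yolo_labels(lp)))
    return out


def evaluate(model: Detector, samples, cfg: TrainConfig, conf_thresh: float | None = None):
    """P / R / mAP50 / mAP50-95 of a model over in-memory samples.

    Same-sized images are forwarded in batches (eval mode, so batching does
    not change the outputs).
    """
    model.eval()
    ct = conf_thresh if conf_thresh is not None else cfg.conf_thresh
    dets_all, gts_all = [], []
    i = 0
    while i < len(samples):
        j = i + 1
        shape = samples[i][0].shape
        while j < len(samples) and j - i < cfg.batch_size and samples[j][0].shape == shape:
            j += 1
        batch = samples[i:j]
        raw = model(preprocess(np.stack([img for img, _ in batch])))
        for bi, (img, labels) in enumerate(batch):
            dets = decode([(b.data[bi], c.data[bi]) for b, c in raw],
                          conf_thresh=ct, nms_iou=cfg.nms_iou, image_size=img.shape[:2])
            dets_all.append(dets)
            gts_all.append(detections_to_gts(labels, img.shape[:2]))
        i = j
    total = ConfusionCounts()
    for dets, gts in zip(dets_all, gts_all):
        for c in match_detections(dets, gts, 0.5).values():
            total = total + c
    p, r = precision_recall(total)
    return {"P": p, "R": r, "mAP50": map50(dets_all, gts_all),
            "mAP50-95": map50_95(dets_all, gts_all)}


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def train_epoch(model, samples, optimizer, cfg, rng):
    """One full pass; returns mean loss components."""
    model.train()
    sums = {"loss": 0.0, "cls": 0.0, "box": 0.0}
    n_batches = 0
    for batch in _batches(len(samples), cfg.batch_size, rng):
        imgs = np.stack([samples[i][0] for i in batch])
        targets = [samples[i][1] for i in batch]
        raw = model(preprocess(imgs))
        loss, comps = assign_and_loss(raw, targets, image_size=cfg.image_size)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite loss at batch {n_batches}: {comps}")
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        sums["loss"] += float(loss.data)
        sums["cls"] += comps["cls"]
        sums["box"] += comps["box"]
        n_batches += 1
    if n_batches == 0:
        raise RuntimeError("empty training loader")
    return {k: v / n_batches for k, v in sums.items()}


def train(cfg: TrainConfig, train_samples, val_samples, out_dir: str) -> dict:
    """Full training run; returns summary with best metrics and paths."""
    cfg.validate()
    if not train_samples or not val_samples:
        raise ValueError("train/val sample lists must be non-empty")
    os.makedirs(out_dir, exist_ok=True)
    _stamp_run(cfg, out_dir)
    model = Detector(ModelConfig.from_preset(cfg.model, init_seed=cfg.seed))
    optimizer = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                    weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm)
    stopper = EarlyStopper(cfg.patience)
    rng = np.random.default_rng(cfg.seed)
    log_path = os.path.join(out_dir, "metrics.csv")
    best_path = os.path.join(out_dir, "best")
    history = []
    with open(log_path, "w", newline="") as f:
        wr = csv.writer(f)
        wr.writerow(["epoch", "lr", "loss", "cls", "box", "P", "R", "mAP50", "mAP50-95"])
        for epoch in range(1, cfg.epochs + 1):
            if cfg.lr_schedule == "cosine":
                optimizer.lr = cfg.lr * 0.5 * (1 + math.cos(math.pi * (epoch - 1) / cfg.epochs))
            stats = train_epoch(model, train_samples, optimizer, cfg, rng)
            val = evaluate(model, val_samples, cfg)
            row = [epoch, optimizer.lr, stats["loss"], stats["cls"], stats["box"],
                   val["P"], val["R"], val["mAP50"], val["mAP50-95"]]
            wr.writerow([f"{v:.6g}" if isinstance(v, float) else v for v in row])
            f.flush()
            history.append({"epoch": epoch, **stats, **val})
            stop = stopper.update(val["mAP50"])
            if stopper.improved:
                model.save(best_path)
            if stop:
                break
    model.save(os.path.join(out_dir, "last"))
    return {"best_mAP50": stopper.best, "epochs_run": len(history),
            "history": history, "best_checkpoint": best_path + ".npz",
            "log": log_path}


def _stamp_run(cfg, out_dir):
    import sys
    with open(os.path.join(out_dir, "run_config.txt"), "w") as f:
        for k, v in asdict(cfg).items():
            f.write(f"{k}: {v}\n")
        f.write(f"python: {sys.version.split()[0]}\n")
        f.write(f"numpy: {np.__version__}\n")


def smoke_overfit(n_images: int = 20, size: int = 256, max_steps: int = 1500,
                  target_map50: float = 0.9, seed: int = 0, batch_size: int = 8,
                  lr: float = 2e-3, eval_every: int = 25, model: str = "alpd-net",
                  optimizer: str = "adam", verbose: bool = False) -> dict:
    """Capability check: overfit a handful of easy synthetic scenes.

    Trains the full detector (all modules on by default) on ``n_images``
    easy scenes — large plants, no occlusion — at a reduced input size until
    the train-set mAP50 reaches ``target_map50`` or ``max_steps`` is hit.
    Returns the achieved mAP50, the step count, and the loss trace.
    """
    from .scenes import SceneSpec, generate_scene
    spec = SceneSpec(image_size=size, plants_per_image=(1, 2),
                     plant_radius=(int(size * 0.22), int(size * 0.36)),
                     weed_density=4, occlusion_prob=0.0, seed=seed)
    samples = [(s.image, s.labels) for s in (generate_scene(spec, i) for i in range(n_images))]
    cfg = TrainConfig(image_size=size, batch_size=batch_size, seed=seed, lr=lr,
                      model=model).validate()
    mdl = Detector(ModelConfig.from_preset(model, init_seed=seed))
    if optimizer == "adam":
        opt = Adam(mdl.parameters(), lr=lr, clip_norm=10.0)
    else:
        opt = SGD(mdl.parameters(), lr=lr, momentum=0.9, weight_decay=0.0, clip_norm=10.0)
    rng = np.random.default_rng(seed)
    losses = []
    step = 0
    achieved = 0.0
    while step < max_steps:
        for batch in _batches(len(samples), batch_size, rng):
            mdl.train()
            imgs = np.stack([samples[i][0] for i in batch])
            targets = [samples[i][1] for i in batch]
            raw = mdl(preprocess(imgs))
            loss, _ = assign_and_loss(raw, targets, image_size=size)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
            if step % eval_every == 0 or step >= max_steps:
                achieved = evaluate(mdl, samples, cfg, conf_thresh=0.25)["mAP50"]
                if verbose:
                    print(f"step {step}: loss {losses[-1]:.3f} train mAP50 {achieved:.3f}")
                if achieved >= target_map50 or step >= max_steps:
                    return {"map50": achieved, "steps": step, "losses": losses,
                            "reached": achieved >= target_map50, "model": mdl}
    achieved = evaluate(mdl, samples, cfg)["mAP50"]
    return {"map50": achieved, "steps": step, "losses": losses,
            "reached": achieved >= target_map50, "model": mdl}
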