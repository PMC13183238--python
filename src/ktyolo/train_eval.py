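"""Training loop, stratified evaluation and ablation runners.

The optimizer protocol is SGD with momentum 0.937, weight decay 0.0005 and
initial learning rate 0.01 at batch size 16, with early stopping on
validation mAP50 (patience 50 within a 500-epoch budget).  The learning
rate decays linearly to 1% of its initial value over the epoch budget.
Augmentation is horizontal flip only, keeping ablation comparisons
interpretable.  One master seed fans out to weight init, data order and
augmentation.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .detector import Detector, dataset_from_scenes
from .evalmetrics import APResult, DetectionRecord, evaluate_detections
from .losses import SlideLossParams
from .netgraph import ModelConfig, build_detector
from .nn import SGD

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "train",
    "evaluate",
    "run_ablation",
    "save_checkpoint",
    "load_checkpoint",
    "load_samples",
    "KERNEL_ABLATION_SETS",
]

KERNEL_ABLATION_SETS = ((1,), (3,), (5,), (7,), (3, 5), (1, 3, 5), (1, 3, 5, 7))


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch_size: int = 16
    max_epochs: int = 500
    early_stop_patience: int = 50
    input_size: int = 640
    seed: int = 0
    cls_loss: str = "bce"  # bce | slide
    slide_mu: object = "auto"  # "auto" | float
    eval_every: int = 1
    hflip: bool = True
    score_thresh: float = 0.01
    nms_iou: float = 0.7

    def __post_init__(self):
        if self.cls_loss not in ("bce", "slide"):
            raise ValueError("cls_loss must be 'bce' or 'slide'")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        for name in ("lr", "momentum", "weight_decay", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainResult:
    detector: Detector
    best_state: list
    best_map50: float
    best_epoch: int
    stopped_epoch: int
    log: list  # per-epoch dicts
    mu_trace: list


@dataclass
class EvalReport:
    overall: APResult
    by_stratum: dict  # tag -> APResult
    mu_trace: list = field(default_factory=list)

    def to_json(self, path):
        def ap_dict(r: APResult):
            return {
                "per_class_ap": {str(k): v for k, v in r.per_class_ap.items()},
                "map50": r.map50,
                "map50_95": r.map50_95,
                "precision": r.precision,
                "recall": r.recall,
                "excluded_classes": r.excluded_classes,
            }

        Path(path).write_text(json.dumps({
            "overall": ap_dict(self.overall),
            "by_stratum": {k: ap_dict(v) for k, v in self.by_stratum.items()},
            "mu_trace": self.mu_trace,
        }, indent=1))


def save_checkpoint(detector: Detector, path) -> None:
    """Serialize weights, batch-norm statistics and the model config (npz)."""
    arrays = {f"p{i}": p.value for i, p in enumerate(detector.parameters())}
    arrays.update({f"b{i}": b for i, b in enumerate(detector.buffers())})
    arrays["_config_json"] = np.frombuffer(
        json.dumps(asdict(detector.config)).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> Detector:
    with np.load(path) as z:
        cfg = ModelConfig.from_dict(json.loads(bytes(z["_config_json"]).decode()))
        detector = Detector(build_detector(cfg), seed=0)
        for i, p in enumerate(detector.parameters()):
            p.value[...] = z[f"p{i}"]
        for i, b in enumerate(detector.buffers()):
            b[...] = z[f"b{i}"]
    return detector


def load_samples(data_dir) -> list:
    """Load a generated dataset directory back into training samples."""
    from PIL import Image

    from .datasets_io import read_yolo_txt

    data_dir = Path(data_dir)
    sizes = json.loads((data_dir / "sizes.json").read_text())
    images = read_yolo_txt(data_dir / "labels", {k: tuple(v) for k, v in sizes.items()})
    samples = []
    for im in images:
        arr = np.asarray(Image.open(data_dir / "images" / f"{im.image_id}.png"))
        samples.append({
            "image": arr.astype(np.float32).transpose(2, 0, 1) / 255.0,
            "boxes": np.array([r.box for r in im.records], dtype=np.float64).reshape(-1, 4),
            "classes": np.array([r.class_id for r in im.records], dtype=np.int64),
            "image_id": im.image_id,
            "capture_tag": im.capture_tag,
            "season_tag": im.season_tag,
        })
    return samples


def _batches(samples, batch_size, rng):
    order = rng.permutation(len(samples))
    for at in range(0, len(order), batch_size):
        yield [samples[i] for i in order[at : at + batch_size]]


def _collate(batch, rng, hflip):
    images, gts = [], []
    for s in batch:
        img = s["image"]
        boxes = s["boxes"].copy()
        if hflip and rng.uniform() < 0.5:
            img = img[:, :, ::-1].copy()
            w = img.shape[2]
            x1 = boxes[:, 0].copy()
            boxes[:, 0] = w - boxes[:, 2]
            boxes[:, 2] = w - x1
        images.append(img)
        gts.append((boxes, s["classes"]))
    return np.stack(images), gts


def _predict_dataset(detector: Detector, samples, score_thresh, nms_iou, batch_size=8):
    dets, gts = [], []
    for at in range(0, len(samples), batch_size):
        chunk = samples[at : at + batch_size]
        images = np.stack([s["image"] for s in chunk])
        ids = [s["image_id"] for s in chunk]
        preds = detector.predict(images, ids, score_thresh=score_thresh, nms_iou=nms_iou)
        for s, p in zip(chunk, preds):
            dets.extend(p)
            for box, cls in zip(s["boxes"], s["classes"]):
                gts.append(DetectionRecord(s["image_id"], int(cls), tuple(box)))
    return dets, gts


def _map50(dets, gts) -> float:
    """mAP at IoU 0.5 only (the quantity tracked for early stopping)."""
    from .evalmetrics import average_precision

    classes = sorted({g.class_id for g in gts})
    aps = []
    for c in classes:
        c_gts = [g for g in gts if g.class_id == c]
        if not c_gts:
            continue
        aps.append(average_precision([d for d in dets if d.class_id == c], c_gts, 0.5))
    return float(np.mean(aps)) if aps else 0.0


def train(config: TrainConfig, train_samples, val_samples) -> TrainResult:
    """Train a detector; returns the best checkpoint and the training log.

    ``train_samples``/``val_samples`` are sample dicts (see
    :func:`ktyolo.detector.dataset_from_scenes`).  Stops after
    ``early_stop_patience`` consecutive epochs without validation-mAP50
    improvement (strict, by at least 1e-6), or at ``max_epochs``.
    """
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    graph = build_detector(config.model)
    detector = Detector(graph, seed=int(rng.integers(0, 2**31 - 1)))
    opt = SGD(detector.parameters(), lr=config.lr, momentum=config.momentum,
              weight_decay=config.weight_decay)

    if config.cls_loss == "slide":
        auto = config.slide_mu == "auto"
        mu0 = 0.5 if auto else float(config.slide_mu)
        slide_params = SlideLossParams(mu=mu0, auto_mu=auto)
    else:
        slide_params = None

    best_map, best_epoch, best_state = -1.0, -1, detector.state()
    log, mu_trace = [], []
    stopped = config.max_epochs
    for epoch in range(1, config.max_epochs + 1):
        opt.lr = config.lr * (1.0 - 0.99 * (epoch - 1) / max(1, config.max_epochs - 1))
        epoch_losses = []
        for batch in _batches(train_samples, config.batch_size, rng):
            images, gts = _collate(batch, rng, config.hflip)
            loss = detector.train_step(images, gts, opt, cls_loss=config.cls_loss,
                                       slide_params=slide_params)
            epoch_losses.append(loss.total)
        # per-epoch mu refresh from the running assigned-IoU mean
        if slide_params is not None and slide_params.auto_mu:
            slide_params.mu = float(np.clip(detector.mu_tracker.mean, 0.0, 1.0))
        mu_trace.append(slide_params.mu if slide_params else None)

        entry = {"epoch": epoch, "loss": float(np.mean(epoch_losses)), "lr": opt.lr,
                 "mu": mu_trace[-1]}
        if epoch % config.eval_every == 0 and val_samples:
            dets, gts_all = _predict_dataset(detector, val_samples,
                                             config.score_thresh, config.nms_iou)
            val_map = _map50(dets, gts_all)
            entry["val_map50"] = val_map
            if val_map > best_map + 1e-6:
                best_map, best_epoch = val_map, epoch
                best_state = detector.state()
            elif epoch - best_epoch >= config.early_stop_patience:
                log.append(entry)
                stopped = epoch
                break
        log.append(entry)
    detector.load_state(best_state)
    return TrainResult(detector, best_state, best_map, best_epoch, stopped, log, mu_trace)


def evaluate(detector: Detector, samples, strata=("day", "night", "summer", "winter"),
             score_thresh: float = 0.01, nms_iou: float = 0.7) -> EvalReport:
    """Evaluate one checkpoint overall and per stratum (no retraining).

    Strata with no images are omitted; classes with zero ground truths in a
    stratum are excluded from that stratum's mean (absent, not zero).
    """
    dets, gts = _predict_dataset(detector, samples, score_thresh, nms_iou)
    nc = detector.num_classes
    overall = evaluate_detections(dets, gts, num_classes=nc)
    by_stratum = {}
    tag_of = {}
    for s in samples:
        tag_of[s["image_id"]] = (s.get("capture_tag", "unknown"), s.get("season_tag", "unknown"))
    for stratum in strata:
        ids = {i for i, tags in tag_of.items() if stratum in tags}
        if not ids:
            continue
        s_dets = [d for d in dets if d.image_id in ids]
        s_gts = [g for g in gts if g.image_id in ids]
        if not s_gts:
            continue
        by_stratum[stratum] = evaluate_detections(s_dets, s_gts, num_classes=nc)
    return EvalReport(overall, by_stratum, mu_trace=[])


def run_ablation(suite: str, base_config: TrainConfig, train_samples, val_samples,
                 seeds=(0,)) -> list:
    """Run a predefined configuration grid; one result row per cell.

    ``kernel_sets`` sweeps the kernel-subset grid over the KTF model;
    ``loss_swap`` crosses {bce, slide} with {baseline c2f, ktf}.  Rows carry
    the mean and per-seed validation mAP50 of the best checkpoint.
    """
    if suite == "kernel_sets":
        cells = [{"kernel_sizes": ks} for ks in KERNEL_ABLATION_SETS]

        def make(cfg, cell):
            cfg.model = ModelConfig(**{**asdict(cfg.model), "fusion": "ktf",
                                       "kernel_sizes": cell["kernel_sizes"]})
            return cfg
    elif suite == "loss_swap":
        cells = [{"fusion": f, "cls_loss": l}
                 for f in ("c2f", "ktf") for l in ("bce", "slide")]

        def make(cfg, cell):
            cfg.model = ModelConfig(**{**asdict(cfg.model), "fusion": cell["fusion"]})
            cfg.cls_loss = cell["cls_loss"]
            return cfg
    else:
        raise ValueError(f"unknown ablation suite {suite!r}")

    rows = []
    for cell in cells:
        scores = []
        for seed in seeds:
            cfg = make(copy.deepcopy(base_config), cell)
            cfg.seed = int(seed)
            result = train(cfg, train_samples, val_samples)
            scores.append(result.best_map50)
        rows.append({**cell, "map50_mean": float(np.mean(scores)),
                     "map50_per_seed": scores})
    return rows
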