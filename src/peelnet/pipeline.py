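"""Training and evaluation pipeline at desk scale.

Training loss is binary cross-entropy on the per-location class logits plus a
weighted box-regression loss (any member of the WIoU/CIoU/DIoU/GIoU/EIoU
family) on positive locations.  Label assignment is dynamic: candidate cells
are those whose center lies inside a ground-truth box (with a nearest-cell
fallback for boxes smaller than every grid cell); each ground truth keeps its
top-k candidates by IoU of the currently decoded boxes (k = 10), and a cell
claimed by several boxes goes to the one it overlaps most.  Classification
targets are quality-aware: a positive cell's target is the IoU of its decoded
box with its ground truth (floored at 0.02) rather than a hard 1, so the
confidence ranking tracks localization quality and NMS keeps the
best-localized candidate.

``TrainConfig`` defaults mirror the published training settings (Adam,
initial learning rate 1e-5, final 1e-4, weight decay 5e-4, batch 16), with a
linear schedule between the two rates.  ``micro_train_config`` is the
small-scale overfitting recipe used by the test harness (see
docs/methods.md for why it uses a larger constant rate).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import nn
from .afpn import level_boxes
from .boxes import iou_matrix
from .data import AnnotatedImage
from .losses import box_loss
from .metrics import MetricReport, evaluate_detections, run_stats
from .model import STRIDES, Detector, ModelConfig, build_model

__all__ = ["TrainConfig", "train", "evaluate", "compare_losses", "ablate",
           "micro_train_config", "detection_loss"]


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    lr_initial: float = 1e-5
    lr_final: float = 1e-4
    weight_decay: float = 5e-4
    box_loss: str = "wiou"
    box_gain: float = 7.5
    assign_topk: int = 10
    seed: int = 0
    image_size: int = 128

    def validate(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch size must be positive")
        if self.lr_initial <= 0 or self.lr_final <= 0:
            raise ValueError("learning rates must be positive")
        return self


def micro_train_config(iterations: int = 300, seed: int = 0,
                       box_loss: str = "wiou") -> TrainConfig:
    """Overfitting recipe for a handful of scenes: batch = dataset, so one
    epoch is one iteration; constant Adam rate 5e-3."""
    return TrainConfig(epochs=iterations, batch_size=8, lr_initial=5e-3,
                       lr_final=5e-3, box_loss=box_loss, seed=seed)


def _grid_geometry(image_size: int):
    """Cell centers (L,2) and strides (L,) for the three prediction levels."""
    centers, strides = [], []
    for s in STRIDES:
        n = image_size // s
        gy, gx = np.mgrid[0:n, 0:n]
        c = np.stack([(gx.ravel() + 0.5) * s, (gy.ravel() + 0.5) * s], axis=1)
        centers.append(c)
        strides.append(np.full(n * n, s, dtype=np.float64))
    return np.concatenate(centers), np.concatenate(strides)


def assign_targets(pred_boxes: np.ndarray, centers: np.ndarray,
                   gts: np.ndarray, topk: int = 10):
    """Dynamic assignment for one image: (cell index, gt index) positives."""
    gts = np.asarray(gts, dtype=np.float64).reshape(-1, 4)
    if len(gts) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cand: dict[int, tuple[int, float]] = {}
    ious = iou_matrix(pred_boxes, gts)          # (L, G)
    for g, gt in enumerate(gts):
        inside = ((centers[:, 0] > gt[0]) & (centers[:, 0] < gt[2])
                  & (centers[:, 1] > gt[1]) & (centers[:, 1] < gt[3]))
        idx = np.where(inside)[0]
        if len(idx) == 0:
            # box smaller than every cell: fall back to the nearest center
            d = np.square(centers - (gt[:2] + gt[2:]) / 2).sum(axis=1)
            idx = np.array([int(np.argmin(d))])
        order = idx[np.argsort(-ious[idx, g], kind="stable")][:topk]
        for cell in order:
            q = float(ious[cell, g])
            if cell not in cand or q > cand[cell][1]:
                cand[int(cell)] = (g, q)
    cells = np.array(sorted(cand), dtype=int)
    return cells, np.array([cand[int(c)][0] for c in cells], dtype=int)


def _flatten_outputs(outputs):
    """Per-level (cls, reg) -> flattened (N,nc,L) and (N,4,L) Tensors."""
    cls = ad.concat([c.reshape(c.shape[0], c.shape[1], -1) for c, _ in outputs], axis=2)
    reg = ad.concat([r.reshape(r.shape[0], 4, -1) for _, r in outputs], axis=2)
    return cls, reg


def _decoded_boxes(reg, centers, strides):
    """(N,4,L) regression Tensor -> (N,L,4) corner-box Tensor."""
    d = ad.softplus(reg) * strides[None, None, :]
    x1 = centers[None, :, 0] - d[:, 0, :]
    y1 = centers[None, :, 1] - d[:, 1, :]
    x2 = centers[None, :, 0] + d[:, 2, :]
    y2 = centers[None, :, 1] + d[:, 3, :]
    return ad.stack([x1, y1, x2, y2], axis=2)


def detection_loss(outputs, gts_batch, classes_batch, cfg: TrainConfig):
    """Total loss Tensor plus scalar components for one forward pass."""
    cls, reg = _flatten_outputs(outputs)
    n, nc, L = cls.shape
    centers, strides = _grid_geometry(cfg.image_size)
    boxes_t = _decoded_boxes(reg, centers, strides)

    targets = np.zeros((n, nc, L))
    img_idx, cell_idx, gt_boxes = [], [], []
    for i in range(n):
        cells, gids = assign_targets(boxes_t.data[i], centers,
                                     gts_batch[i], cfg.assign_topk)
        if not len(cells):
            continue
        gt_arr = np.asarray(gts_batch[i], dtype=np.float64).reshape(-1, 4)
        quality = iou_matrix(boxes_t.data[i][cells], gt_arr)[
            np.arange(len(cells)), gids]
        for cell, g, q in zip(cells, gids, quality):
            targets[i, int(classes_batch[i][g]), cell] = max(float(q), 0.02)
            img_idx.append(i)
            cell_idx.append(cell)
            gt_boxes.append(gt_arr[g])

    npos = max(len(img_idx), 1)
    t = ad.Tensor(targets)
    bce = t * ad.softplus(-cls) + (1.0 - t) * ad.softplus(cls)
    cls_loss = bce.sum() * (1.0 / npos)

    if img_idx:
        pb = boxes_t[np.asarray(img_idx), np.asarray(cell_idx)]     # (P,4)
        bl = box_loss(pb, np.stack(gt_boxes), cfg.box_loss).mean()
    else:
        bl = ad.Tensor(0.0)
    total = cls_loss + cfg.box_gain * bl
    return total, {"loss": total.item(), "cls": cls_loss.item(), "box": bl.item()}


def _to_arrays(dataset):
    images = np.stack([s.image.transpose(2, 0, 1) for s in dataset])
    gts = [s.boxes for s in dataset]
    classes = [s.classes for s in dataset]
    return images, gts, classes


def train(cfg: TrainConfig, dataset, model_cfg: ModelConfig | None = None,
          model: Detector | None = None):
    """Train a detector on a list of :class:`AnnotatedImage`.

    Returns ``(model, history)`` with one history record per iteration.
    """
    cfg.validate()
    if not dataset:
        raise ValueError("empty dataset")
    if model is None:
        model_cfg = model_cfg or ModelConfig(image_size=cfg.image_size)
        model = build_model(model_cfg, seed=cfg.seed)
    model.train()
    images, gts, classes = _to_arrays(dataset)
    m = len(dataset)
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = math.ceil(m / cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    opt = nn.Adam(model.parameters(), lr=cfg.lr_initial,
                  weight_decay=cfg.weight_decay)
    history = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(m)
        for b in range(steps_per_epoch):
            sel = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            frac = step / max(total_steps - 1, 1)
            opt.lr = cfg.lr_initial + frac * (cfg.lr_final - cfg.lr_initial)
            outputs = model.forward(images[sel])
            loss, parts = detection_loss(outputs, [gts[i] for i in sel],
                                         [classes[i] for i in sel], cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            parts.update(epoch=epoch, step=step, lr=opt.lr)
            history.append(parts)
            step += 1
    return model, history


def evaluate(model: Detector, dataset, conf_thr: float = 0.05,
             nms_iou: float = 0.45, runs: int = 1) -> MetricReport:
    """Evaluate a trained model; with runs > 1, attach SD / 95% CI of mAP@0.5."""
    images, gts, _ = _to_arrays(dataset)
    values = []
    report = None
    for _ in range(max(runs, 1)):
        dets = model.predict(images, conf_thr, nms_iou)
        report = evaluate_detections(dets, gts)
        values.append(report.map50)
    if runs > 1:
        rs = run_stats(values)
        report.sd = rs.sd
        report.ci_half_width = rs.ci_half_width
    return report


def compare_losses(cfg: TrainConfig, dataset, kinds,
                   model_cfg: ModelConfig | None = None):
    """Train/evaluate one model per box-loss kind; returns (table, histories)."""
    rows, histories = [], {}
    for kind in kinds:
        run_cfg = dataclasses.replace(cfg, box_loss=kind)
        model, hist = train(run_cfg, dataset, model_cfg)
        report = evaluate(model, dataset)
        histories[kind] = hist
        rows.append({
            "Bounding box regression loss": kind,
            "mAP@0.5 (%)": report.map50,
            "mAP@0.5:0.95 (%)": report.map50_95,
            "Final training loss": hist[-1]["loss"],
        })
    return pd.DataFrame(rows), histories


ABLATION_NAMES = (
    "baseline",
    "+C3k2-MLCA",
    "+C3k2-MLCA+ReCalibrationFPN-P345",
    "+C3k2-MLCA+ReCalibrationFPN-P345+EIEStem",
    "+C3k2-MLCA+ReCalibrationFPN-P345+EIEStem+AFPN-P345",
)


def ablate(cfg: TrainConfig, dataset, levels=range(5)):
    """Run the five-step ablation lattice; baseline trains with CIoU, the
    enhanced configurations with WIoU."""
    rows = []
    for level in levels:
        mc = ModelConfig.ablation(level, image_size=cfg.image_size)
        run_cfg = dataclasses.replace(cfg, box_loss="ciou" if level == 0 else "wiou")
        model, hist = train(run_cfg, dataset, mc)
        report = evaluate(model, dataset)
        rows.append({
            "Experiment": ABLATION_NAMES[level],
            "p (%)": report.precision,
            "R (%)": report.recall,
            "mAP@0.5 (%)": report.map50,
            "mAP@0.5:0.95 (%)": report.map50_95,
            "F1": report.f1,
            "Final training loss": hist[-1]["loss"],
        })
    return pd.DataFrame(rows)
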