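"""AFPN head: asymptotic (progressive) pyramid fusion, plus box decoding.

Adaptive fusion resizes contributing levels to a common resolution, scores
each with a 1x1 conv, softmax-normalizes the scores per pixel (weights are
nonnegative and sum to one across levels) and takes the weighted sum.  The
head fuses P3 with P4 first, then folds P5 in, iterating the full three-level
fusion a configurable number of times with shared stage weights.

Decoding is anchor-free: each location regresses four nonnegative
left/top/right/bottom distances (softplus-activated, in stride units) around
its cell center; detections above the confidence threshold go through greedy
class-wise non-maximum suppression.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .boxes import iou_matrix
from .metrics import Detection


def fusion_weights(logits_data: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the level axis (axis 1) of an (N,L,H,W) array."""
    m = logits_data.max(axis=1, keepdims=True)
    e = np.exp(logits_data - m)
    return e / e.sum(axis=1, keepdims=True)


class AdaptiveFuse(nn.Module):
    """Per-pixel softmax-weighted sum of same-shape feature maps."""

    def __init__(self, n_levels: int, channels: int):
        super().__init__()
        self.score = [nn.Conv2d(channels, 1, 1) for _ in range(n_levels)]

    def weights(self, levels):
        logits = ad.concat([conv(f) for conv, f in zip(self.score, levels)], axis=1)
        m = ad.Tensor(logits.data.max(axis=1, keepdims=True))
        e = ad.exp(logits - m)
        return e / e.sum(axis=1, keepdims=True)          # (N, L, H, W)

    def forward(self, levels):
        if not levels:
            raise ValueError("adaptive fusion needs at least one level")
        if len(levels) == 1:
            return levels[0]
        w = self.weights(levels)
        out = w[:, 0:1] * levels[0]
        for i in range(1, len(levels)):
            out = out + w[:, i:i + 1] * levels[i]
        return out


class _StageFuse(nn.Module):
    """Fuse a set of source levels into one target level's shape/channels."""

    def __init__(self, src_channels, c_out: int):
        super().__init__()
        self.adapt = [nn.ConvBnAct(c, c_out, 1) for c in src_channels]
        self.fuse = AdaptiveFuse(len(src_channels), c_out)
        self.post = nn.ConvBnAct(c_out, c_out, 3)

    def forward(self, sources, target_hw):
        adapted = []
        for conv, f in zip(self.adapt, sources):
            g = conv(f)
            if g.shape[2:] != tuple(target_hw):
                g = ad.resize_nearest(g, target_hw)
            adapted.append(g)
        return self.post(self.fuse(adapted))


class AFPN(nn.Module):
    """Progressive two-stage pyramid fusion with iterative refinement."""

    def __init__(self, channels: tuple[int, int, int], iterations: int = 2):
        super().__init__()
        if iterations < 1:
            raise ValueError("refinement iteration count must be >= 1")
        c3, c4, c5 = channels
        self.iterations = iterations
        self.stage1_3 = _StageFuse((c3, c4), c3)
        self.stage1_4 = _StageFuse((c3, c4), c4)
        self.stage2_3 = _StageFuse((c3, c4, c5), c3)
        self.stage2_4 = _StageFuse((c3, c4, c5), c4)
        self.stage2_5 = _StageFuse((c3, c4, c5), c5)

    def forward(self, pyramid):
        if len(pyramid) != 3:
            raise ValueError("head expects exactly three pyramid levels")
        p3, p4, p5 = pyramid
        p3, p4 = (self.stage1_3([p3, p4], p3.shape[2:]),
                  self.stage1_4([p3, p4], p4.shape[2:]))
        for _ in range(self.iterations):
            n3 = self.stage2_3([p3, p4, p5], p3.shape[2:])
            n4 = self.stage2_4([p3, p4, p5], p4.shape[2:])
            n5 = self.stage2_5([p3, p4, p5], p5.shape[2:])
            p3, p4, p5 = n3, n4, n5
        return [p3, p4, p5]


class PlainHead(nn.Module):
    """Identity pyramid pass-through with per-level 3x3 convs (ablation)."""

    def __init__(self, channels: tuple[int, int, int], iterations: int = 1):
        super().__init__()
        self.convs = [nn.ConvBnAct(c, c, 3) for c in channels]

    def forward(self, pyramid):
        if len(pyramid) != 3:
            raise ValueError("head expects exactly three pyramid levels")
        return [conv(p) for conv, p in zip(self.convs, pyramid)]


# -- anchor-free decode --------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def level_boxes(reg: np.ndarray, stride: int) -> np.ndarray:
    """Decode a (4, h, w) regression map into (h*w, 4) corner boxes."""
    _, h, w = reg.shape
    gy, gx = np.mgrid[0:h, 0:w]
    cx = (gx + 0.5) * stride
    cy = (gy + 0.5) * stride
    d = _softplus(reg) * stride
    boxes = np.stack([cx - d[0], cy - d[1], cx + d[2], cy + d[3]], axis=-1)
    return boxes.reshape(-1, 4)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy NMS; returns kept indices in descending-score order."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i][None], boxes[rest])[0]
        order = rest[ious < iou_thr]
    return np.asarray(keep, dtype=int)


def decode(prediction, strides=(8, 16, 32), conf_thr: float = 0.25,
           nms_iou: float = 0.45, image_id: int = 0) -> list[Detection]:
    """Turn per-level (cls_logits, reg) numpy maps into final detections.

    ``prediction``: list over levels of ``(cls (nc,h,w), reg (4,h,w))``.
    """
    if not (0 < conf_thr < 1 and 0 < nms_iou < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    all_boxes, all_scores, all_cls = [], [], []
    for (cls_map, reg), stride in zip(prediction, strides):
        nc = cls_map.shape[0]
        boxes = level_boxes(np.asarray(reg, dtype=np.float64), stride)
        scores = _sigmoid(np.asarray(cls_map, dtype=np.float64)).reshape(nc, -1)
        for c in range(nc):
            m = scores[c] >= conf_thr
            if m.any():
                all_boxes.append(boxes[m])
                all_scores.append(scores[c][m])
                all_cls.append(np.full(int(m.sum()), c))
    if not all_boxes:
        return []
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    classes = np.concatenate(all_cls)
    dets = []
    for c in np.unique(classes):
        m = classes == c
        keep = nms(boxes[m], scores[m], nms_iou)
        bc, sc = boxes[m], scores[m]
        dets.extend(Detection(bc[k], float(sc[k]), int(c), image_id) for k in keep)
    dets.sort(key=lambda d: -d.score)
    return dets
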