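"""Bounding-box regression losses: Wise-IoU v1 and the standard IoU family.

All losses operate on differentiable :class:`~peelnet.autodiff.Tensor` boxes
in corner form ``(x1, y1, x2, y2)`` with shape ``(N, 4)`` (a single box may be
passed as a length-4 sequence) and are differentiable with respect to the
predicted box only; the ground truth enters as a constant.

Wise-IoU v1 scales the plain IoU loss by a distance-attention factor

    L = R * (1 - IoU),    R = exp( ((cx - cx_gt)^2 + (cy - cy_gt)^2)
                                   / (W_g^2 + H_g^2)* )

where ``W_g, H_g`` are the dimensions of the smallest box enclosing the pair
and the starred denominator is *detached*: it is evaluated, then treated as a
constant during differentiation, so no gradient is attributed through the
enclosing-box size.  Since the two centers always lie inside the enclosing
box, ``1 <= R <= e``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor

__all__ = ["iou_t", "wiou_v1", "giou_loss", "diou_loss", "ciou_loss",
           "eiou_loss", "box_loss", "LOSS_KINDS"]

_EPS = 1e-10


def _prep(pred, gt):
    pred = as_tensor(pred)
    gt = as_tensor(gt).detach()
    if pred.ndim == 1:
        pred = pred.reshape(1, 4)
    if gt.ndim == 1:
        gt = gt.reshape(1, 4)
    for b in (pred, gt):
        if np.any(b.data[:, 2] <= b.data[:, 0]) or np.any(b.data[:, 3] <= b.data[:, 1]):
            raise ValueError("degenerate box: require x2 > x1 and y2 > y1")
    return pred, gt


def _corners(b: Tensor):
    return b[:, 0], b[:, 1], b[:, 2], b[:, 3]


def iou_t(pred: Tensor, gt: Tensor) -> Tensor:
    """Differentiable IoU of paired boxes, shape (N,)."""
    pred, gt = _prep(pred, gt)
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    iw = ad.maximum(ad.minimum(px2, gx2) - ad.maximum(px1, gx1), 0.0)
    ih = ad.maximum(ad.minimum(py2, gy2) - ad.maximum(py1, gy1), 0.0)
    inter = iw * ih
    union = (px2 - px1) * (py2 - py1) + (gx2 - gx1) * (gy2 - gy1) - inter
    return inter / (union + _EPS)


def _center_dist2(pred: Tensor, gt: Tensor) -> Tensor:
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    dx = (px1 + px2) * 0.5 - (gx1 + gx2) * 0.5
    dy = (py1 + py2) * 0.5 - (gy1 + gy2) * 0.5
    return dx * dx + dy * dy


def _enclosing(pred: Tensor, gt: Tensor):
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    wg = ad.maximum(px2, gx2) - ad.minimum(px1, gx1)
    hg = ad.maximum(py2, gy2) - ad.minimum(py1, gy1)
    return wg, hg


def wiou_v1(pred, gt, detach_enclosing: bool = True) -> Tensor:
    """Wise-IoU v1 loss, shape (N,).

    ``detach_enclosing=True`` is the published form: the enclosing-box
    denominator ``W_g^2 + H_g^2`` is evaluated and then held constant during
    differentiation ("kept separate in the calculation").  The ``False``
    variant differentiates it too and exists only as a contrast for gradient
    tests.
    """
    pred, gt = _prep(pred, gt)
    wg, hg = _enclosing(pred, gt)
    denom = wg * wg + hg * hg
    if detach_enclosing:
        denom = denom.detach()
    if np.any(denom.data <= 0):
        raise ValueError("degenerate enclosing box (W_g^2 + H_g^2 = 0)")
    r = ad.exp(_center_dist2(pred, gt) / denom)
    return r * (1.0 - iou_t(pred, gt))


def giou_loss(pred, gt) -> Tensor:
    """Generalized IoU loss: 1 - IoU + |C minus union| / |C|."""
    pred, gt = _prep(pred, gt)
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    iw = ad.maximum(ad.minimum(px2, gx2) - ad.maximum(px1, gx1), 0.0)
    ih = ad.maximum(ad.minimum(py2, gy2) - ad.maximum(py1, gy1), 0.0)
    inter = iw * ih
    union = (px2 - px1) * (py2 - py1) + (gx2 - gx1) * (gy2 - gy1) - inter
    wg, hg = _enclosing(pred, gt)
    c = wg * hg
    return 1.0 - inter / (union + _EPS) + (c - union) / (c + _EPS)


def diou_loss(pred, gt) -> Tensor:
    """Distance IoU loss: 1 - IoU + d^2 / c^2 (c = enclosing diagonal)."""
    pred, gt = _prep(pred, gt)
    wg, hg = _enclosing(pred, gt)
    c2 = wg * wg + hg * hg
    return 1.0 - iou_t(pred, gt) + _center_dist2(pred, gt) / (c2 + _EPS)


def ciou_loss(pred, gt) -> Tensor:
    """Complete IoU loss: DIoU plus an aspect-ratio consistency term."""
    pred, gt = _prep(pred, gt)
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    i = iou_t(pred, gt)
    wg, hg = _enclosing(pred, gt)
    c2 = wg * wg + hg * hg
    w, h = px2 - px1, py2 - py1
    wgt, hgt = gx2 - gx1, gy2 - gy1
    v = (4.0 / np.pi ** 2) * (ad.arctan(wgt / hgt) - ad.arctan(w / h)) ** 2
    # trade-off weight alpha is treated as a constant, as in the original
    alpha = Tensor(v.data / (1.0 - i.data + v.data + _EPS))
    return 1.0 - i + _center_dist2(pred, gt) / (c2 + _EPS) + alpha * v


def eiou_loss(pred, gt) -> Tensor:
    """Efficient IoU loss: DIoU plus separate width/height distance terms."""
    pred, gt = _prep(pred, gt)
    px1, py1, px2, py2 = _corners(pred)
    gx1, gy1, gx2, gy2 = _corners(gt)
    wg, hg = _enclosing(pred, gt)
    c2 = wg * wg + hg * hg
    w, h = px2 - px1, py2 - py1
    wgt, hgt = gx2 - gx1, gy2 - gy1
    return (1.0 - iou_t(pred, gt)
            + _center_dist2(pred, gt) / (c2 + _EPS)
            + (w - wgt) ** 2 / (wg * wg + _EPS)
            + (h - hgt) ** 2 / (hg * hg + _EPS))


LOSS_KINDS = {
    "wiou": wiou_v1,
    "giou": giou_loss,
    "diou": diou_loss,
    "ciou": ciou_loss,
    "eiou": eiou_loss,
}


def box_loss(pred, gt, kind: str = "wiou") -> Tensor:
    """Dispatch by loss-kind name (the CLI's ``--box-loss`` values)."""
    try:
        fn = LOSS_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown box loss {kind!r}; choose from {sorted(LOSS_KINDS)}")
    return fn(pred, gt)
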