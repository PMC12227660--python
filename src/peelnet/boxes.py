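"""Axis-aligned bounding-box geometry in continuous pixel coordinates.

The canonical box form throughout the package is the corner form
``(x1, y1, x2, y2)`` with ``x2 > x1`` and ``y2 > y1``.  Conversions to and
from the normalized YOLO center form are explicit, so no code path has to
guess which convention an array is in.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "validate_boxes", "corners_to_center", "center_to_corners",
    "yolo_to_corners", "corners_to_yolo", "iou", "iou_matrix",
    "enclosing_dims", "box_area",
]


def validate_boxes(b: np.ndarray) -> np.ndarray:
    """Return boxes as a float (N, 4) array; raise on degenerate boxes."""
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if b.shape[-1] != 4:
        raise ValueError(f"boxes must have 4 coordinates, got shape {b.shape}")
    if np.any(b[:, 2] <= b[:, 0]) or np.any(b[:, 3] <= b[:, 1]):
        raise ValueError("degenerate box: require x2 > x1 and y2 > y1")
    return b


def box_area(b: np.ndarray) -> np.ndarray:
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    return (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])


def corners_to_center(b: np.ndarray) -> np.ndarray:
    """(x1,y1,x2,y2) -> (cx,cy,w,h)."""
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    cx = (b[:, 0] + b[:, 2]) / 2
    cy = (b[:, 1] + b[:, 3]) / 2
    return np.stack([cx, cy, b[:, 2] - b[:, 0], b[:, 3] - b[:, 1]], axis=1)


def center_to_corners(b: np.ndarray) -> np.ndarray:
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    hw, hh = b[:, 2] / 2, b[:, 3] / 2
    return np.stack([b[:, 0] - hw, b[:, 1] - hh, b[:, 0] + hw, b[:, 1] + hh], axis=1)


def yolo_to_corners(b: np.ndarray, width: int, height: int) -> np.ndarray:
    """Normalized (cx,cy,w,h) in [0,1] -> pixel corner form."""
    b = np.atleast_2d(np.asarray(b, dtype=np.float64)).copy()
    b[:, [0, 2]] *= width
    b[:, [1, 3]] *= height
    return center_to_corners(b)


def corners_to_yolo(b: np.ndarray, width: int, height: int) -> np.ndarray:
    c = corners_to_center(b)
    c[:, [0, 2]] /= width
    c[:, [1, 3]] /= height
    return c


def iou(a, b) -> float:
    """Intersection-over-union of two single boxes (corner form)."""
    a = validate_boxes(a)[0]
    b = validate_boxes(b)[0]
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return float(inter / union)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (M,4) and (N,4) corner-form boxes -> (M,N)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    union = box_area(a)[:, None] + box_area(b)[None, :] - inter
    return inter / union


def enclosing_dims(a, b) -> tuple[float, float]:
    """Width/height (W_g, H_g) of the smallest box enclosing both boxes."""
    a = validate_boxes(a)[0]
    b = validate_boxes(b)[0]
    wg = max(a[2], b[2]) - min(a[0], b[0])
    hg = max(a[3], b[3]) - min(a[1], b[1])
    return float(wg), float(hg)
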