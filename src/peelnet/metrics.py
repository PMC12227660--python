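"""Detection evaluation: matching, precision/recall, F1, AP/mAP, run stats.

Conventions (documented because every evaluator has to pick them):

* Matching is greedy by descending confidence; each ground-truth box may be
  matched at most once; a detection is a true positive iff its best-IoU
  unmatched ground truth reaches the IoU threshold.  Ties are broken by
  higher IoU, then input order.
* Precision and recall are percentages: P = TP/(TP+FP)x100, R = TP/(TP+FN)x100,
  both defined as 0 when their denominator is 0.
* F1 = 2PR/(P+R) is reported on the 0-1 scale.
* AP is the area under the monotone-interpolated precision envelope over
  recall, using every operating point ("all-points" interpolation).
* Table-style P/R/F1 are reported at the confidence threshold that maximizes
  F1 over the detection-score sweep.
* Run statistics over repeated experiments use the sample standard deviation
  (n-1 denominator) and a normal confidence interval x +- z*SD/sqrt(n),
  z = 1.96 for 95%.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .boxes import iou_matrix

__all__ = [
    "Detection", "MatchCounts", "match", "precision_recall", "f1",
    "average_precision", "mean_ap", "ap_at_threshold", "map_range",
    "run_stats", "RunStats", "MetricReport", "evaluate_detections",
]

MAP_RANGE_THRESHOLDS = np.arange(0.5, 0.96, 0.05)


@dataclasses.dataclass
class Detection:
    """One decoded detection: corner-form box, confidence, class index."""
    box: np.ndarray
    score: float
    cls: int = 0
    image_id: int = 0


@dataclasses.dataclass
class MatchCounts:
    n_tp: int
    n_fp: int
    n_fn: int


def match(dets, gts, iou_thr: float):
    """Greedily match detections to ground truths at one IoU threshold.

    ``dets``: list of :class:`Detection` (single image, single class);
    ``gts``: (G, 4) array of corner boxes.  Returns ``(MatchCounts, flags)``
    where ``flags[i]`` is True iff the i-th detection (in descending-score
    order with stable ties) is a true positive.
    """
    if not 0 < iou_thr < 1:
        raise ValueError("iou_thr must lie in (0, 1)")
    gts = np.asarray(gts, dtype=np.float64).reshape(-1, 4)
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    flags = np.zeros(len(dets), dtype=bool)
    taken = np.zeros(len(gts), dtype=bool)
    if len(dets) and len(gts):
        mat = iou_matrix(np.stack([dets[i].box for i in order]), gts)
        for r, i in enumerate(order):
            ious = np.where(taken, -1.0, mat[r])
            j = int(np.argmax(ious))
            if ious[j] >= iou_thr:
                taken[j] = True
                flags[i] = True
    tp = int(flags.sum())
    return MatchCounts(tp, len(dets) - tp, len(gts) - tp), flags


def precision_recall(c: MatchCounts) -> tuple[float, float]:
    """Precision and recall in percent; 0 when a denominator is 0."""
    p = 100.0 * c.n_tp / (c.n_tp + c.n_fp) if (c.n_tp + c.n_fp) else 0.0
    r = 100.0 * c.n_tp / (c.n_tp + c.n_fn) if (c.n_tp + c.n_fn) else 0.0
    return p, r


def f1(p: float, r: float) -> float:
    """Harmonic mean of percent precision/recall, on the 0-1 scale."""
    if p == 0 and r == 0:
        return 0.0
    return 2.0 * p * r / (p + r) / 100.0


def _sorted_flags(dets_by_image, gts_by_image, iou_thr):
    """Pooled (score, tp) pairs over images, sorted by descending score."""
    scores, tps = [], []
    n_gt = 0
    for dets, gts in zip(dets_by_image, gts_by_image):
        gts = np.asarray(gts, dtype=np.float64).reshape(-1, 4)
        n_gt += len(gts)
        _, flags = match(dets, gts, iou_thr)
        scores.extend(d.score for d in dets)
        tps.extend(flags)
    scores = np.asarray(scores)
    tps = np.asarray(tps, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    return scores[order], tps[order], n_gt


def pr_curve(dets_by_image, gts_by_image, iou_thr: float = 0.5):
    """Cumulative (recall, precision) points swept over confidence."""
    scores, tps, n_gt = _sorted_flags(dets_by_image, gts_by_image, iou_thr)
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(~tps)
    recall = tp_cum / n_gt if n_gt else np.zeros_like(tp_cum, dtype=float)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    return recall, precision, scores, tps, n_gt


def average_precision(recall: np.ndarray, precision: np.ndarray) -> float:
    """All-points interpolated AP: area under the precision envelope."""
    if len(recall) == 0:
        return 0.0
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[0.0], precision, [0.0]])
    # monotone non-increasing envelope from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def ap_at_threshold(dets_by_image, gts_by_image, iou_thr: float = 0.5) -> float:
    recall, precision, _, _, n_gt = pr_curve(dets_by_image, gts_by_image, iou_thr)
    if n_gt == 0:
        return 0.0
    return average_precision(recall, precision)


def mean_ap(per_class_ap) -> float:
    per_class_ap = list(per_class_ap)
    if not per_class_ap:
        raise ValueError("need at least one class AP")
    return float(np.mean(per_class_ap))


def map_range(dets_by_image, gts_by_image,
              thresholds=MAP_RANGE_THRESHOLDS) -> float:
    """mAP averaged over the 0.5:0.05:0.95 IoU threshold ladder."""
    return float(np.mean([ap_at_threshold(dets_by_image, gts_by_image, float(t))
                          for t in thresholds]))


@dataclasses.dataclass
class RunStats:
    """Mean, sample SD and normal CI half-width over repeated runs."""
    values: list
    mean: float
    sd: float
    ci_half_width: float
    n: int
    z: float


def run_stats(values, z: float = 1.96) -> RunStats:
    values = [float(v) for v in values]
    n = len(values)
    if n < 2:
        raise ValueError("run statistics need at least two runs")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return RunStats(values, mean, sd, z * sd / np.sqrt(n), n, z)


@dataclasses.dataclass
class MetricReport:
    """The quantities a detector comparison table reports."""
    precision: float            # percent, at the max-F1 operating point
    recall: float               # percent
    f1: float                   # 0-1 scale
    ap_per_class: dict
    map50: float                # percent
    map50_95: float             # percent
    n_images: int
    n_gt: int
    operating_score: float
    sd: float | None = None
    ci_half_width: float | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def to_text(self) -> str:
        head = (f"{'p (%)':>8} {'r (%)':>8} {'mAP@0.5 (%)':>12} "
                f"{'mAP@0.5:0.95 (%)':>17} {'F1':>7}")
        row = (f"{self.precision:8.1f} {self.recall:8.1f} {self.map50:12.1f} "
               f"{self.map50_95:17.1f} {self.f1:7.3f}")
        return head + "\n" + row


def evaluate_detections(dets_by_image, gts_by_image, classes=(0,)) -> MetricReport:
    """Full evaluation of per-image detection lists against ground truth."""
    ap50, ap_range = {}, {}
    for c in classes:
        d_c = [[d for d in dets if d.cls == c] for dets in dets_by_image]
        g_c = gts_by_image  # single-class ground truth lists are per class already
        ap50[int(c)] = ap_at_threshold(d_c, g_c, 0.5)
        ap_range[int(c)] = map_range(d_c, g_c)

    # operating point: score threshold maximizing F1 on the pooled 0.5 sweep
    scores, tps, n_gt = _sorted_flags(dets_by_image, gts_by_image, 0.5)
    best = (0.0, 0.0, 0.0, 1.0)  # f1, p, r, score
    if len(scores) and n_gt:
        tp_cum = np.cumsum(tps)
        fp_cum = np.cumsum(~tps)
        p = 100.0 * tp_cum / np.maximum(tp_cum + fp_cum, 1)
        r = 100.0 * tp_cum / n_gt
        f1s = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-12) / 100.0, 0.0)
        k = int(np.argmax(f1s))
        best = (float(f1s[k]), float(p[k]), float(r[k]), float(scores[k]))

    return MetricReport(
        precision=best[1], recall=best[2], f1=best[0],
        ap_per_class=ap50,
        map50=100.0 * mean_ap(ap50.values()),
        map50_95=100.0 * mean_ap(ap_range.values()),
        n_images=len(list(gts_by_image)),
        n_gt=int(sum(np.asarray(g).reshape(-1, 4).shape[0] for g in gts_by_image)),
        operating_score=best[3],
    )
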