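"""Evaluation mathematics: matching, P/R/F1, AP/mAP, run statistics."""

import itertools

import numpy as np
import pytest

from peelnet.boxes import iou_matrix
from peelnet.metrics import (Detection, MatchCounts, ap_at_threshold,
                             average_precision, evaluate_detections, f1,
                             map_range, match, mean_ap, pr_curve,
                             precision_recall, run_stats)


def det(box, score, cls=0):
    return Detection(np.asarray(box, dtype=float), score, cls)


class TestMatch:
    def test_perfect_replay(self):
        gts = np.array([[0, 0, 10, 10], [20, 20, 30, 30]], dtype=float)
        dets = [det(g, 1.0) for g in gts]
        counts, flags = match(dets, gts, 0.5)
        assert (counts.n_tp, counts.n_fp, counts.n_fn) == (2, 0, 0)
        assert flags.all()

    def test_duplicate_detection_is_fp(self):
        gts = np.array([[0, 0, 10, 10]], dtype=float)
        dets = [det([0, 0, 10, 10], 0.9), det([1, 1, 11, 11], 0.8)]
        counts, flags = match(dets, gts, 0.5)
        assert (counts.n_tp, counts.n_fp, counts.n_fn) == (1, 1, 0)
        assert flags.tolist() == [True, False]

    def test_toy_layout_against_exhaustive_assignment(self):
        """Greedy-by-confidence counts equal the best one-to-one assignment
        among score-ordered prefixes, enumerated by brute force."""
        gts = np.array([[0, 0, 10, 10], [12, 0, 22, 10]], dtype=float)
        dets = [det([1, 0, 11, 10], 0.9),    # overlaps both gts, best for gt0
                det([11, 0, 21, 10], 0.8),   # best for gt1
                det([2, 1, 12, 11], 0.7)]    # leftover duplicate
        counts, flags = match(dets, gts, 0.3)
        # brute force: maximize TP over all injective det->gt maps honouring
        # the IoU threshold and greedy confidence priority
        boxes = np.stack([d.box for d in dets])
        mat = iou_matrix(boxes, gts)
        best_tp = 0
        for assign in itertools.product([-1, 0, 1], repeat=3):
            used = [g for g in assign if g >= 0]
            if len(used) != len(set(used)):
                continue
            if all(g < 0 or mat[i, g] >= 0.3 for i, g in enumerate(assign)):
                best_tp = max(best_tp, len(used))
        assert counts.n_tp == best_tp == 2
        assert counts.n_fp == 1 and counts.n_fn == 0

    def test_counts_conservation_random(self, rng):
        for _ in range(20):
            n_gt = int(rng.integers(0, 6))
            n_det = int(rng.integers(0, 8))
            gts = np.hstack([rng.uniform(0, 50, (n_gt, 2)),
                             rng.uniform(51, 90, (n_gt, 2))])[:, [0, 2, 1, 3]] \
                if n_gt else np.empty((0, 4))
            dets = [det(np.sort(rng.uniform(0, 90, 4).reshape(2, 2), axis=1).T.ravel()
                        + [0, 0, 1, 1], rng.random()) for _ in range(n_det)]
            dets = [det([d.box[0], d.box[1], d.box[0] + 5, d.box[1] + 5], d.score)
                    for d in dets]
            c, _ = match(dets, gts, 0.5)
            assert c.n_tp + c.n_fn == n_gt
            assert c.n_tp + c.n_fp == n_det

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            match([], np.empty((0, 4)), 1.5)


class TestPrecisionRecallF1:
    def test_percent_values(self):
        assert precision_recall(MatchCounts(9, 1, 0))[0] == 90.0
        assert precision_recall(MatchCounts(9, 0, 1))[1] == 90.0

    def test_zero_denominator_convention(self):
        assert precision_recall(MatchCounts(0, 0, 3)) == (0.0, 0.0)

    @pytest.mark.parametrize("p,r,expected", [
        (96.5, 96.0, 0.962),
        (89.1, 84.2, 0.866),
        (93.9, 89.5, 0.916),
        (93.4, 92.2, 0.928),
        (94.6, 92.4, 0.935),
    ])
    def test_f1_reproduces_reported_table_values(self, p, r, expected):
        assert f1(p, r) == pytest.approx(expected, abs=5e-4)

    def test_f1_symmetry_and_edge(self):
        assert f1(80.0, 80.0) == pytest.approx(0.8)
        assert f1(0.0, 0.0) == 0.0


def brute_force_ap(scores, tps, n_gt):
    """Independent AP oracle: rectangle sum over every confidence cut."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    tps = np.asarray(tps, dtype=bool)[order]
    best_prec = {}
    tp = fp = 0
    for flag in tps:
        tp += flag
        fp += not flag
        r = tp / n_gt
        p = tp / (tp + fp)
        best_prec[r] = max(best_prec.get(r, 0.0), p)
    # envelope: precision at recall >= r
    recalls = sorted(best_prec)
    ap, prev = 0.0, 0.0
    for i, r in enumerate(recalls):
        env = max(best_prec[rr] for rr in recalls[i:])
        ap += (r - prev) * env
        prev = r
    return ap


class TestAveragePrecision:
    def test_perfect_detector(self):
        gts = [np.array([[0, 0, 10, 10], [20, 20, 30, 30]], dtype=float)]
        dets = [[det(g, s) for g, s in zip(gts[0], (0.9, 0.8))]]
        assert ap_at_threshold(dets, gts) == 1.0
        assert map_range(dets, gts) == 1.0

    def test_no_tp(self):
        gts = [np.array([[0, 0, 10, 10]], dtype=float)]
        dets = [[det([50, 50, 60, 60], 0.9)]]
        assert ap_at_threshold(dets, gts) == 0.0

    def test_toy_sweep_tp_fp_tp(self):
        """TP, FP, TP over two gts: hand-enumerated PR points.

        points: (0.5, 1), (0.5, 1/2), (1.0, 2/3); envelope area =
        0.5*1 + 0.5*(2/3) = 5/6.
        """
        gts = [np.array([[0, 0, 10, 10], [20, 0, 30, 10]], dtype=float)]
        dets = [[det([0, 0, 10, 10], 0.9),
                 det([50, 50, 60, 60], 0.8),
                 det([20, 0, 30, 10], 0.7)]]
        assert ap_at_threshold(dets, gts) == pytest.approx(5 / 6)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n_gt = int(rng.integers(1, 5))
            gts_arr = np.array([[30 * i, 0, 30 * i + 10, 10] for i in range(n_gt)],
                               dtype=float)
            dets = []
            for i in range(int(rng.integers(1, 10))):
                if rng.random() < 0.6 and n_gt:
                    g = int(rng.integers(0, n_gt))
                    dets.append(det(gts_arr[g] + rng.uniform(-1, 1, 4) * 0.5,
                                    float(rng.random())))
                else:
                    dets.append(det([500 + 20 * i, 0, 510 + 20 * i, 10],
                                    float(rng.random())))
            recall, precision, scores, tps, n = pr_curve([dets], [gts_arr], 0.5)
            got = average_precision(recall, precision)
            want = brute_force_ap(scores, tps, n_gt)
            assert got == pytest.approx(want, abs=1e-12)

    def test_recall_monotone_along_sweep(self, rng):
        gts = [np.array([[0, 0, 10, 10], [20, 0, 30, 10]], dtype=float)]
        dets = [[det([0, 0, 10, 10], float(s)) for s in rng.random(6)]]
        recall, precision, *_ = pr_curve(dets, gts, 0.5)
        assert np.all(np.diff(recall) >= 0)
        assert np.all((precision >= 0) & (precision <= 1))


class TestMeanAP:
    def test_single_class(self):
        assert mean_ap([0.7]) == 0.7

    def test_two_class_mean(self):
        assert mean_ap([1.0, 0.0]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_ap([])


class TestRunStats:
    def test_constant_runs(self):
        rs = run_stats([3.0] * 5)
        assert rs.sd == 0.0 and rs.ci_half_width == 0.0

    def test_hand_arithmetic(self):
        rs = run_stats([1, 2, 3, 4, 5], z=1.96)
        assert rs.mean == 3.0
        assert rs.sd == pytest.approx(np.sqrt(2.5), rel=1e-12)
        assert rs.sd == pytest.approx(1.5811, abs=1e-4)
        assert rs.ci_half_width == pytest.approx(1.96 * np.sqrt(2.5) / np.sqrt(5), rel=1e-12)
        assert rs.ci_half_width == pytest.approx(1.3859, abs=1e-4)

    def test_scaling(self, rng):
        v = rng.normal(10, 2, 6)
        assert run_stats(list(3.5 * v)).sd == pytest.approx(3.5 * run_stats(list(v)).sd)

    def test_too_few_runs(self):
        with pytest.raises(ValueError):
            run_stats([1.0])


class TestEvaluateDetections:
    def test_ground_truth_replay_is_perfect(self, small_scenes):
        gts = [s.boxes for s in small_scenes]
        dets = [[det(b, 1.0) for b in g] for g in gts]
        report = evaluate_detections(dets, gts)
        assert report.map50 == 100.0
        assert report.map50_95 == 100.0
        assert report.precision == 100.0 and report.recall == 100.0
        assert report.f1 == pytest.approx(1.0)

    def test_empty_predictions(self, small_scenes):
        gts = [s.boxes for s in small_scenes]
        report = evaluate_detections([[] for _ in gts], gts)
        assert report.map50 == 0.0 and report.recall == 0.0
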