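"""Detection metric oracles: matching, PR, AP interpolation, NMS."""
import itertools

import numpy as np
import pytest

from peapod.metrics import (ap, evaluate_detections, iou_matrix, map50,
                            match_and_count, nms, precision_recall)

RNG = np.random.default_rng(21)


def det(x1, y1, x2, y2, conf=0.9, cls=0):
    return [x1, y1, x2, y2, conf, cls]


def gt(x1, y1, x2, y2, cls=0):
    return [x1, y1, x2, y2, cls]


class TestMatching:
    def test_identical_sets(self):
        preds = np.array([det(0, 0, 10, 10), det(20, 20, 30, 30, 0.8, 1)])
        gts = np.array([gt(0, 0, 10, 10), gt(20, 20, 30, 30, 1)])
        tp, fp, fn, _ = match_and_count(preds, gts, 0.5)
        assert (tp, fp, fn) == (2, 0, 0)

    def test_prediction_without_truth(self):
        tp, fp, fn, _ = match_and_count(np.array([det(0, 0, 5, 5)]),
                                        np.zeros((0, 5)), 0.5)
        assert (tp, fp, fn) == (0, 1, 0)

    def test_double_detection_of_one_truth(self):
        preds = np.array([det(0, 0, 10, 10, 0.6), det(1, 0, 11, 10, 0.9)])
        gts = np.array([gt(0, 0, 10, 10)])
        tp, fp, fn, flags = match_and_count(preds, gts, 0.5)
        assert (tp, fp, fn) == (1, 1, 0)
        assert flags[1] and not flags[0]  # the higher-confidence one matched

    def test_class_must_agree(self):
        tp, fp, fn, _ = match_and_count(np.array([det(0, 0, 10, 10, 0.9, 1)]),
                                        np.array([gt(0, 0, 10, 10, 0)]), 0.5)
        assert (tp, fp, fn) == (0, 1, 1)

    def test_greedy_equals_exhaustive_on_small_instances(self):
        """On random <=6-box instances, greedy matching attains the maximum
        one-to-one match count found by brute force over assignments."""
        def optimal_tp(preds, gts, thr):
            iou = iou_matrix(preds[:, :4], gts[:, :4])
            ok = (iou >= thr) & (preds[:, None, 5] == gts[None, :, 4])
            best = 0
            for perm in itertools.permutations(range(len(gts)),
                                               min(len(preds), len(gts))):
                cnt = sum(1 for i, j in enumerate(perm) if ok[i, j])
                best = max(best, cnt)
            return best

        for trial in range(30):
            n_p, n_g = RNG.integers(1, 7), RNG.integers(1, 7)
            cells = RNG.permutation(9)
            def boxes(n, jitter):
                out = []
                for c in cells[:n]:
                    x, y = (c % 3) * 20, (c // 3) * 20
                    dx, dy = RNG.uniform(-jitter, jitter, 2)
                    out.append([x + dx, y + dy, x + 15 + dx, y + 15 + dy,
                                RNG.uniform(0.1, 1), RNG.integers(0, 2)])
                return np.array(out)
            preds = boxes(n_p, 3)
            gts = boxes(n_g, 0)[:, [0, 1, 2, 3, 5]]
            tp, _, _, _ = match_and_count(preds, gts, 0.5)
            assert tp == optimal_tp(preds, gts, 0.5)


class TestPrecisionRecallAP:
    def test_ratios(self):
        assert precision_recall(8, 2, 0)[0] == pytest.approx(0.8)
        assert precision_recall(6, 0, 2)[1] == pytest.approx(0.75)

    def test_zero_over_zero_defined_as_zero(self):
        assert precision_recall(0, 0, 0) == (0.0, 0.0)

    def test_negative_tallies_rejected(self):
        with pytest.raises(ValueError):
            precision_recall(-1, 0, 0)

    def test_hand_example_all_point_interpolation(self):
        """Ranked outcomes [TP, FP, TP] with 2 truths -> AP = 0.8333."""
        preds = [np.array([det(0, 0, 10, 10, 0.9),
                           det(50, 50, 60, 60, 0.8),
                           det(20, 20, 30, 30, 0.7)])]
        gts = [np.array([gt(0, 0, 10, 10), gt(20, 20, 30, 30)])]
        res = evaluate_detections(preds, gts)
        assert res.ap_per_class[0] == pytest.approx(0.5 * 1 + 0.5 * (2 / 3))

    def test_perfect_predictions_score_one(self):
        gts = [np.array([gt(0, 0, 10, 10, 0), gt(20, 20, 30, 30, 1)])] * 3
        preds = [np.array([det(0, 0, 10, 10, 0.9, 0),
                           det(20, 20, 30, 30, 0.95, 1)])] * 3
        res = evaluate_detections(preds, gts)
        assert res.map50 == 1.0 and res.precision == 1.0 and res.recall == 1.0

    def test_empty_predictions_score_zero(self):
        gts = [np.array([gt(0, 0, 10, 10)])]
        res = evaluate_detections([np.zeros((0, 6))], gts)
        assert res.map50 == 0.0

    def test_duplication_invariance(self):
        """Copying every image (with its truths) leaves AP unchanged."""
        preds, gts = [], []
        for i in range(4):
            n = RNG.integers(1, 4)
            g = []
            p = []
            for j in range(n):
                x, y = RNG.uniform(0, 80, 2)
                g.append([x, y, x + 12, y + 12, RNG.integers(0, 2)])
                if RNG.random() < 0.8:
                    dx = RNG.uniform(-4, 4)
                    p.append([x + dx, y, x + 12 + dx, y + 12,
                              RNG.uniform(0.2, 1), g[-1][4]])
            if RNG.random() < 0.5:
                p.append([0, 0, 10, 10, RNG.uniform(0.2, 1), 0])
            preds.append(np.array(p).reshape(-1, 6))
            gts.append(np.array(g).reshape(-1, 5))
        once = evaluate_detections(preds, gts).map50
        twice = evaluate_detections(preds * 2, gts * 2).map50
        assert once == pytest.approx(twice)

    def test_coco_mode_close_to_all_point(self):
        preds = [np.array([det(0, 0, 10, 10, 0.9),
                           det(20, 20, 30, 30, 0.7)])]
        gts = [np.array([gt(0, 0, 10, 10), gt(20, 20, 30, 30)])]
        a = evaluate_detections(preds, gts, mode="all_point").map50
        c = evaluate_detections(preds, gts, mode="coco101").map50
        assert abs(a - c) < 0.02

    def test_map_is_unweighted_class_mean(self):
        assert map50({0: 0.5, 1: 1.0}) == pytest.approx(0.75)
        assert map50({}) == 0.0


class TestNMS:
    def test_duplicate_suppression(self):
        dets = np.array([det(0, 0, 10, 10, 0.9), det(0, 0, 10, 10, 0.8)])
        out = nms(dets, 0.65)
        assert len(out) == 1 and out[0, 4] == 0.9

    def test_disjoint_boxes_survive(self):
        dets = np.array([det(0, 0, 10, 10, 0.9), det(50, 50, 60, 60, 0.2)])
        assert len(nms(dets, 0.65)) == 2

    def test_classwise_independence(self):
        dets = np.array([det(0, 0, 10, 10, 0.9, 0), det(0, 0, 10, 10, 0.8, 1)])
        assert len(nms(dets, 0.5)) == 2

    def test_matches_exhaustive_oracle_on_random_boxes(self):
        def naive(dets, thr):
            keep = []
            remaining = sorted(range(len(dets)), key=lambda i: -dets[i][4])
            while remaining:
                i = remaining.pop(0)
                keep.append(tuple(dets[i]))
                remaining = [j for j in remaining
                             if dets[j][5] != dets[i][5] or
                             iou_matrix(dets[i][None, :4],
                                        dets[j][None, :4])[0, 0] <= thr]
            return sorted(keep)

        for trial in range(20):
            n = RNG.integers(1, 6)
            dets = []
            for _ in range(n):
                x, y = RNG.uniform(0, 40, 2)
                w, h = RNG.uniform(5, 25, 2)
                dets.append([x, y, x + w, y + h,
                             round(RNG.uniform(0.1, 1), 3), RNG.integers(0, 2)])
            dets = np.array(dets)
            got = sorted(map(tuple, nms(dets, 0.5)))
            assert got == naive(dets, 0.5)


def test_ap_of_empty_curve_is_zero():
    assert ap([]) == 0.0
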