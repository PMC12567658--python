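"""Precision / recall / mAP: worked examples and invariants."""

import itertools

import numpy as np
import pytest

from lmtb import metrics as M


def _box(cx, cy, s=0.1):
    return [cx, cy, s, s]


def _gts_three():
    return {"img": np.array([
        [0, *_box(0.2, 0.2)],
        [0, *_box(0.5, 0.5)],
        [0, *_box(0.8, 0.8)],
    ])}


def _dets_five():
    # conf-ordered: TP, duplicate-FP, TP, clean-FP, TP
    return {"img": np.array([
        [0, 0.9, *_box(0.2, 0.2)],
        [0, 0.8, *_box(0.21, 0.2)],
        [0, 0.7, *_box(0.5, 0.5)],
        [0, 0.6, *_box(0.35, 0.35)],
        [0, 0.5, *_box(0.8, 0.8)],
    ])}


def brute_force_max_matching(dets, gts, iou_t):
    """Exhaustive one-to-one assignment maximising TP (oracle)."""
    iou = M.box_iou_xywh(dets[:, 2:6], gts[:, 1:5])
    best = 0
    n_d, n_g = len(dets), len(gts)
    for assign in itertools.product(range(-1, n_g), repeat=n_d):
        used = [a for a in assign if a >= 0]
        if len(used) != len(set(used)):
            continue
        tp = sum(
            1 for d, g in enumerate(assign)
            if g >= 0 and dets[d, 0] == gts[g, 0] and iou[d, g] >= iou_t
        )
        best = max(best, tp)
    return best


class TestMatching:
    def test_perfect_detections(self):
        gts = _gts_three()
        dets = {"img": np.column_stack([
            gts["img"][:, 0], np.full(3, 0.9), gts["img"][:, 1:5]
        ])}
        assert M.match_detections(dets, gts, 0.5) == (3, 0, 0)

    def test_no_detections(self):
        gts = _gts_three()
        assert M.match_detections({}, gts, 0.5) == (0, 0, 3)

    def test_crafted_case_matches_exhaustive_oracle(self):
        dets, gts = _dets_five(), _gts_three()
        tp, fp, fn = M.match_detections(dets, gts, 0.5)
        oracle_tp = brute_force_max_matching(dets["img"], gts["img"], 0.5)
        assert tp == oracle_tp == 3
        assert (fp, fn) == (2, 0)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            M.match_detections({}, {}, 1.0)

    def test_malformed_boxes_rejected(self):
        with pytest.raises(ValueError):
            M.match_detections(
                {"i": np.array([[0, 0.9, 0.5, 0.5, -0.1, 0.1]])},
                {"i": np.zeros((0, 5))}, 0.5,
            )


class TestPrecisionRecall:
    def test_worked_values(self):
        assert M.precision_recall(2, 1, 0)[0] == pytest.approx(2 / 3)
        assert M.precision_recall(2, 0, 1)[1] == pytest.approx(2 / 3)

    def test_zero_over_zero_convention(self):
        assert M.precision_recall(0, 0, 0) == (0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            M.precision_recall(-1, 0, 0)


class TestAveragePrecision:
    def test_perfect_detection_map_is_one(self):
        gts = _gts_three()
        dets = {"img": np.column_stack([
            gts["img"][:, 0], np.full(3, 0.9), gts["img"][:, 1:5]
        ])}
        assert M.mean_average_precision(dets, gts, M.MAP5095_THRESHOLDS) == pytest.approx(1.0)

    def test_no_detections_map_is_zero(self):
        assert M.mean_average_precision({}, _gts_three(), (0.5,)) == 0.0

    def test_hand_integrated_five_det_three_gt_case(self):
        """TP,FP,TP,FP,TP by confidence -> all-points AP = 1/3 + 2/9 + 1/5."""
        ap = M.average_precision(_dets_five(), _gts_three(), 0.5)[0]
        assert ap == pytest.approx(34 / 45, abs=1e-9)

    def test_101_point_close_to_all_points(self):
        ap_all = M.mean_average_precision(_dets_five(), _gts_three(), (0.5,), "all")
        ap_101 = M.mean_average_precision(_dets_five(), _gts_three(), (0.5,), "101")
        assert abs(ap_all - ap_101) < 0.02

    def test_duplicate_of_matched_detection_never_increases_ap(self):
        dets, gts = _dets_five(), _gts_three()
        before = M.mean_average_precision(dets, gts, (0.5,))
        dup = np.vstack([dets["img"], [[0, 0.45, *_box(0.2, 0.2)]]])
        after = M.mean_average_precision({"img": dup}, gts, (0.5,))
        assert after <= before + 1e-12

    def test_detections_for_class_absent_from_gts_score_zero(self):
        gts = {"img": np.array([[0, *_box(0.5, 0.5)]])}
        dets = {"img": np.array([
            [0, 0.9, *_box(0.5, 0.5)],
            [1, 0.9, *_box(0.2, 0.2)],
        ])}
        aps = M.average_precision(dets, gts, 0.5)
        assert aps[0] == pytest.approx(1.0)
        assert aps[1] == 0.0


class TestInvariants:
    def _random_data(self, rng, n_img=4):
        dets, gts = {}, {}
        for i in range(n_img):
            ng, nd = rng.integers(0, 6), rng.integers(0, 8)
            gts[f"i{i}"] = np.column_stack([
                np.zeros(ng), rng.uniform(0.2, 0.8, (ng, 2)).reshape(ng, 2),
                rng.uniform(0.05, 0.2, (ng, 2)),
            ]) if ng else np.zeros((0, 5))
            dets[f"i{i}"] = np.column_stack([
                np.zeros(nd), rng.uniform(0, 1, nd),
                rng.uniform(0.2, 0.8, (nd, 2)), rng.uniform(0.05, 0.2, (nd, 2)),
            ]) if nd else np.zeros((0, 6))
        return dets, gts

    def test_metrics_bounded_and_map50_dominates(self, rng):
        for _ in range(10):
            dets, gts = self._random_data(rng)
            tp, fp, fn = M.match_detections(dets, gts, 0.5)
            p, r = M.precision_recall(tp, fp, fn)
            m50 = M.mean_average_precision(dets, gts, (0.5,))
            m5095 = M.mean_average_precision(dets, gts, M.MAP5095_THRESHOLDS)
            for v in (p, r, m50, m5095):
                assert 0.0 <= v <= 1.0
            assert m50 >= m5095 - 1e-12

    def test_image_order_invariance(self, rng):
        dets, gts = self._random_data(rng)
        rev_d = dict(reversed(list(dets.items())))
        rev_g = dict(reversed(list(gts.items())))
        assert M.match_detections(dets, gts, 0.5) == M.match_detections(rev_d, rev_g, 0.5)
        assert M.mean_average_precision(dets, gts, (0.5,)) == pytest.approx(
            M.mean_average_precision(rev_d, rev_g, (0.5,))
        )
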