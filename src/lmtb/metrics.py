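"""Detection metrics: precision, recall and mean average precision.

Definitions follow the standard object-detection conventions:

    P = TP / (TP + FP),   R = TP / (TP + FN),
    mAP = (1/N) * sum_n  integral_0^1  P_n(R_n) dR_n

with IoU-based greedy one-to-one matching (detections visited in order of
descending confidence; each matches the highest-IoU unmatched ground truth
of its class at or above the threshold).  The AP integral uses all-points
interpolation by default; 101-point interpolation is available.  ``0/0`` is
defined as 0 throughout.

Detections are mappings ``image_id -> (n, 6) array`` of
``cls conf cx cy w h`` rows; ground truths ``image_id -> (m, 5)`` of
``cls cx cy w h``; boxes are normalised to [0, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "box_iou_xywh",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_average_precision",
    "MAP5095_THRESHOLDS",
]

MAP5095_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


def _validate_boxes(arr, width):
    a = np.asarray(arr, dtype=np.float64).reshape(-1, width)
    boxes = a[:, width - 4 :]
    if np.any(~np.isfinite(a)):
        raise ValueError("non-finite values in boxes")
    if np.any(boxes[:, 2:] < 0) or np.any(boxes[:, :2] < -0.5) or np.any(boxes[:, :2] > 1.5):
        raise ValueError("malformed normalised boxes")
    return a


def box_iou_xywh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (n, 4) and (m, 4) centre-format boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ax1, ay1 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax2, ay2 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx1, by1 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx2, by2 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    iw = np.maximum(np.minimum(ax2[:, None], bx2) - np.maximum(ax1[:, None], bx1), 0)
    ih = np.maximum(np.minimum(ay2[:, None], by2) - np.maximum(ay1[:, None], by1), 0)
    inter = iw * ih
    area_a = (ax2 - ax1) * (ay2 - ay1)
    area_b = (bx2 - bx1) * (by2 - by1)
    union = area_a[:, None] + area_b - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-16), 0.0)


def _match_one_image(dets, gts, iou_t):
    """Greedy matching in one image; returns per-detection TP flags (sorted
    by descending confidence) and the detection order used."""
    order = np.argsort(-dets[:, 1], kind="stable")
    d = dets[order]
    flags = np.zeros(len(d), dtype=bool)
    used = np.zeros(len(gts), dtype=bool)
    if len(gts):
        iou = box_iou_xywh(d[:, 2:6], gts[:, 1:5])
    for i in range(len(d)):
        if not len(gts):
            break
        cand = (~used) & (gts[:, 0] == d[i, 0]) & (iou[i] >= iou_t)
        if cand.any():
            j = np.argmax(np.where(cand, iou[i], -1.0))
            used[j] = True
            flags[i] = True
    return d, flags, used


def match_detections(dets: dict, gts: dict, iou_t: float = 0.5):
    """Dataset-level greedy matching; returns (TP, FP, FN) counts."""
    if not (0 < iou_t < 1):
        raise ValueError("IoU threshold must be in (0, 1)")
    tp = fp = fn = 0
    for img in sorted(set(dets) | set(gts)):
        d = _validate_boxes(dets.get(img, np.zeros((0, 6))), 6)
        g = _validate_boxes(gts.get(img, np.zeros((0, 5))), 5)
        _, flags, used = _match_one_image(d, g, iou_t)
        tp += int(flags.sum())
        fp += int((~flags).sum())
        fn += int((~used).sum())
    return tp, fp, fn


def precision_recall(tp: int, fp: int, fn: int):
    """P = TP/(TP+FP), R = TP/(TP+FN); 0/0 -> 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def _ap_from_flags(conf, flags, n_gt, interpolation="all"):
    if n_gt == 0:
        return 0.0
    if len(conf) == 0:
        return 0.0
    order = np.argsort(-conf, kind="stable")
    tp_cum = np.cumsum(flags[order])
    fp_cum = np.cumsum(~flags[order])
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-16)
    # precision envelope (monotone non-increasing from the right)
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    if interpolation == "101":
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(mrec, grid, side="left")
        return float(np.mean(mpre[np.minimum(idx, len(mpre) - 1)]))
    changed = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[changed + 1] - mrec[changed]) * mpre[changed + 1]))


def average_precision(dets: dict, gts: dict, iou_t: float = 0.5,
                      interpolation: str = "all") -> dict:
    """Per-class AP at one IoU threshold."""
    per_image = {}
    classes = set()
    for img in sorted(set(dets) | set(gts)):
        d = _validate_boxes(dets.get(img, np.zeros((0, 6))), 6)
        g = _validate_boxes(gts.get(img, np.zeros((0, 5))), 5)
        per_image[img] = _match_one_image(d, g, iou_t) + (g,)
        classes |= set(d[:, 0].astype(int)) | set(g[:, 0].astype(int))
    aps = {}
    for c in sorted(classes):
        conf, flags = [], []
        n_gt = 0
        for img, (d, fl, _, g) in per_image.items():
            sel = d[:, 0] == c
            conf.append(d[sel, 1])
            flags.append(fl[sel])
            n_gt += int((g[:, 0] == c).sum())
        conf = np.concatenate(conf) if conf else np.zeros(0)
        flags = np.concatenate(flags) if flags else np.zeros(0, dtype=bool)
        aps[c] = _ap_from_flags(conf, flags, n_gt, interpolation)
    return aps


def mean_average_precision(dets: dict, gts: dict, iou_list=(0.5,),
                           interpolation: str = "all") -> float:
    """Class-then-threshold averaged AP.

    ``iou_list=(0.5,)`` gives mAP50; ``MAP5095_THRESHOLDS`` gives mAP50-95.
    Classes are those present in the ground truth (a class with detections
    but no ground truth anywhere scores AP 0 and is included).
    """
    vals = []
    for t in iou_list:
        aps = average_precision(dets, gts, t, interpolation)
        if aps:
            vals.append(float(np.mean(list(aps.values()))))
    return float(np.mean(vals)) if vals else 0.0
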