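"""Detection metrics: IoU matching, precision/recall, AP/mAP, NMS.

Detections are ``(N, 6)`` arrays ``[x1, y1, x2, y2, conf, cls]``; ground
truths are ``(M, 5)`` arrays ``[x1, y1, x2, y2, cls]``.  AP uses all-point
(continuous) interpolation of the precision envelope over recall; a
101-point COCO-style mode is available for cross-checks.  A 0/0 precision
or recall is defined as 0 (logged), which occurs with empty predictions
early in training.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = ["iou_matrix", "nms", "match_and_count", "precision_recall",
           "ap", "map50", "evaluate_detections", "EvalResult"]

log = logging.getLogger(__name__)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4+) and (M,4+) corner boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(dets: np.ndarray, iou_thr: float = 0.65) -> np.ndarray:
    """Class-wise greedy non-maximum suppression."""
    dets = np.asarray(dets, dtype=np.float64).reshape(-1, 6)
    keep_rows = []
    for cls in np.unique(dets[:, 5]):
        d = dets[dets[:, 5] == cls]
        d = d[np.argsort(-d[:, 4], kind="stable")]
        kept: List[np.ndarray] = []
        for row in d:
            if not kept or iou_matrix(row[None, :4],
                                      np.array(kept)[:, :4]).max() <= iou_thr:
                kept.append(row)
        keep_rows.extend(kept)
    if not keep_rows:
        return np.zeros((0, 6))
    out = np.array(keep_rows)
    return out[np.argsort(-out[:, 4], kind="stable")]


def match_and_count(predictions: np.ndarray, truths: np.ndarray,
                    iou_thr: float = 0.5):
    """Greedy confidence-descending one-to-one matching within class.

    Returns ``(tp, fp, fn, pred_flags)`` where ``pred_flags`` marks, per
    prediction in confidence-descending order within the input, whether it
    matched a truth (for PR-curve construction).
    """
    if not 0 < iou_thr < 1:
        raise ValueError("iou_thr must lie in (0, 1)")
    preds = np.asarray(predictions, dtype=np.float64).reshape(-1, 6)
    gts = np.asarray(truths, dtype=np.float64).reshape(-1, 5)
    order = np.argsort(-preds[:, 4], kind="stable")
    flags = np.zeros(len(preds), dtype=bool)
    used = np.zeros(len(gts), dtype=bool)
    iou = iou_matrix(preds[:, :4], gts[:, :4]) if len(gts) else None
    for i in order:
        cand = np.where((~used) & (gts[:, 4] == preds[i, 5]))[0] if len(gts) else []
        if len(cand) == 0:
            continue
        ious = iou[i, cand]
        j = int(np.argmax(ious))
        if ious[j] >= iou_thr:
            used[cand[j]] = True
            flags[i] = True
    tp = int(flags.sum())
    return tp, int(len(preds) - tp), int(len(gts) - tp), flags


def precision_recall(tp: int, fp: int, fn: int) -> Tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); 0/0 is defined as 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("tallies must be non-negative")
    if tp + fp == 0 or tp + fn == 0:
        log.info("0/0 precision or recall encountered; defined as 0")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def ap(pr_points: Sequence[Tuple[float, float]], mode: str = "all_point") -> float:
    """Area under P(R) from (recall, precision) points sorted by recall.

    ``all_point`` integrates the running-max precision envelope between
    consecutive recall values; ``coco101`` averages the envelope sampled at
    101 evenly spaced recalls.
    """
    if not len(pr_points):
        return 0.0
    pts = np.asarray(pr_points, dtype=np.float64)
    r = np.concatenate([[0.0], pts[:, 0]])
    p = np.concatenate([[1.0], pts[:, 1]])
    # precision envelope (non-increasing from the right)
    env = np.maximum.accumulate(p[::-1])[::-1]
    if mode == "coco101":
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(r, grid, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        vals[grid > r[-1]] = 0.0
        return float(vals.mean())
    return float(np.sum((r[1:] - r[:-1]) * env[1:]))


def map50(ap_per_class: Dict[int, float]) -> float:
    """Unweighted mean of per-class AP."""
    if not ap_per_class:
        return 0.0
    return float(np.mean(list(ap_per_class.values())))


@dataclass
class EvalResult:
    precision: float
    recall: float
    ap_per_class: Dict[int, float]
    map50: float
    pr_curves: Dict[int, np.ndarray] = field(default_factory=dict)


def evaluate_detections(preds_per_image: Sequence[np.ndarray],
                        truths_per_image: Sequence[np.ndarray],
                        iou_thr: float = 0.5, mode: str = "all_point") -> EvalResult:
    """Dataset-level PR/AP/mAP with a full confidence sweep (threshold-free)."""
    assert len(preds_per_image) == len(truths_per_image)
    tp = fp = fn = 0
    recs: List[Tuple[float, bool, int]] = []   # (conf, matched, cls)
    npos: Dict[int, int] = {}
    for preds, gts in zip(preds_per_image, truths_per_image):
        preds = np.asarray(preds, dtype=np.float64).reshape(-1, 6)
        gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
        t, f, n, flags = match_and_count(preds, gts, iou_thr)
        tp, fp, fn = tp + t, fp + f, fn + n
        recs.extend(zip(preds[:, 4], flags, preds[:, 5].astype(int)))
        for c in gts[:, 4].astype(int):
            npos[c] = npos.get(c, 0) + 1
    p, r = precision_recall(tp, fp, fn)
    ap_pc, curves = {}, {}
    for c, n_pos in npos.items():
        crecs = sorted([(cf, mt) for cf, mt, cc in recs if cc == c],
                       key=lambda x: -x[0])
        if not crecs:
            ap_pc[c] = 0.0
            curves[c] = np.zeros((0, 2))
            continue
        matched = np.array([m for _, m in crecs], dtype=np.float64)
        ctp = np.cumsum(matched)
        cfp = np.cumsum(1.0 - matched)
        rec = ctp / n_pos
        prec = ctp / np.maximum(ctp + cfp, 1e-12)
        curves[c] = np.stack([rec, prec], axis=1)
        ap_pc[c] = ap(curves[c], mode)
    return EvalResult(p, r, ap_pc, map50(ap_pc), curves)
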