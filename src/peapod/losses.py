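"""Anchor-free detection loss: class BCE + CIoU box loss + distribution
focal loss, with task-aligned positive assignment.

This is the unmodified loss of the baseline detector family (the
architecture work changes blocks and the optimiser, not the loss).  Box
regression predicts, per anchor cell, a discrete distribution over
``reg_max`` bins for each of the four cell-to-edge distances; its
expectation decodes the box.  Positives are chosen per ground-truth box
from the anchors whose centre lies inside it, ranked by the task-aligned
metric ``cls^alpha * iou^beta``.
"""
from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .autograd import Tensor, concat
from .metrics import iou_matrix

__all__ = ["DetectionLoss", "make_anchors"]


def make_anchors(shapes: Sequence[Tuple[int, int]], strides: Sequence[int]):
    """Cell-centre anchor points (A,2) in pixels and their strides (A,)."""
    pts, sts = [], []
    for (h, w), s in zip(shapes, strides):
        cx = (np.arange(w) + 0.5) * s
        cy = (np.arange(h) + 0.5) * s
        gx, gy = np.meshgrid(cx, cy)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        sts.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(sts)


def _bce_with_logits(x: Tensor, target: np.ndarray) -> Tensor:
    t = Tensor(target)
    return x.maximum(0.0) - x * t + (1.0 + (x.abs() * -1.0).exp()).log()


def _ciou_loss(pred: Tensor, gt: np.ndarray, eps: float = 1e-7) -> Tensor:
    """1 - CIoU for (F,4) corner boxes (pred is a Tensor, gt a constant)."""
    g = Tensor(gt)
    px1, py1 = pred.slice_axis(1, 0, 1), pred.slice_axis(1, 1, 2)
    px2, py2 = pred.slice_axis(1, 2, 3), pred.slice_axis(1, 3, 4)
    gx1, gy1 = g.slice_axis(1, 0, 1), g.slice_axis(1, 1, 2)
    gx2, gy2 = g.slice_axis(1, 2, 3), g.slice_axis(1, 3, 4)
    pw, ph = (px2 - px1).clamp(eps), (py2 - py1).clamp(eps)
    gw, gh = (gx2 - gx1).clamp(eps), (gy2 - gy1).clamp(eps)
    inter = (px2.minimum(gx2) - px1.maximum(gx1)).clamp(0.0) * \
            (py2.minimum(gy2) - py1.maximum(gy1)).clamp(0.0)
    union = pw * ph + gw * gh - inter + eps
    iou = inter / union
    # squared centre distance over squared enclosing-box diagonal
    cw = px2.maximum(gx2) - px1.minimum(gx1)
    ch = py2.maximum(gy2) - py1.minimum(gy1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) * 0.25
    v = (4.0 / np.pi**2) * ((gw / gh).arctan() - (pw / ph).arctan()) ** 2
    alpha = v.data / np.maximum(1.0 - iou.data + v.data, eps)  # detached
    return (1.0 - iou + rho2 / c2 + Tensor(alpha) * v).reshape(-1)


class DetectionLoss:
    def __init__(self, num_classes: int, reg_max: int = 16,
                 strides=(8, 16, 32), topk: int = 10,
                 alpha: float = 0.5, beta: float = 6.0,
                 gain_box: float = 7.5, gain_cls: float = 0.5,
                 gain_dfl: float = 1.5):
        self.nc, self.rm = num_classes, reg_max
        self.strides = strides
        self.topk, self.alpha, self.beta = topk, alpha, beta
        self.gains = (gain_box, gain_cls, gain_dfl)

    # -- assignment (numpy, no gradients) ---------------------------------
    def _assign(self, dec_boxes, cls_prob, gts, anchors, strides):
        """Returns (fg_mask (A,), gt_index (A,), weight (A,))."""
        A = len(anchors)
        fg = np.zeros(A, dtype=bool)
        gt_idx = np.zeros(A, dtype=int)
        weight = np.zeros(A)
        if len(gts) == 0:
            return fg, gt_idx, weight
        inside = (anchors[:, 0][None] > gts[:, None, 0]) & \
                 (anchors[:, 0][None] < gts[:, None, 2]) & \
                 (anchors[:, 1][None] > gts[:, None, 1]) & \
                 (anchors[:, 1][None] < gts[:, None, 3])           # (M, A)
        iou = iou_matrix(gts[:, :4], dec_boxes)                     # (M, A)
        score = cls_prob[:, gts[:, 4].astype(int)].T                # (M, A)
        gcx = (gts[:, 0] + gts[:, 2]) / 2
        gcy = (gts[:, 1] + gts[:, 3]) / 2
        dist = np.hypot(anchors[:, 0][None] - gcx[:, None],
                        anchors[:, 1][None] - gcy[:, None])
        # distance epsilon breaks ties when iou is uniformly ~0 early on
        align = (score**self.alpha) * (iou**self.beta) + \
            1e-9 / (1.0 + dist / strides[None])
        align = np.where(inside, align, -1.0)
        cand = np.zeros_like(inside)
        k = min(self.topk, A)
        top = np.argpartition(-align, k - 1, axis=1)[:, :k]
        for m in range(len(gts)):
            sel = top[m][align[m, top[m]] > 0]
            cand[m, sel] = True
        # resolve anchors claimed by several boxes toward the best alignment
        claimed = cand.any(axis=0)
        best = np.argmax(np.where(cand, align, -np.inf), axis=0)
        fg = claimed
        gt_idx = best
        weight = np.where(fg, iou[best, np.arange(A)], 0.0).clip(0.0, 1.0)
        return fg, gt_idx, weight

    # -- loss -------------------------------------------------------------
    def __call__(self, preds: List[Tensor],
                 targets: Sequence[np.ndarray]) -> Tuple[Tensor, Dict[str, float]]:
        rm, nc = self.rm, self.nc
        B = preds[0].shape[0]
        shapes = [p.shape[2:] for p in preds]
        anchors, strides = make_anchors(shapes, self.strides)
        A = len(anchors)
        flat = concat([p.reshape(B, p.shape[1], -1).transpose((0, 2, 1))
                       for p in preds], axis=1)                    # (B, A, C)
        box_logits = flat.slice_axis(2, 0, 4 * rm)
        cls_logits = flat.slice_axis(2, 4 * rm, 4 * rm + nc)

        # decoded boxes (pixels) for assignment, detached
        bl = box_logits.data.reshape(B, A, 4, rm)
        e = np.exp(bl - bl.max(axis=3, keepdims=True))
        dist = (e / e.sum(axis=3, keepdims=True) @ np.arange(rm))   # (B, A, 4)
        dist_px = dist * strides[None, :, None]
        dec = np.stack([anchors[:, 0] - dist_px[:, :, 0],
                        anchors[:, 1] - dist_px[:, :, 1],
                        anchors[:, 0] + dist_px[:, :, 2],
                        anchors[:, 1] + dist_px[:, :, 3]], axis=2)
        cls_prob = 1.0 / (1.0 + np.exp(-cls_logits.data))

        cls_target = np.zeros((B, A, nc), dtype=np.float32)
        fg_rows, fg_gt, fg_w = [], [], []
        for b in range(B):
            gts = np.asarray(targets[b], dtype=np.float64).reshape(-1, 5)
            fg, gi, w = self._assign(dec[b], cls_prob[b], gts, anchors, strides)
            idx = np.where(fg)[0]
            for a in idx:
                cls_target[b, a, int(gts[gi[a], 4])] = w[a]
            fg_rows.append(idx + b * A)
            fg_gt.append(gts[gi[idx]] if len(idx) else np.zeros((0, 5)))
            fg_w.append(w[idx])

        norm = max(float(cls_target.sum()), 1.0)
        loss_cls = _bce_with_logits(cls_logits, cls_target).sum() * (1.0 / norm)

        fg_rows = np.concatenate(fg_rows).astype(int)
        parts: Dict[str, float] = {}
        if len(fg_rows):
            gt_boxes = np.concatenate(fg_gt)
            w = np.concatenate(fg_w)
            a_fg = anchors[fg_rows % A]
            s_fg = strides[fg_rows % A]
            box_flat = box_logits.reshape(B * A, 4 * rm).take_rows(fg_rows)
            dist_t = (box_flat.reshape(-1, 4, rm).softmax(axis=2) *
                      Tensor(np.arange(rm, dtype=np.float32))).sum(axis=2)
            # corners in per-anchor stride units: (acx - l, acy - t, acx + r, acy + b)
            acx, acy = a_fg[:, 0] / s_fg, a_fg[:, 1] / s_fg
            centre = np.stack([acx, acy, acx, acy], axis=1).astype(np.float32)
            sign = np.array([-1.0, -1.0, 1.0, 1.0], dtype=np.float32)
            pred_cor = dist_t * Tensor(sign[None, :]) + Tensor(centre)
            gt_cor = gt_boxes[:, :4] / s_fg[:, None]
            ciou = _ciou_loss(pred_cor, gt_cor.astype(np.float32))
            loss_box = (ciou * Tensor(w.astype(np.float32))).sum() * (1.0 / norm)

            # DFL towards the two integer bins around each target distance
            tgt = np.stack([acx - gt_cor[:, 0], acy - gt_cor[:, 1],
                            gt_cor[:, 2] - acx, gt_cor[:, 3] - acy], axis=1)
            tgt = np.clip(tgt, 0.0, rm - 1 - 1e-3)
            lo = np.floor(tgt).astype(int)
            frac = tgt - lo
            wmat = np.zeros((len(fg_rows), 4, rm), dtype=np.float32)
            rows = np.arange(len(fg_rows))[:, None].repeat(4, 1)
            cols = np.arange(4)[None, :].repeat(len(fg_rows), 0)
            wmat[rows, cols, lo] = 1.0 - frac
            wmat[rows, cols, np.minimum(lo + 1, rm - 1)] += frac
            wmat *= w[:, None, None]
            z = box_flat.reshape(-1, 4, rm)
            zs = z - Tensor(z.data.max(axis=2, keepdims=True))  # stable log-softmax
            logp = zs - zs.exp().sum(axis=2, keepdims=True).log()
            loss_dfl = (logp * Tensor(wmat)).sum() * (-1.0 / (norm * 4.0))
        else:
            loss_box = Tensor(0.0)
            loss_dfl = Tensor(0.0)

        gb, gc, gd = self.gains
        total = loss_box * gb + loss_cls * gc + loss_dfl * gd
        parts.update(box=float(loss_box.data), cls=float(loss_cls.data),
                     dfl=float(loss_dfl.data), total=float(total.data),
                     num_fg=int(len(fg_rows)))
        return total, parts
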