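"""Desk-scale training and evaluation driver.

``smoke_train`` optimises a detector on an in-memory dataset with Adam
(momentum 0.937), a learning rate decayed from ``lr0`` to ``lrf`` (linear by
default, cosine behind a flag) and the standard anchor-free loss.  It is a
correctness vehicle — small images and short schedules — not a production
trainer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor
from .data import BoxLabel
from .losses import DetectionLoss
from .metrics import EvalResult, evaluate_detections
from .model import PeaDetector
from .optim import Adam

__all__ = ["TrainResult", "smoke_train", "evaluate_model", "prepare_items",
           "save_checkpoint", "load_checkpoint"]


def prepare_items(items) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Normalise ``(image, labels)`` pairs to ((3,H,W) float in [0,1], (M,5))."""
    out = []
    for img, labels in items:
        arr = np.asarray(img)
        if arr.ndim == 3 and arr.shape[2] == 3:
            arr = arr.transpose(2, 0, 1)
        arr = arr.astype(np.float32)
        if arr.max() > 1.5:
            arr = arr / 255.0
        if len(labels) and isinstance(labels[0], BoxLabel):
            gts = np.array([b.as_array() for b in labels])
        else:
            gts = np.asarray(labels, dtype=np.float64).reshape(-1, 5)
        out.append((arr, gts))
    return out


@dataclass
class TrainResult:
    history: List[Dict[str, float]]
    final_eval: Optional[EvalResult]
    model: PeaDetector


def evaluate_model(model: PeaDetector, items, conf_thres: float = 0.001,
                   iou_nms: float = 0.65, iou_match: float = 0.5) -> EvalResult:
    """mAP@0.5 evaluation with a full confidence sweep (threshold-free AP)."""
    data = prepare_items(items)
    preds, truths = [], []
    for img, gts in data:
        det = model.predict(img[None], conf_thres=conf_thres, iou_thres=iou_nms)[0]
        preds.append(det)
        truths.append(gts)
    return evaluate_detections(preds, truths, iou_thr=iou_match)


def smoke_train(model: PeaDetector, train_items, val_items=None,
                epochs: int = 10, batch_size: int = 8,
                lr0: float = 1e-2, lrf: float = 1e-4,
                schedule: str = "linear", weight_decay: float = 1e-4,
                seed: int = 0, log_every: int = 1,
                checkpoint: str | Path | None = None) -> TrainResult:
    data = prepare_items(train_items)
    if not data:
        raise ValueError("empty training dataset")
    crit = DetectionLoss(model.config.num_classes, model.config.reg_max)
    opt = Adam(model.parameters(), lr=lr0, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    history = []
    for ep in range(epochs):
        if schedule == "cosine":
            frac = 0.5 * (1 + np.cos(np.pi * ep / max(1, epochs - 1)))
            opt.lr = lrf + (lr0 - lrf) * frac
        else:  # linear decay between the endpoint learning rates
            opt.lr = lr0 + (lrf - lr0) * (ep / max(1, epochs - 1))
        model.train()
        order = rng.permutation(len(data))
        losses, parts_acc = [], []
        for start in range(0, len(order), batch_size):
            batch = [data[i] for i in order[start:start + batch_size]]
            imgs = np.stack([b[0] for b in batch])
            gts = [b[1] for b in batch]
            preds = model(Tensor(imgs))
            loss, parts = crit(preds, gts)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(parts["total"])
            parts_acc.append(parts)
        rec = {"epoch": ep + 1, "lr": opt.lr,
               "loss": float(np.mean(losses)),
               "box": float(np.mean([p["box"] for p in parts_acc])),
               "cls": float(np.mean([p["cls"] for p in parts_acc])),
               "dfl": float(np.mean([p["dfl"] for p in parts_acc]))}
        if val_items is not None and ((ep + 1) % log_every == 0 or ep == epochs - 1):
            rec["val_map50"] = evaluate_model(model, val_items).map50
        history.append(rec)
    final = evaluate_model(model, val_items) if val_items is not None else None
    if checkpoint is not None:
        save_checkpoint(checkpoint, model, opt, epochs)
    return TrainResult(history, final, model)



def save_checkpoint(path, model: PeaDetector, opt: Adam, epoch: int):
    state = {f"model::{k}": v for k, v in model.state_dict().items()}
    state.update({f"opt::{k}": v for k, v in opt.state_dict().items()})
    state["epoch"] = np.array(epoch)
    np.savez(path, **state)


def load_checkpoint(path, model: PeaDetector, opt: Adam | None = None) -> int:
    with np.load(path) as d:
        model.load_state_dict({k[7:]: d[k] for k in d.files
                               if k.startswith("model::")})
        if opt is not None:
            opt.load_state_dict({k[5:]: d[k] for k in d.files
                                 if k.startswith("opt::")})
        return int(d["epoch"])
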