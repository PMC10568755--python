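"""Germination-vigor statistics and condition comparison.

Two standard indicators quantify seed vigor from a per-day germination
series: the germination rate, 100 * Nt / N (Nt seeds germinated by day t of
N sown), and the germination index, sum_t Gt / Dt (Gt seeds newly
germinated on day Dt), which weights early germination more heavily.
Detections from the per-day plate images are turned into a series by
assigning each detection to its nearest layout cell (seeds do not move in
the incubator) and taking a seed's germination day as the first day its
detection is classed as sprouted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["GerminationSeries", "germination_rate", "germination_index",
           "series_from_detections", "compare_conditions", "plot_comparison"]

log = logging.getLogger(__name__)


def germination_rate(nt: int, n: int) -> float:
    """Percentage of seeds germinated: 100 * Nt / N."""
    if n <= 0:
        raise ValueError("total seed count N must be positive")
    if not 0 <= nt <= n:
        raise ValueError(f"Nt={nt} outside [0, N={n}]")
    return 100.0 * nt / n


def germination_index(gt_by_day: Sequence[float],
                      days: Sequence[int] | None = None) -> float:
    """Germination index: sum over days of Gt / Dt (Dt 1-based)."""
    days = list(days) if days is not None else list(range(1, len(gt_by_day) + 1))
    if len(days) != len(gt_by_day):
        raise ValueError("days and Gt lengths differ")
    if any(d <= 0 for d in days):
        raise ValueError("day indices must be 1-based positive")
    if any(g < 0 for g in gt_by_day):
        raise ValueError("Gt must be non-negative")
    return float(sum(g / d for g, d in zip(gt_by_day, days)))


@dataclass
class GerminationSeries:
    """Per-day germination counts for one plate/genotype/condition."""
    plate: str
    genotype: str
    condition: str
    n_total: int
    nt: List[int]                       # cumulative germinated, day 1..T
    gt: List[int] = field(default=None)  # newly germinated per day

    def __post_init__(self):
        if self.gt is None:
            prev = 0
            self.gt = []
            for v in self.nt:
                self.gt.append(v - prev)
                prev = v
        if any(b < a for a, b in zip(self.nt, self.nt[1:])):
            raise ValueError("Nt must be non-decreasing")
        if self.nt and self.nt[-1] > self.n_total:
            raise ValueError("Nt exceeds the total seed count")
        if any(g < 0 for g in self.gt):
            raise ValueError("Gt must be non-negative")

    @property
    def days(self) -> List[int]:
        return list(range(1, len(self.nt) + 1))

    def final_rate(self) -> float:
        return germination_rate(self.nt[-1], self.n_total)

    def index(self) -> float:
        return germination_index(self.gt, self.days)


def series_from_detections(per_day_detections: Sequence[np.ndarray],
                           layout: Sequence[Tuple[float, float]],
                           n_total: int | None = None,
                           plate: str = "plate", genotype: str = "",
                           condition: str = "") -> GerminationSeries:
    """Build a series by tracking seeds through per-day detections.

    ``per_day_detections[d]`` is an (N, 6) array ``[x1,y1,x2,y2,conf,cls]``
    for day d+1; ``layout`` holds the stationary cell centres.  Each
    detection claims the nearest cell (ties and double claims resolved by
    confidence, logged); a seed's germination day is the first day its
    assigned detection has the sprout class, and germination is enforced to
    be monotone — later non-sprout detections for a germinated seed are
    treated as detector noise and logged.
    """
    centers = np.asarray(layout, dtype=np.float64)
    n_cells = len(centers)
    n_total = n_total if n_total is not None else n_cells
    event: List[Optional[int]] = [None] * n_cells
    nt = []
    for day_i, dets in enumerate(per_day_detections, start=1):
        dets = np.asarray(dets, dtype=np.float64).reshape(-1, 6)
        claim_conf = np.full(n_cells, -1.0)
        claim_cls = np.zeros(n_cells, dtype=int)
        for det in dets:
            cx, cy = (det[0] + det[2]) / 2, (det[1] + det[3]) / 2
            cell = int(np.argmin(np.hypot(centers[:, 0] - cx,
                                          centers[:, 1] - cy)))
            if det[4] > claim_conf[cell]:
                if claim_conf[cell] >= 0:
                    log.info("day %d: cell %d claimed twice; keeping the "
                             "higher-confidence detection", day_i, cell)
                claim_conf[cell] = det[4]
                claim_cls[cell] = int(det[5])
        for cell in range(n_cells):
            if claim_conf[cell] < 0:
                continue
            if claim_cls[cell] == 1 and event[cell] is None:
                event[cell] = day_i
            elif claim_cls[cell] == 0 and event[cell] is not None:
                log.info("day %d: cell %d reverted to not-sprout after "
                         "germinating on day %d; ignored (monotonicity)",
                         day_i, cell, event[cell])
        nt.append(sum(1 for e in event if e is not None and e <= day_i))
    return GerminationSeries(plate, genotype, condition, n_total, nt)


def compare_conditions(series: Sequence[GerminationSeries],
                       control: str = "CK", stress: str = "S1") -> pd.DataFrame:
    """Per-genotype and pooled germination rate/index with percent decrease.

    Replicate plates are averaged within (genotype, condition) before the
    percent-decrease computation 100 * (CK - S) / CK.  Genotypes missing
    either condition are skipped with a warning.
    """
    groups: Dict[Tuple[str, str], List[GerminationSeries]] = {}
    for s in series:
        groups.setdefault((s.genotype, s.condition), []).append(s)
    genotypes = sorted({g for g, _ in groups})
    rows = []
    for g in genotypes:
        ck = groups.get((g, control))
        st = groups.get((g, stress))
        if not ck or not st:
            log.warning("genotype %s missing %s pair; skipped", g,
                        control if not ck else stress)
            continue
        ck_rate = float(np.mean([s.final_rate() for s in ck]))
        st_rate = float(np.mean([s.final_rate() for s in st]))
        ck_gi = float(np.mean([s.index() for s in ck]))
        st_gi = float(np.mean([s.index() for s in st]))
        rows.append({
            "genotype": g,
            "rate_ck": ck_rate, "rate_stress": st_rate,
            "rate_decrease_pct": 100.0 * (ck_rate - st_rate) / ck_rate
            if ck_rate else 0.0,
            "gi_ck": ck_gi, "gi_stress": st_gi,
            "gi_decrease_pct": 100.0 * (ck_gi - st_gi) / ck_gi if ck_gi else 0.0,
        })
    df = pd.DataFrame(rows)
    if len(df):
        pooled = {
            "genotype": "pooled",
            "rate_ck": df["rate_ck"].mean(), "rate_stress": df["rate_stress"].mean(),
            "gi_ck": df["gi_ck"].mean(), "gi_stress": df["gi_stress"].mean(),
        }
        pooled["rate_decrease_pct"] = 100.0 * (
            pooled["rate_ck"] - pooled["rate_stress"]) / pooled["rate_ck"] \
            if pooled["rate_ck"] else 0.0
        pooled["gi_decrease_pct"] = 100.0 * (
            pooled["gi_ck"] - pooled["gi_stress"]) / pooled["gi_ck"] \
            if pooled["gi_ck"] else 0.0
        df = pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)
    return df


def plot_comparison(df: pd.DataFrame, path):
    """Grouped bar charts of final germination rate and index per genotype."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    body = df[df["genotype"] != "pooled"]
    x = np.arange(len(body))
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (a, b, title) in zip(axes, [
            ("rate_ck", "rate_stress", "Final germination rate (%)"),
            ("gi_ck", "gi_stress", "Germination index")]):
        ax.bar(x - 0.2, body[a], width=0.4, label="control")
        ax.bar(x + 0.2, body[b], width=0.4, label="stress")
        ax.set_xticks(x)
        ax.set_xticklabels(body["genotype"], rotation=20)
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
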