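"""Synthetic seed-plate image series with exact ground truth.

The generator emulates what the incubator camera sees: a grid of roughly
elliptical seeds on a paper-textured plate, photographed once per day.  Each
seed draws a germination day from a per-day probability curve; from that day
its germ — a quadratic Bezier stroke leaving the seed — grows monotonically.
A seed is labelled ``sprout`` exactly when the drawn germ length reaches
half the seed length (the standard visual scoring criterion), so the box
labels and the per-day germination events are consistent by construction.
Root-like clutter strokes and per-day brightness jitter provide nuisance
structure.  Appearance is chosen for controllability, not realism.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data import BoxLabel

__all__ = ["PlateSpec", "GroundTruth", "generate_plate_series",
           "series_counts_from_events"]

GERMINATION_RATIO = 0.5   # germ length >= half the seed length => sprout


@dataclass
class PlateSpec:
    grid: Tuple[int, int] = (6, 6)                   # rows x cols (36 seeds/plate)
    image_size: Tuple[int, int] = (384, 320)         # (W, H)
    seed_axes: Tuple[float, float] = (11.0, 15.0)    # semi-axis range, px
    # marginal probability of germinating on each day, given not yet germinated;
    # germination starts on day 2 and reaches ~80% of seeds by day 5
    sprout_prob_by_day: Tuple[float, ...] = (0.0, 0.4, 0.35, 0.3, 0.2)
    sprout_len_ratio: Tuple[float, float] = (0.8, 1.6)  # final germ/seed length
    growth_per_day: float = 0.35                     # ratio gained per day
    clutter_density: int = 6                         # root-like strokes per image
    brightness_jitter: Tuple[float, float] = (0.85, 1.15)
    seed: int = 0

    def __post_init__(self):
        if not all(0.0 <= p <= 1.0 for p in self.sprout_prob_by_day):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.grid[0] * self.grid[1] > 126:
            raise ValueError("grid too dense: at most 126 seeds per plate")


@dataclass
class GroundTruth:
    labels_by_day: List[List[BoxLabel]]
    events: Dict[int, Optional[int]]     # seed id -> 1-based germination day
    centers: List[Tuple[float, float]]   # layout cell centres (x, y)


def series_counts_from_events(events: Dict[int, Optional[int]],
                              n_days: int) -> Tuple[List[int], List[int]]:
    """Cumulative (Nt) and newly-germinated (Gt) counts for days 1..n_days."""
    nt, gt = [], []
    for d in range(1, n_days + 1):
        gt.append(sum(1 for e in events.values() if e == d))
        nt.append(sum(1 for e in events.values() if e is not None and e <= d))
    return nt, gt


def _paint_disk(img, x, y, r, color, soft=1.5):
    h, w = img.shape[:2]
    x0, x1 = max(0, int(x - r - 2)), min(w, int(x + r + 3))
    y0, y1 = max(0, int(y - r - 2)), min(h, int(y + r + 3))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
    a = np.clip((r - d) / soft + 0.5, 0, 1)[..., None]
    img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - a) + np.asarray(color) * a


def _bezier(p0, p1, p2, n=40):
    t = np.linspace(0, 1, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def generate_plate_series(spec: PlateSpec, n_days: int):
    """Render one image per day; returns ``(images, GroundTruth)``.

    Seeds keep their positions across days, germs grow monotonically, and a
    seed's label flips to ``sprout`` on exactly the day its germ/seed length
    ratio first reaches 0.5.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    rows, cols = spec.grid
    pitch_x, pitch_y = w / cols, h / rows
    amax = spec.seed_axes[1]
    if pitch_x < 2.2 * amax or pitch_y < 2.2 * amax:
        raise ValueError("grid too dense for the configured seed size")

    # per-seed static draws
    seeds = []
    for r in range(rows):
        for c in range(cols):
            cx = (c + 0.5) * pitch_x + rng.uniform(-2, 2)
            cy = (r + 0.5) * pitch_y + rng.uniform(-2, 2)
            a = rng.uniform(*spec.seed_axes)         # semi-major
            b = a * rng.uniform(0.75, 0.95)          # semi-minor
            theta = rng.uniform(0, np.pi)
            color = np.array([168, 180, 92]) + rng.normal(0, 8, 3)
            germ_dir = rng.uniform(0, 2 * np.pi)
            bend = rng.uniform(-0.6, 0.6)
            final_ratio = rng.uniform(*spec.sprout_len_ratio)
            seeds.append(dict(cx=cx, cy=cy, a=a, b=b, theta=theta, color=color,
                              germ_dir=germ_dir, bend=bend,
                              final_ratio=final_ratio))

    # germination day per seed (1-based); None = never within the horizon
    events: Dict[int, Optional[int]] = {}
    probs = list(spec.sprout_prob_by_day) + [0.0] * max(
        0, n_days - len(spec.sprout_prob_by_day))
    for i in range(len(seeds)):
        day = None
        for d in range(1, n_days + 1):
            if rng.random() < probs[d - 1]:
                day = d
                break
        events[i] = day

    def ratio_on(seed_idx: int, day: int) -> float:
        ev = events[seed_idx]
        if ev is None:
            return 0.0
        if day < ev - 1:
            return 0.0
        if day == ev - 1:
            return 0.25 * min(1.0, probs[ev - 1] + 0.5)  # emerging, below criterion
        r = GERMINATION_RATIO + spec.growth_per_day * (day - ev)
        return min(r, seeds[seed_idx]["final_ratio"])

    base = np.full((h, w, 3), (214, 208, 196), dtype=np.float32)
    texture = rng.normal(0, 4.0, size=(h, w, 1)).astype(np.float32)
    base = base + texture

    images, labels_by_day = [], []
    centers = [(s["cx"], s["cy"]) for s in seeds]
    for day in range(1, n_days + 1):
        img = base.copy()
        # root-like clutter crossing between seeds
        crng = np.random.default_rng(spec.seed * 7919 + day)
        for _ in range(spec.clutter_density):
            p0 = crng.uniform((0, 0), (w, h))
            p2 = crng.uniform((0, 0), (w, h))
            p1 = (p0 + p2) / 2 + crng.uniform(-40, 40, 2)
            for x, y in _bezier(p0, p1, p2, 60):
                _paint_disk(img, x, y, 1.3, (176, 160, 140))
        labels = []
        for i, s in enumerate(seeds):
            seed_len = 2 * s["a"]
            ratio = ratio_on(i, day)
            germ_pts = np.empty((0, 2))
            if ratio > 0:
                length = ratio * seed_len
                d0 = np.array([np.cos(s["germ_dir"]), np.sin(s["germ_dir"])])
                start = np.array([s["cx"], s["cy"]]) + d0 * s["b"] * 0.8
                perp = np.array([-d0[1], d0[0]])
                p2 = start + d0 * length
                p1 = start + d0 * length * 0.5 + perp * s["bend"] * length * 0.5
                germ_pts = _bezier(start, p1, p2, max(8, int(length)))
                for x, y in germ_pts:
                    _paint_disk(img, x, y, 2.4, (235, 232, 210))
            # seed body (painted after germ so the body occludes its base)
            ca, sa = np.cos(s["theta"]), np.sin(s["theta"])
            x0 = max(0, int(s["cx"] - s["a"] - 2))
            x1 = min(w, int(s["cx"] + s["a"] + 3))
            y0 = max(0, int(s["cy"] - s["a"] - 2))
            y1 = min(h, int(s["cy"] + s["a"] + 3))
            yy, xx = np.mgrid[y0:y1, x0:x1]
            u = (xx - s["cx"]) * ca + (yy - s["cy"]) * sa
            v = -(xx - s["cx"]) * sa + (yy - s["cy"]) * ca
            m = (u / s["a"]) ** 2 + (v / s["b"]) ** 2
            alpha = np.clip((1.0 - m) * 4, 0, 1)[..., None]
            shade = 1.0 - 0.25 * np.clip(m, 0, 1)[..., None]
            img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - alpha) + \
                s["color"] * shade * alpha
            # box: ellipse extent union visible germ points
            ex = np.sqrt((s["a"] * ca) ** 2 + (s["b"] * sa) ** 2)
            ey = np.sqrt((s["a"] * sa) ** 2 + (s["b"] * ca) ** 2)
            bx1, bx2 = s["cx"] - ex, s["cx"] + ex
            by1, by2 = s["cy"] - ey, s["cy"] + ey
            if len(germ_pts):
                bx1 = min(bx1, germ_pts[:, 0].min() - 2.5)
                bx2 = max(bx2, germ_pts[:, 0].max() + 2.5)
                by1 = min(by1, germ_pts[:, 1].min() - 2.5)
                by2 = max(by2, germ_pts[:, 1].max() + 2.5)
            cls = 1 if ratio >= GERMINATION_RATIO else 0
            labels.append(BoxLabel(cls, max(0.0, bx1), max(0.0, by1),
                                   min(float(w), bx2), min(float(h), by2)))
        gain = np.random.default_rng(spec.seed * 104729 + day).uniform(
            *spec.brightness_jitter)
        img = np.clip(img * gain, 0, 255).astype(np.uint8)
        images.append(img)
        labels_by_day.append(labels)
    return images, GroundTruth(labels_by_day, events, centers)
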