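"""Label-preserving image augmentation and the dataset-doubling policy.

Each augmentation is a paired transform: an image operator plus the matching
coordinate map applied to every bounding box.  Photometric operators
(brightness, Gaussian noise) leave geometry untouched; flips reflect corner
coordinates about the image frame; scaling multiplies every coordinate by
the scale factor.  The dataset policy emits exactly one augmented copy per
original image, doubling the set, with a reproducible manifest.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from PIL import Image

from .data import BoxLabel

__all__ = ["AugmentSpec", "AugmentPolicy", "transform_image",
           "transform_labels", "augment_dataset"]

log = logging.getLogger(__name__)

METHODS = ("brightness", "hflip", "vflip", "scale", "gauss_noise")


@dataclass
class AugmentSpec:
    """One augmentation: a method plus its parameters."""
    method: str
    brightness_factor: float = 1.0
    scale_s: float = 1.0
    noise_sigma: float = 10.0
    box_jitter_sigma: float = 0.0   # optional label jitter for noise; off by default
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.scale_s <= 0:
            raise ValueError("scale factor must be > 0")


def transform_image(image: np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """Apply the image half of the transform to an (H, W, 3) uint8 array."""
    if image.size == 0:
        raise ValueError("empty image")
    m = spec.method
    if m == "brightness":
        out = np.clip(image.astype(np.float32) * spec.brightness_factor, 0, 255)
        return out.astype(np.uint8)
    if m == "hflip":
        return image[:, ::-1].copy()
    if m == "vflip":
        return image[::-1].copy()
    if m == "scale":
        h, w = image.shape[:2]
        nw, nh = int(w * spec.scale_s), int(h * spec.scale_s)
        return np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    if m == "gauss_noise":
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma, size=image.shape)
        return np.clip(image.astype(np.float32) + noise, 0, 255).astype(np.uint8)
    raise AssertionError(m)


def transform_labels(labels: Sequence[BoxLabel], spec: AugmentSpec,
                     w: int, h: int) -> List[BoxLabel]:
    """Apply the coordinate map matching ``spec`` to boxes valid in (w, h).

    Corner order is re-normalised, boxes are clipped to the output frame and
    degenerate (zero-area) survivors are dropped with a logged warning.
    """
    m = spec.method
    out_w, out_h = w, h
    mapped = []
    jit = None
    if m == "gauss_noise" and spec.box_jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        jit = rng.normal(0.0, spec.box_jitter_sigma, size=(len(labels), 2))
    for i, b in enumerate(labels):
        x1, y1, x2, y2 = b.x1, b.y1, b.x2, b.y2
        if m == "hflip":
            x1, x2 = w - b.x2, w - b.x1
        elif m == "vflip":
            y1, y2 = h - b.y2, h - b.y1
        elif m == "scale":
            s = spec.scale_s
            x1, y1, x2, y2 = s * x1, s * y1, s * x2, s * y2
            out_w, out_h = int(w * s), int(h * s)
        elif m == "gauss_noise" and jit is not None:
            dx, dy = jit[i]
            x1, x2 = x1 + dx, x2 + dx
            y1, y2 = y1 + dy, y2 + dy
        # brightness (and default gauss_noise) leave coordinates unchanged
        if x1 > x2:
            x1, x2 = x2, x1
        if y1 > y2:
            y1, y2 = y2, y1
        x1, x2 = max(0.0, x1), min(float(out_w), x2)
        y1, y2 = max(0.0, y1), min(float(out_h), y2)
        if x2 - x1 <= 0 or y2 - y1 <= 0:
            log.warning("dropping degenerate box %d after %s", i, m)
            continue
        mapped.append(BoxLabel(b.cls, x1, y1, x2, y2))
    return mapped


@dataclass
class AugmentPolicy:
    """Sampling policy for the per-image augmentation draw."""
    methods: Tuple[str, ...] = METHODS
    brightness_range: Tuple[float, float] = (0.6, 1.4)
    scale_range: Tuple[float, float] = (0.7, 1.3)
    noise_sigma: float = 10.0

    def sample(self, rng: np.random.Generator, seed: int) -> AugmentSpec:
        m = self.methods[rng.integers(len(self.methods))]
        return AugmentSpec(
            method=m,
            brightness_factor=float(rng.uniform(*self.brightness_range)),
            scale_s=float(rng.uniform(*self.scale_range)),
            noise_sigma=self.noise_sigma,
            seed=seed,
        )


def augment_dataset(items, policy: AugmentPolicy | None = None, seed: int = 0):
    """Double a dataset: one augmented copy per original.

    ``items`` is a sequence of ``(image, labels)`` pairs.  Returns
    ``(augmented_items, manifest)`` where the manifest records, per copy,
    the source index, method and parameters; the output list holds the
    originals followed by their augmented copies.
    """
    if not len(items):
        raise ValueError("empty dataset")
    policy = policy or AugmentPolicy()
    rng = np.random.default_rng(seed)
    out = list(items)
    manifest = []
    for i, (img, labels) in enumerate(items):
        spec = policy.sample(rng, seed=seed * 100003 + i)
        h, w = img.shape[:2]
        out.append((transform_image(img, spec),
                    transform_labels(labels, spec, w, h)))
        manifest.append({"source": i, "method": spec.method,
                         "brightness_factor": round(spec.brightness_factor, 6),
                         "scale_s": round(spec.scale_s, 6),
                         "noise_sigma": spec.noise_sigma, "seed": spec.seed})
    return out, manifest
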