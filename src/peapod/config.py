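"""Model configuration: every architectural choice that determines the
parameter count, plus YAML round-tripping.

The default constructor is the frozen, calibrated lightweight detector
(ghost C2f stages, grouped downsamples, CARAFE neck upsampling, partial-conv
head, coordinate attention).  :meth:`ModelConfig.baseline` gives the
unmodified reference detector at the same -n scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import List

import yaml

__all__ = ["ModelConfig", "DBS_SITES"]

# Identifiers of the stride-2 downsampling units eligible for DBS replacement.
DBS_SITES = ("stem", "backbone_p2", "backbone_p3", "backbone_p4",
             "backbone_p5", "neck_p4", "neck_p5")

# Calibrated placement: every downsample whose in/out channel gcd is >= 64
# at the -n scale; the stem (gcd 1, no saving) and the narrow P2 conv stay dense.
_DEFAULT_DBS = ["backbone_p3", "backbone_p4", "backbone_p5", "neck_p4", "neck_p5"]


@dataclass
class ModelConfig:
    num_classes: int = 2
    input_size: int = 640
    width_multiple: float = 0.25
    depth_multiple: float = 0.33
    reg_max: int = 16

    use_ghost: bool = True
    ghost_primary_kernel: int = 3   # primary conv of the first GhostConv
    ghost_cheap_kernel: int = 3     # depthwise cheap transform

    dbs_placement: List[str] = field(default_factory=lambda: list(_DEFAULT_DBS))

    upsample: str = "carafe"        # carafe | bilinear | nearest
    carafe_k_up: int = 3
    carafe_k_encoder: int = 5
    carafe_sigma: int = 2
    carafe_mid_channels: int = 64
    kernel_normalizer: str = "softmax"   # softmax | sigmoid

    head: str = "pdetect"           # pdetect | standard
    pcc_ratio: int = 4
    pcc_kernel: int = 3

    use_ca: bool = True
    ca_reduction: int = 32

    seed: int = 0

    def __post_init__(self):
        if self.carafe_k_up % 2 == 0 or self.carafe_k_encoder % 2 == 0:
            raise ValueError("CARAFE kernels must be odd")
        if self.carafe_sigma < 2:
            raise ValueError("CARAFE sigma must be >= 2")
        if self.kernel_normalizer not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown kernel_normalizer {self.kernel_normalizer!r}")
        if self.upsample not in ("carafe", "bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")
        if self.head not in ("pdetect", "standard"):
            raise ValueError(f"unknown head {self.head!r}")
        unknown = set(self.dbs_placement) - set(DBS_SITES)
        if unknown:
            raise ValueError(f"unknown DBS sites {sorted(unknown)}")

    # -- presets ----------------------------------------------------------
    @classmethod
    def peas(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)

    @classmethod
    def baseline(cls, **overrides) -> "ModelConfig":
        """Unmodified -n detector: dense C2f, CBS everywhere, bilinear
        upsampling, standard decoupled head, no attention."""
        base = dict(use_ghost=False, dbs_placement=[], upsample="bilinear",
                    head="standard", use_ca=False)
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "ModelConfig":
        return replace(self, **overrides)

    # -- derived ----------------------------------------------------------
    def channels(self) -> List[int]:
        """Trunk widths (P1..P5) after the width multiple, capped at 1024."""
        base = [64, 128, 256, 512, 1024]
        return [max(8, int(round(min(c, 1024) * self.width_multiple))) for c in base]

    def depth(self, n: int) -> int:
        return max(1, round(n * self.depth_multiple))

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
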