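"""Analytic parameter and FLOP accounting.

Parameters are counted by direct enumeration of learnable arrays (BN
contributes its scale and shift, i.e. 2 per channel; biases where present).
FLOPs follow the convention ``2 * H_out * W_out * (C_in/groups * K^2 + 1) *
C_out`` per convolution — twice the multiply-accumulates plus a per-output
add — with grouped convolutions scaled down by their group count.  BN and
activations are treated as folded into the convolution; counting stops at
the raw prediction maps (no decoding post-processing).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from .autograd import Tensor, no_grad
from .nn import Conv2d, Module

__all__ = ["ComplexityReport", "count_params", "count_flops",
           "pconv_ratio", "dwconv_ratio", "report", "truncate"]


def count_params(model_or_block: Module) -> int:
    """Learnable scalar count by direct enumeration of parameter arrays."""
    return model_or_block.num_params()


def _conv_flops(m: Conv2d) -> int:
    if m.last_out_hw is None:
        raise RuntimeError("run a forward pass (or count_flops) first")
    ho, wo = m.last_out_hw
    return 2 * ho * wo * ((m.c_in // m.groups) * m.k * m.k + 1) * m.c_out


def count_flops(model_or_block: Module, input_h: int, input_w: int,
                in_channels: int = 3) -> int:
    """Total FLOPs at the given input size, from a shape-recording pass."""
    model_or_block.eval()
    with no_grad():
        model_or_block(Tensor(np.zeros((1, in_channels, input_h, input_w),
                                       dtype=np.float32)))
    return sum(_conv_flops(m) for m in model_or_block.modules()
               if isinstance(m, Conv2d))


def pconv_ratio(k: int, r: int) -> float:
    """FLOP ratio of a partial convolution block to the dense k x k conv:
    1/r^2 (partial k x k on a 1/r slice) + 1/k^2 (the 1 x 1 fusion)."""
    if k < 1 or r < 1:
        raise ValueError("k and r must be >= 1")
    return 1.0 / r**2 + 1.0 / k**2


def dwconv_ratio(c_in: int, c_out: int) -> float:
    """FLOP ratio of the grouped (depthwise-style) conv to the dense one:
    1/M with M = gcd(c_in, c_out)."""
    if c_in < 1 or c_out < 1:
        raise ValueError("channel counts must be positive")
    return 1.0 / math.gcd(c_in, c_out)


def truncate(x: float, decimals: int) -> float:
    """Truncate (not round) to the given number of decimals."""
    f = 10.0**decimals
    return math.trunc(x * f) / f


@dataclass
class ComplexityReport:
    per_block: List[Tuple[str, int, int]]
    total_params: int
    total_flops: int
    input_size: int

    def __post_init__(self):
        assert self.total_params == sum(p for _, p, _ in self.per_block)
        assert self.total_flops == sum(f for _, _, f in self.per_block)

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_block, columns=["block", "params", "flops"])
        df.loc[len(df)] = ["total", self.total_params, self.total_flops]
        return df

    def to_tsv(self, path):
        self.table().to_csv(path, sep="\t", index=False)

    def __str__(self):
        lines = [f"{'block':<12s}{'params':>12s}{'flops':>16s}"]
        for name, p, f in self.per_block:
            lines.append(f"{name:<12s}{p:>12,d}{f:>16,d}")
        lines.append(f"{'total':<12s}{self.total_params:>12,d}{self.total_flops:>16,d}")
        lines.append(f"{self.params_m:.3f} M params, {self.gflops:.1f} GFLOPs "
                     f"@ {self.input_size}")
        return "\n".join(lines)


def report(model, input_size: int | None = None) -> ComplexityReport:
    """Per-block params/FLOPs for a built detector."""
    input_size = input_size or model.config.input_size
    count_flops(model, input_size, input_size)  # records output shapes
    rows = []
    for name, child in model._children():
        if name == "config":
            continue
        p = child.num_params()
        f = sum(_conv_flops(m) for m in child.modules() if isinstance(m, Conv2d))
        rows.append((name, p, f))
    return ComplexityReport(rows, sum(p for _, p, _ in rows),
                            sum(f for _, _, f in rows), input_size)
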