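"""Module system: layers with learnable parameters, built on :mod:`peapod.autograd`.

Conventions follow the common detector stacks: convolutions carry no bias when
followed by batch normalisation, BN owns a learnable scale/shift pair per
channel plus (non-learnable) running statistics, and weight initialisation is
Kaiming-uniform with a fan-in bound.
"""
from __future__ import annotations

import math
from typing import Dict, Iterator, Tuple

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Parameter", "Sequential", "Identity",
    "Conv2d", "BatchNorm2d", "SiLU", "Sigmoid", "HSwish",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; children and parameters are discovered from attributes."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[Tuple[str, "Module"]]:
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, c in self._children():
            yield from c.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for name, c in self._children():
            yield from c.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        """Learnable scalar count by direct enumeration of parameter arrays."""
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation ------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield prefix + name, v
        for name, c in self._children():
            yield from c._named_buffers(prefix + name + ".")

    def state_dict(self) -> Dict[str, np.ndarray]:
        d = {k: p.data for k, p in self.named_parameters()}
        d.update({"buf::" + k: v for k, v in self._named_buffers()})
        return d

    def load_state_dict(self, d: Dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for k, v in d.items():
            if k.startswith("buf::"):
                tgt = bufs[k[5:]]
                np.copyto(tgt, v)
            else:
                params[k].data = np.asarray(v, dtype=np.float32).reshape(
                    params[k].shape)

    def checksum(self) -> float:
        return float(sum(float(np.abs(p.data).sum()) for p in self.parameters()))


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = list(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


# A process-wide RNG used for weight init; reseeded by model builders so two
# builds from the same seed produce identical checksums.
_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding=None, groups: int = 1, bias: bool = True):
        super().__init__()
        if min(c_in, c_out, k, stride) < 1:
            raise ValueError("conv dimensions must be positive")
        if c_in % groups or c_out % groups:
            raise ValueError(f"groups={groups} must divide c_in={c_in}, c_out={c_out}")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = c_in // groups * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(_INIT_RNG.uniform(
            -bound, bound, size=(c_out, c_in // groups, k, k)))
        self.bias = Parameter(_INIT_RNG.uniform(-bound, bound, size=(c_out,))) \
            if bias else None
        self.last_out_hw = None  # recorded on forward, used by complexity

    def forward(self, x: Tensor) -> Tensor:
        y = x.conv2d(self.weight, self.bias, self.stride, self.padding, self.groups)
        self.last_out_hw = y.shape[2:]
        return y


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            shape = (1, self.c, 1, 1)
            xhat = (x - self.running_mean.reshape(shape)) * (
                1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape)
        w = self.weight.reshape(1, self.c, 1, 1)
        b = self.bias.reshape(1, self.c, 1, 1)
        return xhat * w + b


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class HSwish(Module):
    def forward(self, x):
        return x.hswish()
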