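"""Network blocks of the lightweight germination detector.

The vocabulary follows the YOLO-family literature: CBS is conv + batch norm +
SiLU; DBS swaps the convolution for a grouped (depthwise-style) one with
``groups = gcd(c_in, c_out)``; GhostConv builds half its output channels with
a cheap depthwise transform; C2f is the split/stack/concat stage used in the
v8 backbone; CARAFE is content-aware upsampling with a predicted, normalised
reassembly kernel per output position; PCC is a partial convolution (a k x k
conv on a 1/r channel slice) followed by a 1 x 1 fusion; coordinate attention
factorises channel attention into two axis-pooled encodings.
"""
from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat
from .nn import BatchNorm2d, Conv2d, Identity, Module, Parameter, Sequential

__all__ = [
    "ConfigError", "CBS", "DBS", "GhostConv", "GhostBottleneck", "Bottleneck",
    "C2f", "SPPF", "CoordAtt", "CARAFE", "Upsample", "PCC", "Concat", "Detect",
]


class ConfigError(ValueError):
    """Raised when a block is constructed with inconsistent channel arithmetic."""


class CBS(Module):
    """k x k convolution (bias folded into BN) + batch normalisation + SiLU."""

    def __init__(self, c_in, c_out, k=1, s=1, act=True, groups=1):
        super().__init__()
        if min(c_in, c_out, k, s) < 1:
            raise ConfigError(f"CBS({c_in},{c_out},k={k},s={s}): non-positive dims")
        try:
            self.conv = Conv2d(c_in, c_out, k, stride=s, groups=groups, bias=False)
        except ValueError as e:
            raise ConfigError(f"CBS({c_in},{c_out}): {e}") from e
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class DBS(CBS):
    """CBS with a grouped convolution, groups = gcd(c_in, c_out).

    With M groups the convolution's weights and multiply-accumulates both
    shrink by a factor M relative to the dense CBS.
    """

    def __init__(self, c_in, c_out, k=3, s=1, act=True):
        super().__init__(c_in, c_out, k, s, act, groups=math.gcd(c_in, c_out))


class GhostConv(Module):
    """Two-stage convolution: a primary k x k conv produces c_out/2 channels,
    a cheap depthwise transform generates the other half, and the two are
    concatenated on the channel axis (primary half first)."""

    def __init__(self, c_in, c_out, k=1, act=True, cheap_k=5):
        super().__init__()
        if c_out % 2:
            raise ConfigError(f"GhostConv({c_in},{c_out}): c_out must be even")
        half = c_out // 2
        self.primary = CBS(c_in, half, k, act=act)
        self.cheap = CBS(half, half, cheap_k, act=act, groups=half)

    def forward(self, x):
        p = self.primary(x)
        return concat([p, self.cheap(p)], axis=1)


class GhostBottleneck(Module):
    """Ghost bottleneck: GhostConv(c -> c/2) then GhostConv(c/2 -> c, act off),
    with a residual add when ``shortcut`` and shapes permit.

    The first ghost uses a 3 x 3 primary (mirroring the 3 x 3 first conv of the
    dense bottleneck it replaces); both cheap transforms are depthwise.
    """

    def __init__(self, c, shortcut=True, primary_k=3, cheap_k=5):
        super().__init__()
        if c % 2:
            raise ConfigError(f"GhostBottleneck(c={c}): c must be even")
        self.g1 = GhostConv(c, c // 2, primary_k, act=True, cheap_k=cheap_k)
        self.g2 = GhostConv(c // 2, c, 1, act=False, cheap_k=cheap_k)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.g2(self.g1(x))
        return x + y if self.shortcut else y


class Bottleneck(Module):
    """Dense residual bottleneck of the v8 C2f stage (two 3 x 3 CBS, e=1)."""

    def __init__(self, c, shortcut=True):
        super().__init__()
        self.cv1 = CBS(c, c, 3)
        self.cv2 = CBS(c, c, 3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(Module):
    """Split into two halves, stack n bottlenecks on one branch, concatenate
    all intermediates, fuse with a 1 x 1 CBS.  ``ghost`` swaps the dense
    bottleneck for :class:`GhostBottleneck`."""

    def __init__(self, c_in, c_out, n=1, shortcut=False, ghost=False,
                 ghost_primary_k=3, ghost_cheap_k=5):
        super().__init__()
        if c_out % 2:
            raise ConfigError(f"C2f({c_in},{c_out}): c_out must be even")
        if n < 1:
            raise ConfigError(f"C2f: n={n} < 1")
        self.c = c_out // 2
        self.cv1 = CBS(c_in, 2 * self.c, 1)
        self.cv2 = CBS((2 + n) * self.c, c_out, 1)
        if ghost:
            self.blocks = [GhostBottleneck(self.c, shortcut, ghost_primary_k,
                                           ghost_cheap_k) for _ in range(n)]
        else:
            self.blocks = [Bottleneck(self.c, shortcut) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        parts = [y.slice_axis(1, 0, self.c), y.slice_axis(1, self.c, 2 * self.c)]
        for b in self.blocks:
            parts.append(b(parts[-1]))
        return self.cv2(concat(parts, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained same-padded max-pools."""

    def __init__(self, c_in, c_out, pool_k=5):
        super().__init__()
        if pool_k % 2 == 0:
            raise ConfigError(f"SPPF: pool_k={pool_k} must be odd")
        c_ = c_in // 2
        self.cv1 = CBS(c_in, c_, 1)
        self.cv2 = CBS(4 * c_, c_out, 1)
        self.k = pool_k

    def forward(self, x):
        y = self.cv1(x)
        outs = [y]
        for _ in range(3):
            outs.append(outs[-1].maxpool2d(self.k, 1, self.k // 2))
        return self.cv2(concat(outs, axis=1))


class CoordAtt(Module):
    """Coordinate attention: per-channel average pools with (H,1) and (1,W)
    kernels, a shared 1 x 1 reduce (+BN, h-swish), then two 1 x 1 expands with
    sigmoid gates applied multiplicatively along each axis."""

    def __init__(self, c, reduction=32):
        super().__init__()
        mid = max(8, c // reduction)
        self.mid = mid
        self.conv1 = Conv2d(c, mid, 1, bias=True)
        self.bn1 = BatchNorm2d(mid)
        self.conv_h = Conv2d(mid, c, 1, bias=True)
        self.conv_w = Conv2d(mid, c, 1, bias=True)

    def forward(self, x):
        B, C, H, W = x.shape
        ph = x.mean(axis=3, keepdims=True)                      # (B,C,H,1)
        pw = x.mean(axis=2, keepdims=True).transpose((0, 1, 3, 2))  # (B,C,W,1)
        y = concat([ph, pw], axis=2)
        y = self.bn1(self.conv1(y)).hswish()
        yh = y.slice_axis(2, 0, H)
        yw = y.slice_axis(2, H, H + W).transpose((0, 1, 3, 2))
        ah = self.conv_h(yh).sigmoid()                          # (B,C,H,1)
        aw = self.conv_w(yw).sigmoid()                          # (B,C,1,W)
        return x * ah * aw


class Upsample(Module):
    """Parameter-free x-sigma upsampling (nearest or bilinear)."""

    def __init__(self, scale=2, mode="bilinear"):
        super().__init__()
        self.scale, self.mode = scale, mode

    def forward(self, x):
        if self.mode == "nearest":
            return x.upsample_nearest(self.scale)
        return x.upsample_bilinear(self.scale)


class CARAFE(Module):
    """Content-aware reassembly upsampling.

    A 1 x 1 channel compressor (c -> c_mid) feeds a k_enc x k_enc content
    encoder producing sigma^2 * k_up^2 channels; pixel-shuffling spreads these
    over the sigma-H x sigma-W grid, each position's k_up^2 logits are
    normalised (softmax by default, so every kernel sums to one), and the
    output value is the dot product of that kernel with the k_up x k_up
    neighbourhood of the source position (floor(i'/sigma), floor(j'/sigma)).
    """

    def __init__(self, c, sigma=2, k_up=3, k_encoder=5, c_mid=64,
                 normalizer="softmax"):
        super().__init__()
        if k_up % 2 == 0 or k_encoder % 2 == 0:
            raise ConfigError(f"CARAFE: kernels must be odd, got {k_up}/{k_encoder}")
        if sigma < 2:
            raise ConfigError(f"CARAFE: sigma={sigma} < 2")
        if normalizer not in ("softmax", "sigmoid"):
            raise ConfigError(f"CARAFE: unknown normalizer {normalizer!r}")
        self.sigma, self.k_up, self.normalizer = sigma, k_up, normalizer
        self.compressor = Conv2d(c, c_mid, 1, bias=False)
        self.encoder = Conv2d(c_mid, sigma * sigma * k_up * k_up, k_encoder,
                              bias=False)

    def forward(self, x):
        B, C, H, W = x.shape
        s, k = self.sigma, self.k_up
        logits = self.encoder(self.compressor(x))     # (B, s^2 k^2, H, W)
        # pixel shuffle: (B, k^2, sH, sW)
        logits = logits.reshape(B, k * k, s, s, H, W)
        logits = logits.transpose((0, 1, 4, 2, 5, 3)).reshape(B, k * k, s * H, s * W)
        if self.normalizer == "softmax":
            kern = logits.softmax(axis=1)
        else:
            kern = logits.sigmoid()
        kern = kern.reshape(B, 1, k * k, s * H, s * W)
        # edge-replicated borders keep the constant-map invariant exact
        nbhd = x.pad_edge(k // 2).unfold(k)           # (B, C, k^2, H, W)
        nbhd = nbhd.reshape(B, C * k * k, H, W).upsample_nearest(s)
        nbhd = nbhd.reshape(B, C, k * k, s * H, s * W)
        return (nbhd * kern).sum(axis=2)


class PCC(Module):
    """Partial convolution + 1 x 1 fusion.

    The input is split on the channel axis: c/r channels pass through a k x k
    CBS, the remaining c - c/r are carried unchanged; concatenation restores c
    channels and a 1 x 1 CBS fuses across channels.  FLOPs relative to a dense
    k x k conv are 1/r^2 + 1/k^2.
    """

    def __init__(self, c, r=4, k=3):
        super().__init__()
        if c % r:
            raise ConfigError(f"PCC(c={c}, r={r}): r must divide c")
        self.c_slice = c // r
        self.g_partial = CBS(self.c_slice, self.c_slice, k)
        self.g_fuse = CBS(c, c, 1)

    def forward(self, x):
        c = x.shape[1]
        x2 = x.slice_axis(1, 0, self.c_slice)
        parts = [self.g_partial(x2)]
        if self.c_slice < c:
            parts.insert(0, x.slice_axis(1, self.c_slice, c))
        return self.g_fuse(concat(parts, axis=1))


class Concat(Module):
    def forward(self, xs):
        return concat(xs, axis=1)


class _DenseBranch(Module):
    def __init__(self, c_in, c_mid, c_out):
        super().__init__()
        self.body = Sequential(CBS(c_in, c_mid, 3), CBS(c_mid, c_mid, 3),
                               Conv2d(c_mid, c_out, 1, bias=True))

    def forward(self, x):
        return self.body(x)


class _PCCBranch(Module):
    """PDetect branch: 1 x 1 entry CBS, two stacked PCC blocks, 1 x 1 head."""

    def __init__(self, c_in, c_mid, c_out, r=4, k=3):
        super().__init__()
        self.body = Sequential(CBS(c_in, c_mid, 1), PCC(c_mid, r, k),
                               PCC(c_mid, r, k), Conv2d(c_mid, c_out, 1, bias=True))

    def forward(self, x):
        return self.body(x)


class Detect(Module):
    """Anchor-free decoupled detection head over three pyramid levels.

    ``pcc=False`` builds the standard head (two stacked 3 x 3 CBS per branch);
    ``pcc=True`` builds the partial-convolution head, replacing each stacked
    CBS pair by PCC blocks behind a 1 x 1 channel adapter.  Box and class
    branches are independent.  Box channels carry 4 * reg_max distribution
    bins; a frozen expectation filter (not trained) decodes them at inference.
    """

    def __init__(self, channels, num_classes=2, reg_max=16, pcc=False,
                 pcc_ratio=4, pcc_kernel=3):
        super().__init__()
        if len(channels) != 3:
            raise ConfigError(f"Detect: expected 3 pyramid levels, got {len(channels)}")
        self.nc = num_classes
        self.reg_max = reg_max
        c2 = max(16, channels[0] // 4, 4 * reg_max)
        c3 = max(channels[0], min(num_classes, 100))
        mk = (_PCCBranch if pcc else _DenseBranch)
        kw = dict(r=pcc_ratio, k=pcc_kernel) if pcc else {}
        self.box_branches = [mk(c, c2, 4 * reg_max, **kw) for c in channels]
        self.cls_branches = [mk(c, c3, num_classes, **kw) for c in channels]
        self.dfl_proj = Parameter(np.arange(reg_max, dtype=np.float32))
        self.dfl_proj.requires_grad = False

    def forward(self, feats):
        outs = []
        for f, bb, cb in zip(feats, self.box_branches, self.cls_branches):
            outs.append(concat([bb(f), cb(f)], axis=1))
        return outs
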