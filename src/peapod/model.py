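"""Assembly of the full detector graph.

Backbone: CBS/DBS stem and downsamples, (ghost) C2f stages with optional
coordinate attention after the first stage, SPPF last.  Neck: PAN-FPN with
CARAFE (or plain interpolation) at both upsample sites.  Head: anchor-free
decoupled head (standard or partial-convolution) over strides 8/16/32.
"""
from __future__ import annotations

from typing import List

import numpy as np

from . import nn
from .autograd import Tensor, concat, no_grad
from .blocks import (CARAFE, CBS, DBS, SPPF, CoordAtt, C2f, ConfigError,
                     Detect, Upsample)
from .config import ModelConfig

__all__ = ["PeaDetector", "build_model"]


class PeaDetector(nn.Module):
    """The detector as an explicit layer graph.

    ``forward`` returns three raw prediction maps, one per pyramid level,
    each with 4*reg_max box-distribution channels followed by num_classes
    class logits.
    """

    strides = (8, 16, 32)

    def __init__(self, config: ModelConfig):
        super().__init__()
        nn.seed_init(config.seed)
        self.config = config
        c1, c2, c3, c4, c5 = config.channels()
        n1, n2 = config.depth(3), config.depth(6)
        dbs = set(config.dbs_placement)

        def down(site, ci, co):
            try:
                return (DBS if site in dbs else CBS)(ci, co, 3, 2)
            except ConfigError as e:
                raise ConfigError(f"{site}: {e}") from e

        def stage(name, ci, co, n, shortcut):
            try:
                return C2f(ci, co, n, shortcut, ghost=config.use_ghost,
                           ghost_primary_k=config.ghost_primary_kernel,
                           ghost_cheap_k=config.ghost_cheap_kernel)
            except ConfigError as e:
                raise ConfigError(f"{name}: {e}") from e

        def up(c):
            if config.upsample == "carafe":
                return CARAFE(c, config.carafe_sigma, config.carafe_k_up,
                              config.carafe_k_encoder, config.carafe_mid_channels,
                              config.kernel_normalizer)
            return Upsample(2, config.upsample)

        # backbone
        self.stem = down("stem", 3, c1)
        self.down_p2 = down("backbone_p2", c1, c2)
        self.stage_p2 = stage("stage_p2", c2, c2, n1, True)
        self.ca = CoordAtt(c2, config.ca_reduction) if config.use_ca else nn.Identity()
        self.down_p3 = down("backbone_p3", c2, c3)
        self.stage_p3 = stage("stage_p3", c3, c3, n2, True)
        self.down_p4 = down("backbone_p4", c3, c4)
        self.stage_p4 = stage("stage_p4", c4, c4, n2, True)
        self.down_p5 = down("backbone_p5", c4, c5)
        self.stage_p5 = stage("stage_p5", c5, c5, n1, True)
        self.sppf = SPPF(c5, c5)

        # neck (PAN-FPN)
        self.up1 = up(c5)
        self.neck_p4 = stage("neck_p4", c5 + c4, c4, n1, False)
        self.up2 = up(c4)
        self.neck_p3 = stage("neck_p3", c4 + c3, c3, n1, False)
        self.neck_down4 = down("neck_p4", c3, c3)
        self.neck_out4 = stage("neck_out4", c3 + c4, c4, n1, False)
        self.neck_down5 = down("neck_p5", c4, c4)
        self.neck_out5 = stage("neck_out5", c4 + c5, c5, n1, False)

        self.head = Detect([c3, c4, c5], config.num_classes, config.reg_max,
                           pcc=(config.head == "pdetect"),
                           pcc_ratio=config.pcc_ratio,
                           pcc_kernel=config.pcc_kernel)

    def forward(self, x: Tensor) -> List[Tensor]:
        x = self.down_p2(self.stem(x))
        p2 = self.ca(self.stage_p2(x))
        p3 = self.stage_p3(self.down_p3(p2))
        p4 = self.stage_p4(self.down_p4(p3))
        p5 = self.sppf(self.stage_p5(self.down_p5(p4)))

        t4 = self.neck_p4(concat([self.up1(p5), p4], axis=1))
        t3 = self.neck_p3(concat([self.up2(t4), p3], axis=1))
        o4 = self.neck_out4(concat([self.neck_down4(t3), t4], axis=1))
        o5 = self.neck_out5(concat([self.neck_down5(o4), p5], axis=1))
        return self.head([t3, o4, o5])

    # -- inference decoding ----------------------------------------------
    def decode(self, preds, conf_thres=0.25, img_size=None):
        """Decode raw maps to per-image arrays of (x1,y1,x2,y2,conf,cls).

        Box distributions are collapsed to expected offsets (l,t,r,b) in
        stride units around each cell centre.
        """
        rm, nc = self.config.reg_max, self.config.num_classes
        results = None
        for lvl, p in enumerate(preds):
            arr = p.data if isinstance(p, Tensor) else np.asarray(p)
            B, _, H, W = arr.shape
            stride = (img_size // H) if img_size else self.strides[lvl]
            box = arr[:, :4 * rm].reshape(B, 4, rm, H, W)
            box = box - box.max(axis=2, keepdims=True)
            e = np.exp(box)
            dist = (e / e.sum(axis=2, keepdims=True) *
                    np.arange(rm).reshape(1, 1, rm, 1, 1)).sum(axis=2)
            cls = 1.0 / (1.0 + np.exp(-arr[:, 4 * rm:]))
            cx = (np.arange(W) + 0.5)[None, :].repeat(H, 0)
            cy = (np.arange(H) + 0.5)[:, None].repeat(W, 1)
            x1 = (cx - dist[:, 0]) * stride
            y1 = (cy - dist[:, 1]) * stride
            x2 = (cx + dist[:, 2]) * stride
            y2 = (cy + dist[:, 3]) * stride
            conf = cls.max(axis=1)
            cid = cls.argmax(axis=1)
            lvl_out = np.stack([x1, y1, x2, y2, conf, cid], axis=-1).reshape(B, -1, 6)
            results = lvl_out if results is None else np.concatenate(
                [results, lvl_out], axis=1)
        return [r[r[:, 4] >= conf_thres] for r in results]

    def predict(self, images: np.ndarray, conf_thres=0.25, iou_thres=0.65):
        """Run eval-mode inference on a (B,3,H,W) float array in [0,1];
        returns per-image arrays of (x1,y1,x2,y2,conf,cls) after NMS."""
        from .metrics import nms
        self.eval()
        with no_grad():
            preds = self.forward(Tensor(images))
        out = []
        for det in self.decode(preds, conf_thres, img_size=images.shape[-1]):
            out.append(nms(det, iou_thres))
        return out

    # -- persistence ------------------------------------------------------
    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as d:
            self.load_state_dict(dict(d))
        return self


def build_model(config: ModelConfig | None = None) -> PeaDetector:
    """Build a detector; deterministic given ``config.seed``."""
    return PeaDetector(config or ModelConfig())
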