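"""Assembly of the baseline and improved detectors.

Both share a Focus + CSPDarknet + SPP backbone and a PAN-style neck with
three detection heads at strides 8/16/32.  The improved variant replaces
every neck CSP block with :class:`~leafdet.nn.blocks.ImprovedCSP` and the two
post-upsample concatenations with :class:`~leafdet.nn.blocks.CAM` fusion.
Width/depth multiples scale channel counts and bottleneck repeats; the
defaults (0.5 / 0.33) give the small baseline configuration whose parameter
count sits near 7.1 M.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, upsample_nearest2x
from .blocks import C3, CAM, SPP, Focus, ImprovedCSP
from .layers import Conv2d, ConvBNAct, Module

__all__ = [
    "Detector",
    "build_baseline_model",
    "build_improved_model",
    "count_parameters",
]

_BASE_CHANNELS = (64, 128, 256, 512, 1024)
_BASE_DEPTHS = (3, 9, 9, 3)


def _ch(base: int, width_multiple: float) -> int:
    return max(8, int(math.ceil(base * width_multiple / 8)) * 8)


def _n(base: int, depth_multiple: float) -> int:
    return max(1, round(base * depth_multiple))


class Detector(Module):
    """Three-headed single-stage detector.

    ``forward`` takes an (n, 3, H, W) tensor with H, W divisible by 32 and
    returns three raw maps of shape (n, 3*(5+num_classes), H/s, W/s) for
    s in (8, 16, 32); decoding lives in :mod:`leafdet.infer`.
    """

    strides = (8, 16, 32)

    def __init__(
        self,
        num_classes: int,
        improved: bool,
        width_multiple: float = 0.5,
        depth_multiple: float = 0.33,
        expansion: int = 2,
    ):
        super().__init__()
        self.num_classes = num_classes
        self.improved = improved
        self.width_multiple = width_multiple
        self.depth_multiple = depth_multiple
        c1, c2, c3, c4, c5 = (_ch(c, width_multiple) for c in _BASE_CHANNELS)
        n1, n2, n3, n4 = (_n(n, depth_multiple) for n in _BASE_DEPTHS)
        no = 3 * (5 + num_classes)

        # backbone (shared by both variants)
        self.stem = Focus(3, c1)
        self.down1 = ConvBNAct(c1, c2, k=3, stride=2)
        self.stage1 = C3(c2, c2, n1)
        self.down2 = ConvBNAct(c2, c3, k=3, stride=2)
        self.stage2 = C3(c3, c3, n2)
        self.down3 = ConvBNAct(c3, c4, k=3, stride=2)
        self.stage3 = C3(c4, c4, n3)
        self.down4 = ConvBNAct(c4, c5, k=3, stride=2)
        self.spp = SPP(c5, c5)
        self.stage4 = C3(c5, c5, n4, shortcut=False)

        # neck (PAN)
        def neck_csp(cin: int, cout: int) -> Module:
            if improved:
                return ImprovedCSP(cin, cout, expansion)
            return C3(cin, cout, n4, shortcut=False)

        self.lat1 = ConvBNAct(c5, c4, k=1)
        self.fuse1 = CAM(c4, c4, c4, expansion) if improved else None
        self.neck1 = neck_csp(c4 if improved else 2 * c4, c4)
        self.lat2 = ConvBNAct(c4, c3, k=1)
        self.fuse2 = CAM(c3, c3, c3, expansion) if improved else None
        self.neck2 = neck_csp(c3 if improved else 2 * c3, c3)
        self.pan1 = ConvBNAct(c3, c3, k=3, stride=2)
        self.neck3 = neck_csp(2 * c3, c4)
        self.pan2 = ConvBNAct(c4, c4, k=3, stride=2)
        self.neck4 = neck_csp(2 * c4, c5)

        self.head_p3 = Conv2d(c3, no, k=1)
        self.head_p4 = Conv2d(c4, no, k=1)
        self.head_p5 = Conv2d(c5, no, k=1)
        self._init_head_biases()

    def _init_head_biases(self) -> None:
        # prior-driven bias init: rare-object objectness, uniform classes
        for head, stride in zip((self.head_p3, self.head_p4, self.head_p5), self.strides):
            b = head.bias.data.reshape(3, 5 + self.num_classes)
            b[:, 4] = math.log(8.0 / (640.0 / stride) ** 2)
            if self.num_classes > 1:
                b[:, 5:] = math.log(0.6 / (self.num_classes - 0.99))
            head.bias.data = b.reshape(-1)

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial dims {x.shape[2:]} must divide 32")
        x = self.stem(x)
        x = self.stage1(self.down1(x))
        p3 = self.stage2(self.down2(x))
        p4 = self.stage3(self.down3(p3))
        p5 = self.stage4(self.spp(self.down4(p4)))

        t5 = self.lat1(p5)
        u4 = upsample_nearest2x(t5)
        j4 = self.fuse1(p4, u4) if self.improved else concat([u4, p4], axis=1)
        n4 = self.neck1(j4)
        t4 = self.lat2(n4)
        u3 = upsample_nearest2x(t4)
        j3 = self.fuse2(p3, u3) if self.improved else concat([u3, p3], axis=1)
        o3 = self.neck2(j3)
        o4 = self.neck3(concat([self.pan1(o3), t4], axis=1))
        o5 = self.neck4(concat([self.pan2(o4), t5], axis=1))
        return [self.head_p3(o3), self.head_p4(o4), self.head_p5(o5)]


def build_baseline_model(
    num_classes: int,
    anchors=None,
    width_multiple: float = 0.5,
    depth_multiple: float = 0.33,
) -> Detector:
    """The original small detector configuration."""
    model = Detector(num_classes, improved=False, width_multiple=width_multiple,
                     depth_multiple=depth_multiple)
    model.anchors = anchors
    return model


def build_improved_model(
    num_classes: int,
    anchors=None,
    width_multiple: float = 0.5,
    depth_multiple: float = 0.33,
    expansion: int = 2,
) -> Detector:
    """The improved detector: ImprovedCSP neck blocks + CAM upsample fusion."""
    model = Detector(num_classes, improved=True, width_multiple=width_multiple,
                     depth_multiple=depth_multiple, expansion=expansion)
    model.anchors = anchors
    return model


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))
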