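"""The detector's building blocks.

Alongside the standard single-stage units (Focus, SPP, CSP bottleneck stack)
this module provides the improved components: a Ghost convolution that makes
half its output channels with cheap depthwise filters, the mobile
inverted-residual unit, an improved CSP block whose processed branch runs
Ghost -> {inverted residual, global-average-pool context} in parallel, the
EPSA multi-kernel split-attention block, and the CAM fusion block combining
a shallow map (global-max-pool gate) with a deep one (global-average-pool
gate) at the neck's upsample junctions.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, max_pool2d, softmax, space_to_depth2
from .layers import BatchNorm2d, Conv2d, ConvBNAct, Module, Sequential

__all__ = [
    "GhostBlock",
    "InvertedResidual",
    "Bottleneck",
    "C3",
    "ImprovedCSP",
    "EPSA",
    "CAM",
    "Focus",
    "SPP",
]


def _broadcast_spatial(pooled: Tensor, h: int, w: int) -> Tensor:
    """Broadcast an (n, c, 1, 1) descriptor back over an h x w plane."""
    return pooled * Tensor(np.ones((1, 1, h, w), dtype=np.float32))


class GhostBlock(Module):
    """Half the output channels from a dense 1x1 conv, the other half from a
    cheap depthwise 3x3 applied to the first half; the two are concatenated."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        if cout % 2:
            raise ValueError("ghost block needs an even output channel count")
        half = cout // 2
        self.primary = ConvBNAct(cin, half, k=1)
        self.cheap = ConvBNAct(half, half, k=3, groups=half)

    def forward(self, x):
        p = self.primary(x)
        return concat([p, self.cheap(p)], axis=1)


class InvertedResidual(Module):
    """Expand (1x1) -> depthwise 3x3 -> project (1x1); residual when shapes allow."""

    def __init__(self, cin: int, cout: int, expansion: int = 2, stride: int = 1):
        super().__init__()
        hidden = cin * expansion
        self.expand = ConvBNAct(cin, hidden, k=1) if expansion != 1 else None
        self.depthwise = ConvBNAct(hidden, hidden, k=3, stride=stride, groups=hidden)
        self.project = ConvBNAct(hidden, cout, k=1, act=False)
        self.use_residual = cin == cout and stride == 1

    def forward(self, x):
        y = self.expand(x) if self.expand is not None else x
        y = self.project(self.depthwise(y))
        return x + y if self.use_residual else y


class Bottleneck(Module):
    """Classic residual bottleneck used inside the baseline CSP stack."""

    def __init__(self, cin: int, cout: int, shortcut: bool = True, e: float = 1.0):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = ConvBNAct(cin, c_, k=1)
        self.cv2 = ConvBNAct(c_, cout, k=3)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """Baseline cross-stage-partial block: a bottleneck stack beside a shortcut
    branch, concatenated and fused by a final 1x1 conv."""

    def __init__(self, cin: int, cout: int, n: int = 1, shortcut: bool = True):
        super().__init__()
        c_ = cout // 2
        self.cv1 = ConvBNAct(cin, c_, k=1)
        self.cv2 = ConvBNAct(cin, c_, k=1)
        self.m = Sequential(*[Bottleneck(c_, c_, shortcut) for _ in range(n)])
        self.cv3 = ConvBNAct(2 * c_, cout, k=1)

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class ImprovedCSP(Module):
    """CSP variant with lightweight branches.

    Branch B is a plain 1x1 conv shortcut.  Branch A is a 1x1 conv followed by
    a Ghost block whose output feeds, in parallel, (i) an inverted-residual
    unit and (ii) a global-average-pool context path broadcast back over the
    spatial plane.  The three equal-width outputs are concatenated and fused
    to ``cout`` by a final 1x1 conv.
    """

    def __init__(self, cin: int, cout: int, expansion: int = 2):
        super().__init__()
        c_ = max(2, cout // 2)
        self.shortcut = ConvBNAct(cin, c_, k=1)
        self.pre = ConvBNAct(cin, c_, k=1)
        self.ghost = GhostBlock(c_, c_)
        self.invres = InvertedResidual(c_, c_, expansion)
        self.fuse = ConvBNAct(3 * c_, cout, k=1)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        b = self.shortcut(x)
        a = self.ghost(self.pre(x))
        local = self.invres(a)
        ctx = _broadcast_spatial(a.mean(axis=(2, 3), keepdims=True), h, w)
        return self.fuse(concat([local, ctx, b], axis=1))


class EPSA(Module):
    """Efficient pyramid split attention.

    Channels are split into ``len(kernels)`` groups convolved with distinct
    kernel sizes (grouped convolution keeps the larger kernels cheap); each
    split's squeezed descriptor produces channel-attention logits which are
    normalized across splits by a softmax and applied multiplicatively.
    """

    def __init__(self, c: int, kernels: tuple[int, ...] = (3, 5, 7, 9),
                 reduction: int = 4):
        super().__init__()
        g = len(kernels)
        if c % g:
            raise ValueError(f"channels {c} not divisible by {g} splits")
        self.cg = c // g

        def _groups(k: int) -> int:
            g_k = min(self.cg, 2 ** ((k - 1) // 2))
            return g_k if self.cg % g_k == 0 else 1

        self.convs = [ConvBNAct(self.cg, self.cg, k=k, groups=_groups(k)) for k in kernels]
        hidden = max(self.cg // reduction, 4)
        self.se = [
            Sequential(
                ConvBNAct(self.cg, hidden, k=1),
                Conv2d(hidden, self.cg, k=1),
            )
            for _ in kernels
        ]

    def forward(self, x):
        n = x.shape[0]
        feats = [
            conv(x[:, i * self.cg : (i + 1) * self.cg]) for i, conv in enumerate(self.convs)
        ]
        logits = [
            se(f.mean(axis=(2, 3), keepdims=True)) for f, se in zip(feats, self.se)
        ]
        stacked = concat(logits, axis=1).reshape(n, len(feats), self.cg, 1, 1)
        att = softmax(stacked, axis=1)
        weighted = [
            f * att[:, i].reshape(n, self.cg, 1, 1) for i, f in enumerate(feats)
        ]
        return concat(weighted, axis=1)


class _PooledGate(Module):
    """Sigmoid gate computed from a global pooled descriptor of the input."""

    def __init__(self, c: int, mode: str):
        super().__init__()
        self.fc = Conv2d(c, c, k=1)
        self.mode = mode

    def forward(self, x):
        pooled = (
            x.mean(axis=(2, 3), keepdims=True)
            if self.mode == "avg"
            else x.max(axis=(2, 3), keepdims=True)
        )
        return x * self.fc(pooled).sigmoid()


class CAM(Module):
    """Fusion of a shallow and a deep feature map at the shallow resolution.

    The deep side contributes a global-average-pool gated branch and an
    inverted-residual -> EPSA branch; the shallow side mirrors this with a
    global-max-pool gate (shallow maps carry texture detail that max pooling
    keeps sharp).  The four branch outputs plus both channel-aligned inputs
    are fused by elementwise addition, preserving the original signals.
    The deep input must already be at the shallow spatial size.
    """

    def __init__(self, shallow_c: int, deep_c: int, out_c: int, expansion: int = 2):
        super().__init__()
        self.align_s = ConvBNAct(shallow_c, out_c, k=1)
        self.align_d = ConvBNAct(deep_c, out_c, k=1)
        self.gate_d = _PooledGate(out_c, "avg")
        self.gate_s = _PooledGate(out_c, "max")
        self.branch_d = Sequential(InvertedResidual(out_c, out_c, expansion), EPSA(out_c))
        self.branch_s = Sequential(InvertedResidual(out_c, out_c, expansion), EPSA(out_c))

    def forward(self, shallow, deep):
        if shallow.shape[2:] != deep.shape[2:]:
            raise ValueError(
                f"deep input must be upsampled to the shallow size first: "
                f"{deep.shape[2:]} vs {shallow.shape[2:]}"
            )
        s = self.align_s(shallow)
        d = self.align_d(deep)
        return self.gate_d(d) + self.branch_d(d) + self.gate_s(s) + self.branch_s(s) + s + d


class Focus(Module):
    """2x2 space-to-depth followed by a convolution (stem of the backbone)."""

    def __init__(self, cin: int, cout: int, k: int = 3):
        super().__init__()
        self.conv = ConvBNAct(4 * cin, cout, k=k)

    def forward(self, x):
        return self.conv(space_to_depth2(x))


class SPP(Module):
    """Spatial pyramid pooling: parallel stride-1 max pools, concatenated."""

    def __init__(self, cin: int, cout: int, ks: tuple[int, ...] = (5, 9, 13)):
        super().__init__()
        c_ = cin // 2
        self.cv1 = ConvBNAct(cin, c_, k=1)
        self.cv2 = ConvBNAct(c_ * (len(ks) + 1), cout, k=1)
        self.ks = ks

    def forward(self, x):
        y = self.cv1(x)
        pools = [max_pool2d(y, k) for k in self.ks]
        return self.cv2(concat([y] + pools, axis=1))
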