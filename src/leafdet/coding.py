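"""Decoding raw head outputs into boxes, and the inverse encoding map.

A detection head predicts, per (cell, anchor), four unbounded reals
``tx, ty, tw, th``.  The center logits are squashed and added to the cell's
integer coordinates; the size logits rescale the anchor prior.

Two center decoders are provided:

* ``decode_center_original`` — offset ``2*sigmoid(t) - 0.5``, open range
  (-0.5, 1.5).  The endpoints are unattainable: predicting a center on a
  neighbouring cell's far boundary would need an infinite logit.
* ``decode_center_improved`` — offset ``clamp(2.2*sigmoid(t) - 0.6, -0.5, 1.5)``.
  The widened pre-clamp range (-0.6, 1.6) makes both endpoints attainable at
  finite logits; the hard clamp then restores the [-0.5, 1.5] range that the
  4-grid assignment scheme relies on.

Size decoding ``bw = pw * (2*sigmoid(tw))^2`` (range (0, 4*pw)) is shared by
both schemes.  Offsets are in grid units; multiply by the grid stride for
pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridCell",
    "AnchorPrior",
    "sigmoid",
    "inv_sigmoid",
    "decode_center_original",
    "decode_center_improved",
    "decode_size",
    "encode_center_improved",
    "encode_size",
    "OFFSET_GAIN",
    "OFFSET_BIAS",
    "OFFSET_MIN",
    "OFFSET_MAX",
]

# improved-decoder constants: offset = clamp(GAIN * sigmoid(t) - BIAS, MIN, MAX)
OFFSET_GAIN = 2.2
OFFSET_BIAS = 0.6
OFFSET_MIN = -0.5
OFFSET_MAX = 1.5


@dataclass(frozen=True)
class GridCell:
    """A cell of a detection grid, addressed by its upper-left corner."""

    cx: int
    cy: int
    stride: int = 1


@dataclass(frozen=True)
class AnchorPrior:
    """Anchor prior size in pixels."""

    pw: float
    ph: float

    def __post_init__(self) -> None:
        if not (self.pw > 0 and self.ph > 0):
            raise ValueError(f"anchor sides must be positive: ({self.pw}, {self.ph})")


def sigmoid(t):
    t = np.asarray(t, dtype=np.float64)
    out = np.where(t >= 0, 1.0 / (1.0 + np.exp(-np.abs(t))), np.exp(-np.abs(t)) / (1.0 + np.exp(-np.abs(t))))
    return float(out) if out.ndim == 0 else out


def inv_sigmoid(p):
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("inverse sigmoid requires p in (0, 1)")
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def decode_center_original(tx: float, ty: float, cell: GridCell) -> tuple[float, float]:
    """Original decoder: ``b = (2*sigmoid(t) - 0.5) + c`` (grid units)."""
    return (
        2.0 * sigmoid(tx) - 0.5 + cell.cx,
        2.0 * sigmoid(ty) - 0.5 + cell.cy,
    )


def decode_center_improved(tx: float, ty: float, cell: GridCell) -> tuple[float, float]:
    """Widened-and-clamped decoder: ``b = clamp(2.2*sigmoid(t) - 0.6) + c``."""
    ox = min(max(OFFSET_GAIN * sigmoid(tx) - OFFSET_BIAS, OFFSET_MIN), OFFSET_MAX)
    oy = min(max(OFFSET_GAIN * sigmoid(ty) - OFFSET_BIAS, OFFSET_MIN), OFFSET_MAX)
    return (ox + cell.cx, oy + cell.cy)


def decode_size(tw: float, th: float, anchor: AnchorPrior) -> tuple[float, float]:
    """Size decoder ``bw = pw * (2*sigmoid(tw))^2``, in pixels, range (0, 4*pw)."""
    return (
        anchor.pw * (2.0 * sigmoid(tw)) ** 2,
        anchor.ph * (2.0 * sigmoid(th)) ** 2,
    )


def encode_center_improved(offset: float) -> float:
    """Inverse of the improved center decoder on its attainable range.

    Maps an offset in [-0.5, 1.5] to the finite logit solving
    ``2.2*sigmoid(t) - 0.6 = offset``; boundary offsets map to the finite
    pre-clamp solutions.
    """
    if not (OFFSET_MIN <= offset <= OFFSET_MAX):
        raise ValueError(f"offset {offset} outside [{OFFSET_MIN}, {OFFSET_MAX}]")
    return inv_sigmoid((offset + OFFSET_BIAS) / OFFSET_GAIN)


def encode_size(b: float, p: float) -> float:
    """Inverse of ``decode_size`` for one side: defined for b/p in (0, 4)."""
    r = b / p
    if not (0.0 < r < 4.0):
        raise ValueError(f"size ratio {r} outside (0, 4): not representable")
    return inv_sigmoid(math.sqrt(r) / 2.0)
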