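"""Axis-aligned box representations, pairwise geometry and IoU-family losses.

The coordinate convention throughout is the image convention: x grows to the
right, y grows downward, so the "upper-left corner" of a box is its
(min-x, min-y) corner.

Four losses are provided:

* ``bce_loss`` — mean binary cross-entropy over a batch of probabilities.
* ``giou_loss`` — ``1 - IoU + (Ac - u)/Ac`` with ``Ac`` the area of the
  minimal enclosing rectangle and ``u`` the union area.
* ``diou`` / ``diou_loss`` — distance-IoU, ``IoU - rho2(b, b_gt)/c2`` where
  ``rho2`` is the squared centroid distance and ``c2`` the squared diagonal
  of the enclosing rectangle.
* ``improved_diou`` / ``improved_diou_loss`` — a DIoU variant that adds the
  squared upper-left-corner distance to the penalty denominator and scales
  the penalty by a width-ratio factor ``(w/w_gt - 1)^2 + 1``.  The extra
  terms stop the optimiser from shrinking/growing a disjoint prediction to
  cheapen the penalty, which matters for small, dense lesions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BoxCXCYWH",
    "BoxXYXY",
    "BoxPairGeometry",
    "pair_geometry",
    "bce_loss",
    "giou_loss",
    "diou",
    "diou_loss",
    "improved_diou",
    "improved_diou_loss",
]

BCE_EPS = 1e-7


@dataclass(frozen=True)
class BoxCXCYWH:
    """Box as (center-x, center-y, width, height); units are the caller's."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"degenerate box: w={self.w}, h={self.h} (must be > 0)")

    def to_xyxy(self) -> "BoxXYXY":
        return BoxXYXY(
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class BoxXYXY:
    """Box as corner pair (x1, y1) top-left, (x2, y2) bottom-right."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(
                f"degenerate box: ({self.x1},{self.y1},{self.x2},{self.y2})"
            )

    def to_cxcywh(self) -> BoxCXCYWH:
        return BoxCXCYWH(
            (self.x1 + self.x2) / 2.0,
            (self.y1 + self.y2) / 2.0,
            self.x2 - self.x1,
            self.y2 - self.y1,
        )

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


@dataclass(frozen=True)
class BoxPairGeometry:
    """Derived quantities of a (prediction, ground truth) box pair.

    Attributes
    ----------
    iou : intersection over union, in [0, 1].
    union_area : area of the union of the two boxes.
    enclose_area : area of the minimal axis-aligned rectangle containing both.
    enclose_diag_sq : squared diagonal length of that enclosing rectangle.
    center_dist_sq : squared Euclidean distance between the two centroids.
    corner_dist_sq : squared distance between the two upper-left corners.
    width_pred, width_gt : widths of prediction and ground truth.
    """

    iou: float
    union_area: float
    enclose_area: float
    enclose_diag_sq: float
    center_dist_sq: float
    corner_dist_sq: float
    width_pred: float
    width_gt: float


def pair_geometry(pred: BoxCXCYWH, gt: BoxCXCYWH) -> BoxPairGeometry:
    """Compute all pairwise geometric quantities used by the box losses."""
    p, g = pred.to_xyxy(), gt.to_xyxy()

    ix = max(0.0, min(p.x2, g.x2) - max(p.x1, g.x1))
    iy = max(0.0, min(p.y2, g.y2) - max(p.y1, g.y1))
    inter = ix * iy
    union = p.area + g.area - inter

    ex1, ey1 = min(p.x1, g.x1), min(p.y1, g.y1)
    ex2, ey2 = max(p.x2, g.x2), max(p.y2, g.y2)
    ew, eh = ex2 - ex1, ey2 - ey1

    return BoxPairGeometry(
        iou=inter / union,
        union_area=union,
        enclose_area=ew * eh,
        enclose_diag_sq=ew * ew + eh * eh,
        center_dist_sq=(pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2,
        corner_dist_sq=(p.x1 - g.x1) ** 2 + (p.y1 - g.y1) ** 2,
        width_pred=pred.w,
        width_gt=gt.w,
    )


def bce_loss(y: Sequence[float], x: Sequence[float]) -> float:
    """Mean binary cross-entropy of probabilities ``x`` against labels ``y``.

    Probabilities are clamped to [eps, 1-eps] with eps = 1e-7 so a hard 0/1
    prediction does not produce an infinite loss.
    """
    y_arr = np.asarray(y, dtype=np.float64)
    x_arr = np.asarray(x, dtype=np.float64)
    if y_arr.size == 0 or y_arr.shape != x_arr.shape:
        raise ValueError("labels and probabilities must be equal-length and non-empty")
    x_arr = np.clip(x_arr, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y_arr * np.log(x_arr) + (1.0 - y_arr) * np.log(1.0 - x_arr)))


def giou_loss(pred: BoxCXCYWH, gt: BoxCXCYWH) -> float:
    """Generalised-IoU loss: ``1 - IoU + (Ac - u)/Ac``; lies in [0, 2)."""
    geo = pair_geometry(pred, gt)
    return 1.0 - geo.iou + (geo.enclose_area - geo.union_area) / geo.enclose_area


def diou(pred: BoxCXCYWH, gt: BoxCXCYWH) -> float:
    """Distance-IoU: ``IoU - rho2(b, b_gt) / c2``; lies in (-1, 1]."""
    geo = pair_geometry(pred, gt)
    return geo.iou - geo.center_dist_sq / geo.enclose_diag_sq


def diou_loss(pred: BoxCXCYWH, gt: BoxCXCYWH) -> float:
    return 1.0 - diou(pred, gt)


def improved_diou(pred: BoxCXCYWH, gt: BoxCXCYWH) -> float:
    """DIoU with corner-distance denominator and width-ratio penalty factor.

    ``IoU - rho2(b, b_gt) / (rho2(l, l_gt) + c2) * ((w/w_gt - 1)^2 + 1)``
    where ``l`` denotes a box's upper-left corner.  Against plain DIoU the
    penalty can no longer be diluted by inflating the prediction (which grows
    ``c2``): the corner term grows along with it and the width-ratio factor
    multiplies the penalty whenever the predicted width deviates from the
    ground truth in either direction.  The factor uses widths only.
    """
    if gt.w <= 0:
        raise ValueError("ground-truth width must be positive")
    geo = pair_geometry(pred, gt)
    ratio = geo.width_pred / geo.width_gt
    penalty = geo.center_dist_sq / (geo.corner_dist_sq + geo.enclose_diag_sq)
    return geo.iou - penalty * ((ratio - 1.0) ** 2 + 1.0)


def improved_diou_loss(pred: BoxCXCYWH, gt: BoxCXCYWH) -> float:
    return 1.0 - improved_diou(pred, gt)


def fig5a_pair(w: float = 1.0, scale: float = 1.0) -> tuple[BoxCXCYWH, BoxCXCYWH]:
    """The canonical disjoint configuration: equal squares of side ``w`` with
    centroids ``2w`` apart horizontally; ``scale`` rescales the predicted
    square about its fixed centroid."""
    gt = BoxCXCYWH(0.0, 0.0, w, w)
    pred = BoxCXCYWH(2.0 * w, 0.0, scale * w, scale * w)
    return pred, gt
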