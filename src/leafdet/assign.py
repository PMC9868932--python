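"""Positive-sample construction: which (scale, cell, anchor) triples are
responsible for each ground-truth box.

A ground-truth center falling in a cell makes that cell a predictor.  Two
axis-aligned neighbours are added on the side of the nearer half of the cell
(the classic 3-cell rule); the extended 4-cell rule additionally takes the
diagonal neighbour completing that 2x2 quadrant — the only further adjacent
cell whose center offset still fits the decodable [-0.5, 1.5] range.  More
cells per ground truth means more positive samples per image, which is what
makes the scheme pay off on scenes with many small lesions.

Anchors are matched by the width/height ratio rule: anchor i matches a target
iff max(w/pw, pw/w, h/ph, ph/h) < ratio_threshold (default 4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .coding import OFFSET_MAX, OFFSET_MIN, AnchorPrior, GridCell

__all__ = [
    "GroundTruthBox",
    "FeatureGrid",
    "Assignment",
    "select_cells",
    "match_anchors",
    "build_targets",
    "DEFAULT_RATIO_THRESHOLD",
]

DEFAULT_RATIO_THRESHOLD = 4.0


@dataclass(frozen=True)
class GroundTruthBox:
    """A labelled box in normalized image coordinates (all fields in [0, 1])."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        if not (self.w > 0 and self.h > 0):
            raise ValueError("box sides must be positive")
        if not (
            0.0 <= self.cx - self.w / 2
            and self.cx + self.w / 2 <= 1.0
            and 0.0 <= self.cy - self.h / 2
            and self.cy + self.h / 2 <= 1.0
        ):
            raise ValueError("box must lie inside the unit square")


@dataclass(frozen=True)
class FeatureGrid:
    """A detection-head lattice: ``nx * ny`` cells of ``stride`` pixels."""

    stride: int
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")


@dataclass(frozen=True)
class Assignment:
    """One positive training sample."""

    scale: int
    cell: GridCell
    anchor: int
    offset_x: float
    offset_y: float
    target_w: float  # pixels
    target_h: float  # pixels
    class_id: int


def select_cells(
    center: tuple[float, float], grid: FeatureGrid, extended: bool = True
) -> set[tuple[int, int]]:
    """Cells responsible for a center at ``(gx, gy)`` grid units.

    Ties at a fractional part of exactly 0.5 resolve to the right (x) and
    upward (y) neighbour.  Cells outside the grid are dropped.
    """
    gx, gy = center
    if not (0.0 <= gx < grid.nx and 0.0 <= gy < grid.ny):
        raise ValueError(f"center {center} outside {grid.nx}x{grid.ny} grid")
    i, j = int(gx), int(gy)
    fx, fy = gx - i, gy - j
    # neighbour on the nearer x-half; ties go right / up (y decreasing)
    dx = -1 if fx < 0.5 else 1
    dy = -1 if fy <= 0.5 else 1
    cells = {(i, j), (i + dx, j), (i, j + dy)}
    if extended:
        cells.add((i + dx, j + dy))
    return {
        (x, y) for (x, y) in cells if 0 <= x < grid.nx and 0 <= y < grid.ny
    }


def match_anchors(
    gt_wh: tuple[float, float],
    anchors: Sequence[AnchorPrior],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> set[int]:
    """Indices of anchors whose shape is within ``ratio_threshold`` of the target."""
    w, h = gt_wh
    if w <= 0 or h <= 0:
        raise ValueError("target sides must be positive")
    out = set()
    for i, a in enumerate(anchors):
        worst = max(w / a.pw, a.pw / w, h / a.ph, a.ph / h)
        if worst < ratio_threshold:
            out.add(i)
    return out


def build_targets(
    gts: Iterable[GroundTruthBox],
    anchor_sets: Sequence[Sequence[AnchorPrior]],
    grids: Sequence[FeatureGrid],
    extended: bool = True,
    input_size: int | None = None,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> list[Assignment]:
    """Enumerate every positive sample for a scene.

    One :class:`Assignment` is emitted per (matched anchor x selected cell x
    ground truth) on each scale.  ``input_size`` (pixels) converts normalized
    ground-truth sizes to pixels; it defaults to ``stride * nx`` of each grid.
    Duplicate (cell, anchor) claims from different ground truths are all kept.
    """
    if len(anchor_sets) != len(grids):
        raise ValueError("one anchor group per grid required")
    out: list[Assignment] = []
    for scale, (anchors, grid) in enumerate(zip(anchor_sets, grids)):
        size_px = input_size if input_size is not None else grid.stride * grid.nx
        for gt in gts:
            w_px, h_px = gt.w * size_px, gt.h * size_px
            matched = match_anchors((w_px, h_px), anchors, ratio_threshold)
            if not matched:
                continue
            gx = min(gt.cx * grid.nx, grid.nx - 1e-9)
            gy = min(gt.cy * grid.ny, grid.ny - 1e-9)
            for (cx, cy) in sorted(select_cells((gx, gy), grid, extended)):
                ox, oy = gx - cx, gy - cy
                assert OFFSET_MIN <= ox <= OFFSET_MAX and OFFSET_MIN <= oy <= OFFSET_MAX
                for a in sorted(matched):
                    out.append(
                        Assignment(
                            scale=scale,
                            cell=GridCell(cx, cy, grid.stride),
                            anchor=a,
                            offset_x=ox,
                            offset_y=oy,
                            target_w=w_px,
                            target_h=h_px,
                            class_id=gt.class_id,
                        )
                    )
    return out
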