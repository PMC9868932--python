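"""k-means anchor clustering under the IoU distance ``d = 1 - IoU``.

Anchor priors are cluster centers of the dataset's box (width, height)
distribution.  Distances between a box and a candidate center are measured by
placing the two boxes concentrically and taking ``1 - IoU``, so a center is
"close" to a box if the two shapes overlap well regardless of absolute
position.  Centroids are updated as the per-cluster arithmetic mean of
(w, h); iteration stops when assignments no longer change.

The nine resulting anchors are split into three area-sorted triples; the
smallest triple serves the stride-8 (highest-resolution) head where small
lesions live, the largest the stride-32 head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coding import AnchorPrior

__all__ = ["WHSample", "AnchorSet", "iou_wh", "kmeans_anchors", "group_by_scale"]


@dataclass(frozen=True)
class WHSample:
    """A box size sample in pixels."""

    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError("sample sides must be positive")


@dataclass
class AnchorSet:
    """Nine anchors ordered by ascending area, grouped into three scales."""

    pairs: list[tuple[float, float]]
    mean_iou: float = 0.0
    groups: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups and len(self.pairs) % 3 == 0:
            self.groups = group_by_scale(self.pairs)

    def to_anchor_priors(self) -> list[list[AnchorPrior]]:
        return [[AnchorPrior(w, h) for (w, h) in g] for g in self.groups]


def iou_wh(a, b) -> float:
    """IoU of two box shapes placed concentrically."""
    wa, ha = (a.w, a.h) if isinstance(a, WHSample) else a
    wb, hb = (b.w, b.h) if isinstance(b, WHSample) else b
    inter = min(wa, wb) * min(ha, hb)
    return inter / (wa * ha + wb * hb - inter)


def _iou_matrix(wh: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise concentric IoU, shape (n_samples, k)."""
    inter = np.minimum(wh[:, None, 0], centers[None, :, 0]) * np.minimum(
        wh[:, None, 1], centers[None, :, 1]
    )
    areas = wh[:, 0] * wh[:, 1]
    careas = centers[:, 0] * centers[:, 1]
    return inter / (areas[:, None] + careas[None, :] - inter)


def kmeans_anchors(
    samples: Sequence[WHSample] | np.ndarray,
    k: int = 9,
    seed: int = 0,
    max_iter: int = 300,
    init: str = "random",
    n_init: int = 30,
) -> AnchorSet:
    """Cluster box sizes into ``k`` anchors under the ``1 - IoU`` distance.

    Parameters
    ----------
    samples : box (w, h) samples, at least ``k`` of them.
    seed : RNG seed; initial centers are ``k`` distinct samples drawn by index.
    init : ``"random"`` (seeded index draw) or ``"kmeans++"`` (distance-
        proportional seeding under the IoU distance).
    n_init : number of seeded restarts; the run with the smallest mean
        ``1 - IoU`` distance wins (k-means is sensitive to initialization).
    """
    wh = np.asarray(
        [(s.w, s.h) if isinstance(s, WHSample) else tuple(s) for s in samples],
        dtype=np.float64,
    )
    n = len(wh)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if np.any(wh <= 0):
        raise ValueError("all sample sides must be positive")

    rng = np.random.default_rng(seed)
    uniq = np.unique(wh, axis=0)
    best: tuple[float, np.ndarray] | None = None
    for _restart in range(max(1, n_init)):
        if init == "kmeans++":
            centers = [uniq[rng.integers(len(uniq))]]
            while len(centers) < k:
                d = 1.0 - _iou_matrix(wh, np.asarray(centers)).max(axis=1)
                p = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
                centers.append(wh[rng.choice(n, p=p)])
            centers = np.asarray(centers)
        elif len(uniq) <= k:
            # degenerate data: fewer distinct shapes than clusters
            centers = uniq[np.resize(np.arange(len(uniq)), k)].astype(np.float64)
        else:
            centers = uniq[rng.choice(len(uniq), size=k, replace=False)].astype(
                np.float64
            )

        labels = np.full(n, -1)
        for _ in range(max_iter):
            iou = _iou_matrix(wh, centers)
            new_labels = iou.argmax(axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = wh[labels == j]
                if len(members):
                    centers[j] = members.mean(axis=0)
                else:  # re-seed an empty cluster on the worst-covered sample
                    centers[j] = wh[(1.0 - iou.max(axis=1)).argmax()]

        mean_dist = float(1.0 - _iou_matrix(wh, centers).max(axis=1).mean())
        if best is None or mean_dist < best[0]:
            best = (mean_dist, centers.copy())

    mean_dist, centers = best
    order = np.lexsort((centers[:, 1], centers[:, 0], centers[:, 0] * centers[:, 1]))
    pairs = [(float(w), float(h)) for w, h in centers[order]]
    return AnchorSet(pairs=pairs, mean_iou=1.0 - mean_dist)


def group_by_scale(pairs: Sequence[tuple[float, float]]) -> list[list[tuple[float, float]]]:
    """Split anchors into three ascending-area triples (ties: width, then height)."""
    if len(pairs) % 3 != 0:
        raise ValueError("anchor count must be divisible by 3")
    ordered = sorted(pairs, key=lambda p: (p[0] * p[1], p[0], p[1]))
    third = len(ordered) // 3
    return [ordered[i * third : (i + 1) * third] for i in range(3)]
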