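"""Detection evaluation: precision, recall, per-class AP, F1 and mAP@0.5.

Matching follows the PASCAL-VOC protocol: detections are visited in order of
descending confidence; each claims the unmatched same-class, same-image
ground truth of highest IoU, and is a true positive iff that IoU reaches the
threshold (default 0.5).  A ground truth can be consumed once; later
detections on it are false positives.  Per-class AP is the area under the
monotone (all-point interpolated) precision-recall envelope, and mAP is the
unweighted mean of per-class APs over the classes present in the ground
truth.

Precision/recall are reported at the operating point of all detections above
the configured confidence floor; F1 is reported at the confidence threshold
that maximises it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .boxes import BoxXYXY

__all__ = [
    "Detection",
    "GTRecord",
    "EvalSummary",
    "box_iou_xyxy",
    "match_detections",
    "precision_recall",
    "average_precision",
    "evaluate",
    "write_report",
]


@dataclass(frozen=True)
class Detection:
    image_id: int | str
    class_id: int
    confidence: float
    box: BoxXYXY

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class GTRecord:
    image_id: int | str
    class_id: int
    box: BoxXYXY


@dataclass
class EvalSummary:
    ap_per_class: dict[int, float]
    map50: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    iou_threshold: float = 0.5
    f1_confidence: float = 0.0


def box_iou_xyxy(a: BoxXYXY, b: BoxXYXY) -> float:
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GTRecord],
    iou_thr: float = 0.5,
) -> tuple[list[Detection], np.ndarray, int]:
    """Greedy confidence-ordered matching.

    Returns (detections sorted by descending confidence, boolean TP flag per
    sorted detection, count of unmatched ground truths = FN).
    """
    if not (0.0 < iou_thr < 1.0):
        raise ValueError("iou_thr must lie in (0, 1)")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    ranked = [dets[i] for i in order]
    consumed = [False] * len(gts)
    flags = np.zeros(len(ranked), dtype=bool)
    for di, det in enumerate(ranked):
        best_iou, best_gi = 0.0, -1
        for gi, gt in enumerate(gts):
            if consumed[gi] or gt.image_id != det.image_id or gt.class_id != det.class_id:
                continue
            iou = box_iou_xyxy(det.box, gt.box)
            if iou > best_iou:
                best_iou, best_gi = iou, gi
        if best_gi >= 0 and best_iou >= iou_thr:
            flags[di] = True
            consumed[best_gi] = True
    fn = consumed.count(False)
    return ranked, flags, fn


def precision_recall(flags: np.ndarray, n_gt: int) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); 0 on an empty denominator."""
    tp = int(np.sum(flags))
    n_det = len(flags)
    p = tp / n_det if n_det else 0.0
    r = tp / n_gt if n_gt else 0.0
    return p, r


def average_precision(flags: np.ndarray, n_gt: int) -> float:
    """All-point interpolated area under the precision-recall curve.

    ``flags`` must be ordered by descending confidence.  The precision curve
    is made monotone non-increasing (the envelope) before integrating over
    recall.
    """
    if n_gt == 0:
        return 0.0
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # envelope: running maximum from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap)


def evaluate(
    dets: Sequence[Detection],
    gts: Sequence[GTRecord],
    iou_thr: float = 0.5,
    conf_floor: float = 0.001,
) -> EvalSummary:
    """Full evaluation: per-class AP, mAP, operating-point P/R and best-F1."""
    dets = [d for d in dets if d.confidence >= conf_floor]
    classes = sorted({g.class_id for g in gts})
    ap_per_class: dict[int, float] = {}
    all_conf: list[float] = []
    all_flags: list[bool] = []
    total_fn = 0
    for c in classes:
        c_dets = [d for d in dets if d.class_id == c]
        c_gts = [g for g in gts if g.class_id == c]
        ranked, flags, fn = match_detections(c_dets, c_gts, iou_thr)
        ap_per_class[c] = average_precision(flags, len(c_gts))
        all_conf.extend(d.confidence for d in ranked)
        all_flags.extend(bool(f) for f in flags)
        total_fn += fn
    # detections whose class never occurs in the ground truth are plain FPs
    for d in dets:
        if d.class_id not in classes:
            all_conf.append(d.confidence)
            all_flags.append(False)

    conf = np.asarray(all_conf)
    flags = np.asarray(all_flags, dtype=bool)
    n_gt = len(gts)
    tp = int(flags.sum())
    fp = int((~flags).sum())
    p, r = precision_recall(flags, n_gt)

    # best F1 over confidence thresholds (evaluated at each detection's score)
    best_f1, best_conf = 0.0, 0.0
    for t in np.unique(conf) if conf.size else []:
        sel = conf >= t
        pt, rt = precision_recall(flags[sel], n_gt)
        f1t = 2 * pt * rt / (pt + rt) if (pt + rt) > 0 else 0.0
        if f1t > best_f1:
            best_f1, best_conf = f1t, float(t)

    return EvalSummary(
        ap_per_class=ap_per_class,
        map50=float(np.mean(list(ap_per_class.values()))) if ap_per_class else 0.0,
        precision=p,
        recall=r,
        f1=best_f1,
        tp=tp,
        fp=fp,
        fn=total_fn,
        iou_threshold=iou_thr,
        f1_confidence=best_conf,
    )


def write_report(
    summary: EvalSummary,
    path: str | Path,
    class_names: Sequence[str] | None = None,
) -> None:
    """Write a per-class CSV report (AP, plus overall P/R/F1/mAP rows)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "AP", "F1", "Recall", "Precision"])
        for c, ap in sorted(summary.ap_per_class.items()):
            name = class_names[c] if class_names else str(c)
            w.writerow([name, f"{ap:.4f}", "", "", ""])
        w.writerow(
            [
                "all",
                f"{summary.map50:.4f}",
                f"{summary.f1:.4f}",
                f"{summary.recall:.4f}",
                f"{summary.precision:.4f}",
            ]
        )
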