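"""Inference: head decoding, non-maximum suppression and model evaluation."""

from __future__ import annotations

import numpy as np

from .boxes import BoxXYXY
from .coding import OFFSET_BIAS, OFFSET_GAIN, OFFSET_MAX, OFFSET_MIN
from .metrics import Detection, EvalSummary, GTRecord, evaluate
from .nn import Tensor
from .synth import Scene
from .train import TrainConfig

__all__ = ["decode_head", "nms", "predict_scenes", "evaluate_model", "gts_from_scenes"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def decode_head(
    raw: np.ndarray,
    anchors: list[tuple[float, float]],
    stride: int,
    num_classes: int,
    improved: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode one raw head map into (boxes_xyxy_px, scores, class_ids).

    ``raw`` is (3*(5+nc), H, W) for one image.  Scores are
    objectness * class probability, one candidate per (anchor, cell, class
    argmax).
    """
    no = 5 + num_classes
    na = len(anchors)
    h, w = raw.shape[1], raw.shape[2]
    p = raw.reshape(na, no, h, w)
    ys, xs = np.mgrid[0:h, 0:w]
    if improved:
        off_x = np.clip(
            OFFSET_GAIN * _sigmoid(p[:, 0]) - OFFSET_BIAS, OFFSET_MIN, OFFSET_MAX
        )
        off_y = np.clip(
            OFFSET_GAIN * _sigmoid(p[:, 1]) - OFFSET_BIAS, OFFSET_MIN, OFFSET_MAX
        )
    else:
        off_x = 2.0 * _sigmoid(p[:, 0]) - 0.5
        off_y = 2.0 * _sigmoid(p[:, 1]) - 0.5
    bx = (off_x + xs[None]) * stride
    by = (off_y + ys[None]) * stride
    pw = np.array([a[0] for a in anchors], dtype=np.float32).reshape(na, 1, 1)
    ph = np.array([a[1] for a in anchors], dtype=np.float32).reshape(na, 1, 1)
    bw = pw * (2.0 * _sigmoid(p[:, 2])) ** 2
    bh = ph * (2.0 * _sigmoid(p[:, 3])) ** 2
    obj = _sigmoid(p[:, 4])
    cls = _sigmoid(p[:, 5:])  # (na, nc, h, w)
    cid = cls.argmax(axis=1)
    cbest = cls.max(axis=1)
    score = obj * cbest
    boxes = np.stack(
        [bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2], axis=-1
    ).reshape(-1, 4)
    return boxes, score.reshape(-1), cid.reshape(-1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.45) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores)
    x1, y1, x2, y2 = boxes[:, 0], boxes[:, 1], boxes[:, 2], boxes[:, 3]
    areas = np.maximum(0.0, x2 - x1) * np.maximum(0.0, y2 - y1)
    keep: list[int] = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        iw = np.maximum(
            0.0, np.minimum(x2[i], x2[rest]) - np.maximum(x1[i], x1[rest])
        )
        ih = np.maximum(
            0.0, np.minimum(y2[i], y2[rest]) - np.maximum(y1[i], y1[rest])
        )
        inter = iw * ih
        iou = inter / (areas[i] + areas[rest] - inter + 1e-12)
        order = rest[iou <= iou_thr]
    return keep


def predict_scenes(
    model,
    scenes: list[Scene],
    cfg: TrainConfig,
    conf_floor: float = 0.001,
    nms_iou: float = 0.45,
    max_det: int = 300,
    agnostic_nms: bool = False,
) -> list[Detection]:
    """Run eval-mode inference over scenes; returns Detection records.

    Suppression is per class by default (the family convention); with
    ``agnostic_nms`` it ignores class labels, so a lower-confidence duplicate
    of another class cannot survive next to a stronger detection.
    """
    model.eval()
    anchor_groups = [[(a.pw, a.ph) for a in g] for g in cfg.anchor_set().to_anchor_priors()]
    out: list[Detection] = []
    size = cfg.input_size
    for img_id, scene in enumerate(scenes):
        sh, sw = scene.image.shape[:2]
        img = scene.image
        if (sh, sw) != (size, size):
            from skimage.transform import resize as _r

            img = np.clip(
                _r(scene.image, (size, size), preserve_range=True, anti_aliasing=False),
                0,
                255,
            )
        x = Tensor(
            np.ascontiguousarray(img.transpose(2, 0, 1), dtype=np.float32)[None]
            / 255.0
        )
        heads = model(x)
        all_boxes, all_scores, all_cids = [], [], []
        for s, raw in enumerate(heads):
            boxes, scores, cids = decode_head(
                raw.data[0],
                anchor_groups[s],
                (8, 16, 32)[s],
                cfg.num_classes,
                improved=cfg.improved,
            )
            sel = scores >= conf_floor
            all_boxes.append(boxes[sel])
            all_scores.append(scores[sel])
            all_cids.append(cids[sel])
        boxes = np.concatenate(all_boxes)
        scores = np.concatenate(all_scores)
        cids = np.concatenate(all_cids)
        if agnostic_nms:
            keep = nms(boxes, scores, nms_iou)[:max_det]
        else:  # class-wise NMS via coordinate offsetting
            shifted = boxes + cids[:, None] * (size * 2.0)
            keep = nms(shifted, scores, nms_iou)[:max_det]
        sx, sy = sw / size, sh / size
        for i in keep:
            x1, y1, x2, y2 = boxes[i]
            x1, x2 = np.clip([x1 * sx, x2 * sx], 0, sw)
            y1, y2 = np.clip([y1 * sy, y2 * sy], 0, sh)
            if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
                continue
            out.append(
                Detection(
                    image_id=img_id,
                    class_id=int(cids[i]),
                    confidence=float(min(scores[i], 1.0)),
                    box=BoxXYXY(float(x1), float(y1), float(x2), float(y2)),
                )
            )
    return out


def gts_from_scenes(scenes: list[Scene]) -> list[GTRecord]:
    out = []
    for img_id, scene in enumerate(scenes):
        h, w = scene.image.shape[:2]
        for b in scene.boxes:
            out.append(
                GTRecord(
                    image_id=img_id,
                    class_id=b.class_id,
                    box=BoxXYXY(
                        (b.cx - b.w / 2) * w,
                        (b.cy - b.h / 2) * h,
                        (b.cx + b.w / 2) * w,
                        (b.cy + b.h / 2) * h,
                    ),
                )
            )
    return out


def evaluate_model(
    model,
    scenes: list[Scene],
    cfg: TrainConfig,
    iou_thr: float = 0.5,
    conf_floor: float = 0.001,
    nms_iou: float = 0.45,
    agnostic_nms: bool = False,
) -> EvalSummary:
    dets = predict_scenes(model, scenes, cfg, conf_floor, nms_iou,
                          agnostic_nms=agnostic_nms)
    return evaluate(dets, gts_from_scenes(scenes), iou_thr, conf_floor)
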