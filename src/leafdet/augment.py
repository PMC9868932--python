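"""Training-time augmentation: mosaic stitching, the standard photometric/
geometric set, and the epoch-fraction schedule that switches between them.

Mosaic stitches random crops of four scenes around a random pivot into one
canvas, remapping and clipping every box; it greatly diversifies context but
drifts from the natural image distribution, so it is only applied during the
first ``mosaic_fraction`` of training epochs (default 0.4) and plain
augmentation takes over for the remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

from .assign import GroundTruthBox
from .synth import Scene

__all__ = ["AugmentConfig", "use_mosaic", "mosaic", "standard_augment"]


@dataclass(frozen=True)
class AugmentConfig:
    mosaic_fraction: float = 0.4
    flip_prob: float = 0.5
    scale_range: tuple[float, float] = (0.75, 1.33)
    distort_range: tuple[float, float] = (0.9, 1.1)
    hue_delta: float = 0.015
    sat_delta: float = 0.4
    val_delta: float = 0.3
    min_box_pixels: float = 2.0
    min_visibility: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.mosaic_fraction <= 1.0):
            raise ValueError("mosaic_fraction must lie in [0, 1]")


def use_mosaic(epoch: int, total_epochs: int, mosaic_fraction: float = 0.4) -> bool:
    """True iff ``epoch`` falls in the first ``mosaic_fraction`` of training."""
    return epoch < math.floor(mosaic_fraction * total_epochs)


def _clip_boxes(
    boxes_px: list[tuple[int, float, float, float, float]],
    canvas_wh: tuple[int, int],
    min_box_pixels: float,
    min_visibility: float,
) -> list[GroundTruthBox]:
    """Clip pixel-space (cid, x1, y1, x2, y2) records to the canvas; drop boxes
    that end up tiny or mostly invisible."""
    cw_px, ch_px = canvas_wh
    out = []
    for cid, x1, y1, x2, y2 in boxes_px:
        orig_area = (x2 - x1) * (y2 - y1)
        cx1, cy1 = max(0.0, x1), max(0.0, y1)
        cx2, cy2 = min(float(cw_px), x2), min(float(ch_px), y2)
        w, h = cx2 - cx1, cy2 - cy1
        if w < min_box_pixels or h < min_box_pixels:
            continue
        if orig_area <= 0 or (w * h) / orig_area < min_visibility:
            continue
        out.append(
            GroundTruthBox(
                cid,
                (cx1 + cx2) / 2.0 / cw_px,
                (cy1 + cy2) / 2.0 / ch_px,
                w / cw_px,
                h / ch_px,
            )
        )
    return out


def mosaic(
    scenes: list[Scene],
    out_size: int,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> Scene:
    """Stitch four scenes into one ``out_size`` square canvas.

    A pivot sampled uniformly in the central 50% of the canvas splits it into
    four quadrants; each is filled from one input scene, randomly rescaled and
    cropped (edge-padded where the source runs out).  Boxes are remapped into
    canvas coordinates, clipped, and dropped when below the size/visibility
    thresholds.
    """
    cfg = config or AugmentConfig()
    if len(scenes) != 4:
        raise ValueError(f"mosaic needs exactly 4 scenes, got {len(scenes)}")
    canvas = np.zeros((out_size, out_size, 3), dtype=np.uint8)
    px = int(rng.uniform(0.25, 0.75) * out_size)
    py = int(rng.uniform(0.25, 0.75) * out_size)
    regions = [  # (x1, y1, x2, y2) of each quadrant
        (0, 0, px, py),
        (px, 0, out_size, py),
        (0, py, px, out_size),
        (px, py, out_size, out_size),
    ]
    all_boxes: list[tuple[int, float, float, float, float]] = []
    for scene, (qx1, qy1, qx2, qy2) in zip(scenes, regions):
        qw, qh = qx2 - qx1, qy2 - qy1
        if qw < 1 or qh < 1:
            continue
        h0, w0 = scene.image.shape[:2]
        s = rng.uniform(0.5, 1.5) * out_size / max(h0, w0)
        sw, sh = max(2, int(w0 * s)), max(2, int(h0 * s))
        scaled = resize(scene.image, (sh, sw), preserve_range=True, anti_aliasing=False)
        # crop window of the quadrant's size; random position, edge-pad shortfall
        ox = int(rng.integers(0, max(1, sw - qw))) if sw > qw else 0
        oy = int(rng.integers(0, max(1, sh - qh))) if sh > qh else 0
        patch = np.zeros((qh, qw, 3))
        cw, ch = min(qw, sw - ox), min(qh, sh - oy)
        patch[:ch, :cw] = scaled[oy : oy + ch, ox : ox + cw]
        canvas[qy1:qy2, qx1:qx2] = np.clip(patch, 0, 255).astype(np.uint8)
        for b in scene.boxes:
            x1 = (b.cx - b.w / 2) * w0 * s - ox + qx1
            y1 = (b.cy - b.h / 2) * h0 * s - oy + qy1
            x2 = (b.cx + b.w / 2) * w0 * s - ox + qx1
            y2 = (b.cy + b.h / 2) * h0 * s - oy + qy1
            # clip to the quadrant first (the crop), then to the canvas
            x1, x2 = max(x1, qx1), min(x2, qx1 + cw)
            y1, y2 = max(y1, qy1), min(y2, qy1 + ch)
            if x2 > x1 and y2 > y1:
                orig_w, orig_h = b.w * w0 * s, b.h * h0 * s
                all_boxes.append((b.class_id, x1, y1, x2, y2))
                # visibility is judged against the pre-clip scaled box
                if (x2 - x1) * (y2 - y1) / (orig_w * orig_h) < cfg.min_visibility:
                    all_boxes.pop()
    boxes = _clip_boxes(all_boxes, (out_size, out_size), cfg.min_box_pixels, 0.0)
    return Scene(image=canvas, boxes=boxes, masks=None)


def standard_augment(
    scene: Scene, config: AugmentConfig, rng: np.random.Generator
) -> Scene:
    """Horizontal flip, isotropic scale, aspect distortion and HSV jitter."""
    img = scene.image.astype(np.float64) / 255.0
    h0, w0 = img.shape[:2]
    boxes_px = [
        (
            b.class_id,
            (b.cx - b.w / 2) * w0,
            (b.cy - b.h / 2) * h0,
            (b.cx + b.w / 2) * w0,
            (b.cy + b.h / 2) * h0,
        )
        for b in scene.boxes
    ]

    if rng.uniform() < config.flip_prob:
        img = img[:, ::-1]
        boxes_px = [(c, w0 - x2, y1, w0 - x1, y2) for c, x1, y1, x2, y2 in boxes_px]

    s = rng.uniform(*config.scale_range)
    dw = rng.uniform(*config.distort_range)
    dh = rng.uniform(*config.distort_range)
    sx, sy = s * dw, s * dh
    if abs(sx - 1) > 1e-9 or abs(sy - 1) > 1e-9:
        sh, sw = max(2, int(h0 * sy)), max(2, int(w0 * sx))
        scaled = resize(img, (sh, sw), preserve_range=True, anti_aliasing=False)
        out = np.zeros_like(img)
        ch, cw = min(h0, sh), min(w0, sw)
        out[:ch, :cw] = scaled[:ch, :cw]
        img = out
        sx_eff, sy_eff = sw / w0, sh / h0
        boxes_px = [
            (c, x1 * sx_eff, y1 * sy_eff, x2 * sx_eff, y2 * sy_eff)
            for c, x1, y1, x2, y2 in boxes_px
        ]

    if config.hue_delta or config.sat_delta or config.val_delta:
        hsv = rgb2hsv(np.clip(img, 0, 1))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-config.hue_delta, config.hue_delta)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(1 - config.sat_delta, 1 + config.sat_delta), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(1 - config.val_delta, 1 + config.val_delta), 0, 1)
        img = hsv2rgb(hsv)

    boxes = _clip_boxes(boxes_px, (w0, h0), config.min_box_pixels, config.min_visibility)
    return Scene(
        image=np.clip(img * 255.0, 0, 255).astype(np.uint8), boxes=boxes, masks=None
    )
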