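"""Synthetic leaf-lesion scenes with exact ground truth.

The generator emulates the regime that makes field imagery of diseased
leaves hard for single-stage detectors: many small, densely packed,
partially overlapping lesions of several visually similar classes on a
textured green background.  Each lesion is an anti-aliased rotated ellipse
with a class-specific hue and mild per-lesion texture; its label box is the
tight axis-aligned extent of the rendered blob.  Nothing photorealistic is
attempted — the point is exact, free ground truth at any sample size.

Also here: YOLO-txt / PASCAL-VOC XML label round-trips, the 9:1
train/test split (10% of train as validation), and the one-shot offline
dataset expansion (Gaussian blur, horizontal flip, small rotation,
brightness) used to multiply an annotated set before training.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .assign import GroundTruthBox

__all__ = [
    "SynthConfig",
    "Scene",
    "DatasetSplit",
    "generate_scene",
    "write_labels",
    "read_labels",
    "split_dataset",
    "expand_dataset",
    "CLASS_COLORS",
]

# one distinct lesion hue per class (RGB, uint8); 8 classes by default
CLASS_COLORS = np.array(
    [
        (120, 70, 40),   # brown necrosis
        (160, 150, 60),  # chlorotic yellow
        (90, 50, 80),    # purple blotch
        (200, 190, 170), # pale mildew
        (60, 40, 30),    # dark rot
        (180, 110, 50),  # rust orange
        (140, 140, 140), # grey mold
        (30, 60, 30),    # dark-green water-soak
    ],
    dtype=np.float64,
)


@dataclass(frozen=True)
class SynthConfig:
    """Scene-generation parameters.

    Lesion side lengths are drawn log-uniformly from ``lesion_size_range``
    (given in pixels at a 640 px image and rescaled with ``image_size``), a
    small-target-biased law under which most lesions land on the stride-8
    head.  ``overlap_allowance`` caps the fraction of a new lesion's area
    already covered by earlier lesions; placements are re-drawn (up to 10
    tries) when it is exceeded, so moderate occlusion is common but total
    occlusion is not.
    """

    image_size: int = 640
    num_classes: int = 8
    lesions_per_image: tuple[int, int] = (3, 12)
    lesion_size_range: tuple[float, float] = (4.0, 64.0)
    overlap_allowance: float = 0.4
    aspect_range: tuple[float, float] = (0.6, 1.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_size_range[0] < 2:
            raise ValueError("lesion sizes must be >= 2 px")
        if self.lesions_per_image[0] < 0:
            raise ValueError("lesion counts must be >= 0")
        if not (1 <= self.num_classes <= len(CLASS_COLORS)):
            raise ValueError(f"num_classes must be in [1, {len(CLASS_COLORS)}]")


@dataclass
class Scene:
    """An image plus its ground-truth boxes (and, optionally, per-lesion masks)."""

    image: np.ndarray  # (H, W, 3) uint8
    boxes: list[GroundTruthBox]
    masks: list[np.ndarray] | None = None  # boolean (H, W) per lesion


@dataclass(frozen=True)
class DatasetSplit:
    train: list
    val: list
    test: list


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Leaf-like background: green base + smooth low-frequency mottling + veins."""
    base = np.array([70.0, 120.0, 55.0])
    noise = rng.standard_normal((size, size, 3))
    smooth = np.stack(
        [ndimage.gaussian_filter(noise[..., c], sigma=size / 24) for c in range(3)],
        axis=-1,
    )
    smooth *= 18.0 / (np.abs(smooth).max() + 1e-9)
    fine = rng.standard_normal((size, size, 1)) * 3.0
    img = base[None, None, :] + smooth + fine
    return np.clip(img, 0, 255)


def _lesion_mask(
    h: int, w: int, angle: float, size: int, cx: float, cy: float
) -> np.ndarray:
    """Soft anti-aliased rotated-ellipse membership in [0, 1] on the full canvas."""
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    ca, sa = math.cos(angle), math.sin(angle)
    u = (ca * dx + sa * dy) / (w / 2.0)
    v = (-sa * dx + ca * dy) / (h / 2.0)
    r = np.sqrt(u * u + v * v)
    # ~1-px soft edge relative to the smaller semi-axis
    edge = 1.0 / max(min(w, h) / 2.0, 1.0)
    return np.clip((1.0 - r) / edge + 0.5, 0.0, 1.0)


def generate_scene(cfg: SynthConfig, rng: np.random.Generator) -> Scene:
    """Render one scene; the emitted box is each blob's tight pixel extent."""
    size = cfg.image_size
    img = _background(size, rng)
    scale = size / 640.0
    lo, hi = cfg.lesion_size_range
    n = int(rng.integers(cfg.lesions_per_image[0], cfg.lesions_per_image[1] + 1))
    occupancy = np.zeros((size, size), dtype=bool)
    boxes: list[GroundTruthBox] = []
    masks: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(10):
            side = math.exp(rng.uniform(math.log(lo), math.log(hi))) * scale
            aspect = rng.uniform(*cfg.aspect_range)
            w = max(2.0, side * math.sqrt(aspect))
            h = max(2.0, side / math.sqrt(aspect))
            angle = rng.uniform(0, math.pi)
            margin = max(w, h) / 2.0 + 2
            if size - margin <= margin:
                continue
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            soft = _lesion_mask(h, w, angle, size, cx, cy)
            hard = soft > 0.5
            area = hard.sum()
            if area < 4:
                continue
            if occupancy[hard].sum() / area > cfg.overlap_allowance:
                continue
            break
        else:
            continue
        class_id = int(rng.integers(cfg.num_classes))
        color = CLASS_COLORS[class_id]
        texture = ndimage.gaussian_filter(
            rng.standard_normal((size, size)), sigma=2.0
        )
        texture = 1.0 + 0.15 * texture / (np.abs(texture).max() + 1e-9)
        alpha = soft[..., None] * rng.uniform(0.75, 0.95)
        img = img * (1 - alpha) + (color[None, None, :] * texture[..., None]) * alpha
        occupancy |= hard
        ys, xs = np.nonzero(hard)
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        boxes.append(
            GroundTruthBox(
                class_id=class_id,
                cx=(x1 + x2) / 2.0 / size,
                cy=(y1 + y2) / 2.0 / size,
                w=(x2 - x1) / size,
                h=(y2 - y1) / size,
            )
        )
        masks.append(hard)
    return Scene(image=np.clip(img, 0, 255).astype(np.uint8), boxes=boxes, masks=masks)


# ---------------------------------------------------------------- label IO


def write_labels(scene_boxes: Sequence[GroundTruthBox], path: str | Path,
                 fmt: str = "yolo_txt", image_size: tuple[int, int] | None = None) -> None:
    """Write labels as YOLO-txt (normalized, 6 decimals) or VOC XML (1-based px)."""
    path = Path(path)
    if fmt == "yolo_txt":
        lines = [
            f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
            for b in scene_boxes
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "voc_xml":
        if image_size is None:
            raise ValueError("voc_xml needs image_size=(width, height)")
        iw, ih = image_size
        root = ET.Element("annotation")
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(iw)
        ET.SubElement(size, "height").text = str(ih)
        ET.SubElement(size, "depth").text = "3"
        for b in scene_boxes:
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = str(b.class_id)
            bb = ET.SubElement(obj, "bndbox")
            ET.SubElement(bb, "xmin").text = str(int(round((b.cx - b.w / 2) * iw)) + 1)
            ET.SubElement(bb, "ymin").text = str(int(round((b.cy - b.h / 2) * ih)) + 1)
            ET.SubElement(bb, "xmax").text = str(int(round((b.cx + b.w / 2) * iw)))
            ET.SubElement(bb, "ymax").text = str(int(round((b.cy + b.h / 2) * ih)))
        ET.ElementTree(root).write(path)
    else:
        raise ValueError(f"unknown label format: {fmt}")


def read_labels(path: str | Path, fmt: str = "yolo_txt",
                image_size: tuple[int, int] | None = None) -> list[GroundTruthBox]:
    """Inverse of :func:`write_labels`; parse errors name the file and line."""
    path = Path(path)
    out: list[GroundTruthBox] = []
    if fmt == "yolo_txt":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                cx, cy, w, h = (float(p) for p in parts[1:])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: {e}") from None
            out.append(GroundTruthBox(cid, cx, cy, w, h))
    elif fmt == "voc_xml":
        if image_size is None:
            raise ValueError("voc_xml needs image_size=(width, height)")
        iw, ih = image_size
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as e:
            raise ValueError(f"{path}: malformed XML: {e}") from None
        for obj in root.iter("object"):
            cid = int(obj.findtext("name"))
            bb = obj.find("bndbox")
            x1 = int(bb.findtext("xmin")) - 1
            y1 = int(bb.findtext("ymin")) - 1
            x2 = int(bb.findtext("xmax"))
            y2 = int(bb.findtext("ymax"))
            out.append(
                GroundTruthBox(
                    cid,
                    (x1 + x2) / 2.0 / iw,
                    (y1 + y2) / 2.0 / ih,
                    (x2 - x1) / iw,
                    (y2 - y1) / ih,
                )
            )
    else:
        raise ValueError(f"unknown label format: {fmt}")
    return out


# ---------------------------------------------------------------- splitting


def split_dataset(
    ids: Sequence,
    train_test_ratio: float = 0.9,
    val_fraction_of_train: float = 0.1,
    seed: int = 0,
) -> DatasetSplit:
    """Seeded shuffle, then floor(n * ratio) into train+val, remainder to test;
    floor(val_fraction) of the train side becomes validation."""
    rng = np.random.default_rng(seed)
    ids = list(ids)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n_trainval = int(len(ids) * train_test_ratio)
    trainval, test = shuffled[:n_trainval], shuffled[n_trainval:]
    n_val = int(n_trainval * val_fraction_of_train)
    return DatasetSplit(train=trainval[n_val:], val=trainval[:n_val], test=test)


# ---------------------------------------------------------------- expansion


def _rotate_scene(scene: Scene, angle_deg: float) -> Scene:
    """Rotate image and re-tighten each box on its rotated mask (falls back to
    the rotated-corner extent when masks are absent)."""
    from skimage.transform import rotate

    img = rotate(
        scene.image.astype(np.float64) / 255.0, angle_deg, resize=False, mode="edge"
    )
    h, w = scene.image.shape[:2]
    boxes: list[GroundTruthBox] = []
    masks: list[np.ndarray] | None = [] if scene.masks is not None else None
    for i, b in enumerate(scene.boxes):
        if scene.masks is not None:
            m = rotate(scene.masks[i].astype(np.float64), angle_deg, resize=False) > 0.5
            if not m.any():
                continue
            ys, xs = np.nonzero(m)
            x1, x2, y1, y2 = xs.min(), xs.max() + 1, ys.min(), ys.max() + 1
            masks.append(m)
        else:
            a = math.radians(-angle_deg)  # image rotate is CCW in (row, col)
            cx0, cy0 = w / 2.0, h / 2.0
            px = np.array([b.cx - b.w / 2, b.cx + b.w / 2]) * w
            py = np.array([b.cy - b.h / 2, b.cy + b.h / 2]) * h
            corners = np.array([(x, y) for x in px for y in py])
            dx, dy = corners[:, 0] - cx0, corners[:, 1] - cy0
            rx = cx0 + dx * math.cos(a) - dy * math.sin(a)
            ry = cy0 + dx * math.sin(a) + dy * math.cos(a)
            x1, x2 = np.clip([rx.min(), rx.max()], 0, w)
            y1, y2 = np.clip([ry.min(), ry.max()], 0, h)
            if x2 - x1 < 1 or y2 - y1 < 1:
                continue
        boxes.append(
            GroundTruthBox(
                b.class_id,
                (x1 + x2) / 2.0 / w,
                (y1 + y2) / 2.0 / h,
                (x2 - x1) / w,
                (y2 - y1) / h,
            )
        )
    return Scene(
        image=np.clip(img * 255.0, 0, 255).astype(np.uint8), boxes=boxes, masks=masks
    )


def _flip_scene(scene: Scene) -> Scene:
    boxes = [
        GroundTruthBox(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h) for b in scene.boxes
    ]
    masks = [m[:, ::-1].copy() for m in scene.masks] if scene.masks is not None else None
    return Scene(image=scene.image[:, ::-1].copy(), boxes=boxes, masks=masks)


def expand_dataset(
    scenes: Sequence[Scene], target_count: int, rng: np.random.Generator
) -> list[Scene]:
    """One-shot offline expansion: randomly blurred / flipped / rotated /
    brightness-adjusted copies are appended until ``target_count`` is reached."""
    if target_count < len(scenes):
        raise ValueError("target_count must be >= the input count")
    out = list(scenes)
    while len(out) < target_count:
        src = out[int(rng.integers(len(scenes)))]
        op = rng.integers(4)
        if op == 0:  # Gaussian blur
            img = ndimage.gaussian_filter(
                src.image.astype(np.float64), sigma=(rng.uniform(0.5, 1.5),) * 2 + (0,)
            )
            new = Scene(np.clip(img, 0, 255).astype(np.uint8), list(src.boxes), src.masks)
        elif op == 1:  # horizontal flip
            new = _flip_scene(src)
        elif op == 2:  # small rotation
            new = _rotate_scene(src, float(rng.uniform(-15.0, 15.0)))
        else:  # brightness
            img = src.image.astype(np.float64) * rng.uniform(0.7, 1.3)
            new = Scene(np.clip(img, 0, 255).astype(np.uint8), list(src.boxes), src.masks)
        out.append(new)
    return out
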