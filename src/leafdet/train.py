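"""Desk-scale training: composite loss, SGD with momentum, mosaic scheduling
and early stopping.

The loss follows the single-stage recipe: binary cross-entropy for class and
objectness terms plus the improved DIoU loss for box regression, evaluated
only at the positive samples produced by the 4-grid assignment rule.  Box
offsets are decoded with the widened-and-clamped formula, so targets at a
cell boundary are reachable at finite logits.

Everything is driven by one seeded numpy RNG; identical config + seed gives
identical loss curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .anchors import AnchorSet
from .assign import Assignment, FeatureGrid, build_targets
from .augment import AugmentConfig, mosaic, standard_augment, use_mosaic
from .coding import OFFSET_BIAS, OFFSET_GAIN, OFFSET_MAX, OFFSET_MIN
from .nn import Tensor, manual_seed
from .nn.autograd import bce_with_logits
from .nn.model import Detector, build_baseline_model, build_improved_model
from .synth import Scene

__all__ = ["TrainConfig", "TrainLog", "Trainer", "improved_diou_loss_t",
           "save_checkpoint", "load_checkpoint", "DEFAULT_ANCHORS"]

# anchor priors re-clustered for lesion-type data (pixels at 640 input)
DEFAULT_ANCHORS = [
    [(13, 10), (13, 14), (29, 32)],
    [(42, 39), (47, 54), (61, 46)],
    [(74, 70), (140, 115), (106, 365)],
]


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the full-scale protocol (640 px input, 400 epochs, batch
    16, SGD momentum 0.937, initial lr 0.01 with x0.1 steps at 70%/90% of
    training, early-stop patience 20, mosaic for the first 40% of epochs);
    desk-scale runs shrink ``input_size``/``epochs``/``width_multiple``.
    """

    input_size: int = 640
    epochs: int = 400
    batch_size: int = 16
    momentum: float = 0.937
    lr0: float = 0.01
    lr_decay_points: tuple[float, float] = (0.7, 0.9)
    lr_decay_factor: float = 0.1
    warmup_epochs: int = 3
    patience: int = 20
    mosaic_fraction: float = 0.4
    num_classes: int = 8
    anchors: list = field(default_factory=lambda: [list(g) for g in DEFAULT_ANCHORS])
    box_weight: float = 0.05
    obj_weight: float = 1.0
    cls_weight: float = 0.5
    obj_balance: tuple[float, float, float] = (4.0, 1.0, 0.4)
    ratio_threshold: float = 4.0
    width_multiple: float = 0.5
    depth_multiple: float = 0.33
    improved: bool = True
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.patience < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs, batch size and patience must be positive")

    def grids(self) -> list[FeatureGrid]:
        return [
            FeatureGrid(s, self.input_size // s, self.input_size // s)
            for s in (8, 16, 32)
        ]

    def anchor_set(self) -> AnchorSet:
        pairs = [tuple(p) for g in self.anchors for p in g]
        return AnchorSet(pairs=pairs)


@dataclass
class TrainLog:
    train_losses: list[float]
    val_losses: list[float]
    stopped_epoch: int
    best_epoch: int


def improved_diou_terms(bx, by, bw, bh, gx, gy, gw, gh) -> tuple[Tensor, Tensor]:
    """Per-sample (IoU, improved DIoU) of decoded predictions vs constants.

    All arguments share one unit system (grid cells here); predictions are
    autograd tensors, ground truths plain arrays.
    """
    px1, px2 = bx - bw * 0.5, bx + bw * 0.5
    py1, py2 = by - bh * 0.5, by + bh * 0.5
    qx1, qx2 = gx - gw * 0.5, gx + gw * 0.5
    qy1, qy2 = gy - gh * 0.5, gy + gh * 0.5
    iw = (px2.minimum(qx2) - px1.maximum(qx1)).maximum(0.0)
    ih = (py2.minimum(qy2) - py1.maximum(qy1)).maximum(0.0)
    inter = iw * ih
    union = bw * bh + gw * gh - inter
    iou = inter / union
    ew = px2.maximum(qx2) - px1.minimum(qx1)
    eh = py2.maximum(qy2) - py1.minimum(qy1)
    c2 = ew * ew + eh * eh
    rho2_b = (bx - gx) ** 2.0 + (by - gy) ** 2.0
    rho2_l = (px1 - qx1) ** 2.0 + (py1 - qy1) ** 2.0
    ratio = bw / gw - 1.0
    idiou = iou - rho2_b / (rho2_l + c2) * (ratio * ratio + 1.0)
    return iou, idiou


def improved_diou_loss_t(bx, by, bw, bh, gx, gy, gw, gh) -> Tensor:
    """Mean improved-DIoU loss over a batch of decoded predictions."""
    _, idiou = improved_diou_terms(bx, by, bw, bh, gx, gy, gw, gh)
    return (1.0 - idiou).mean()


def _decode_offset(t: Tensor) -> Tensor:
    return (t.sigmoid() * OFFSET_GAIN - OFFSET_BIAS).clamp(OFFSET_MIN, OFFSET_MAX)


def detection_loss(
    raw_heads: list[Tensor],
    targets: list[Assignment],
    image_ids: list[int],
    cfg: TrainConfig,
) -> tuple[Tensor, dict[str, float]]:
    """Composite loss over one batch.

    ``targets`` come from :func:`leafdet.assign.build_targets` run per image;
    ``image_ids`` gives the batch index of each assignment.
    """
    n = raw_heads[0].shape[0]
    nc = cfg.num_classes
    no = 5 + nc
    anchor_groups = cfg.anchor_set().to_anchor_priors()
    total_box = Tensor(0.0)
    total_obj = Tensor(0.0)
    total_cls = Tensor(0.0)
    for s, raw in enumerate(raw_heads):
        h, w = raw.shape[2], raw.shape[3]
        p = raw.reshape(n, 3, no, h, w)
        stride = cfg.grids()[s].stride
        scale_t = [
            (t, i) for t, i in zip(targets, image_ids) if t.scale == s
        ]
        obj_target = np.zeros((n, 3, h, w), dtype=np.float32)
        if scale_t:
            img = np.array([i for _, i in scale_t])
            anc = np.array([t.anchor for t, _ in scale_t])
            cy = np.array([t.cell.cy for t, _ in scale_t])
            cx = np.array([t.cell.cx for t, _ in scale_t])

            # one broadcasted gather pulls every channel of every positive
            chan = np.arange(no)
            pred = p[
                (img[:, None], anc[:, None], chan[None, :], cy[:, None], cx[:, None])
            ]  # (n_pos, no)
            tx, ty = pred[:, 0], pred[:, 1]
            tw, th = pred[:, 2], pred[:, 3]
            bx = _decode_offset(tx) + Tensor(cx.astype(np.float32))
            by = _decode_offset(ty) + Tensor(cy.astype(np.float32))
            pw = np.array([anchor_groups[s][t.anchor].pw for t, _ in scale_t],
                          dtype=np.float32) / stride
            ph = np.array([anchor_groups[s][t.anchor].ph for t, _ in scale_t],
                          dtype=np.float32) / stride
            bw = (tw.sigmoid() * 2.0) ** 2.0 * Tensor(pw)
            bh = (th.sigmoid() * 2.0) ** 2.0 * Tensor(ph)
            gx = np.array([t.cell.cx + t.offset_x for t, _ in scale_t], np.float32)
            gy = np.array([t.cell.cy + t.offset_y for t, _ in scale_t], np.float32)
            gw = np.array([t.target_w for t, _ in scale_t], np.float32) / stride
            gh = np.array([t.target_h for t, _ in scale_t], np.float32) / stride
            iou, idiou = improved_diou_terms(bx, by, bw, bh, gx, gy, gw, gh)
            total_box = total_box + (1.0 - idiou).mean()
            # IoU-aware objectness: the target is the (detached) overlap of
            # the decoded box, so confidence learns to rank localization
            obj_target[img, anc, cy, cx] = np.clip(iou.data, 0.0, 1.0)

            if nc > 1:
                onehot = np.zeros((len(scale_t), nc), dtype=np.float32)
                for r, (t, _) in enumerate(scale_t):
                    onehot[r, t.class_id] = 1.0
                total_cls = total_cls + bce_with_logits(pred[:, 5:], onehot).mean()

        obj_logits = p[(slice(None), slice(None), 4)]
        total_obj = total_obj + bce_with_logits(obj_logits, obj_target).mean() * float(
            cfg.obj_balance[s]
        )

    # per-scale means are summed (not averaged) across scales and the total is
    # scaled by batch size — the convention the default term weights assume
    loss = (
        total_box * cfg.box_weight
        + total_obj * cfg.obj_weight
        + total_cls * cfg.cls_weight
    ) * float(n)
    parts = {
        "box": float(total_box.data) * cfg.box_weight,
        "obj": float(total_obj.data) * cfg.obj_weight,
        "cls": float(total_cls.data) * cfg.cls_weight,
    }
    return loss, parts


class SGD:
    """SGD with classical momentum."""

    def __init__(self, params, lr: float, momentum: float):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data = p.data + v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Trainer:
    """Wires augmentation, target assignment, the model and the loss together."""

    def __init__(
        self,
        scenes: list[Scene],
        cfg: TrainConfig,
        val_scenes: list[Scene] | None = None,
        model: Detector | None = None,
    ):
        if not scenes:
            raise ValueError("training set is empty")
        self.cfg = cfg
        self.scenes = scenes
        self.val_scenes = val_scenes or []
        self.rng = np.random.default_rng(cfg.seed)
        if model is None:
            manual_seed(cfg.seed)
            builder = build_improved_model if cfg.improved else build_baseline_model
            model = builder(
                cfg.num_classes,
                anchors=cfg.anchor_set(),
                width_multiple=cfg.width_multiple,
                depth_multiple=cfg.depth_multiple,
            )
        self.model = model
        self.optimizer = SGD(model.parameters(), cfg.lr0, cfg.momentum)
        self.aug_cfg = AugmentConfig(mosaic_fraction=cfg.mosaic_fraction)

    # ------------------------------------------------------------------
    def _lr_at(self, epoch: int) -> float:
        lr = self.cfg.lr0
        if self.cfg.warmup_epochs and epoch < self.cfg.warmup_epochs:
            return lr * (epoch + 1) / self.cfg.warmup_epochs
        for frac in self.cfg.lr_decay_points:
            if epoch >= frac * self.cfg.epochs:
                lr *= self.cfg.lr_decay_factor
        return lr

    def _prepare_scene(self, idx: int, epoch: int) -> Scene:
        cfg = self.cfg
        if not cfg.augment:
            return self.scenes[idx]
        if use_mosaic(epoch, cfg.epochs, cfg.mosaic_fraction):
            others = self.rng.integers(len(self.scenes), size=3)
            four = [self.scenes[idx]] + [self.scenes[i] for i in others]
            return mosaic(four, cfg.input_size, self.rng, self.aug_cfg)
        return standard_augment(self.scenes[idx], self.aug_cfg, self.rng)

    def _batch_loss(self, batch: list[Scene], train_mode: bool) -> Tensor:
        cfg = self.cfg
        imgs = np.stack(
            [
                np.ascontiguousarray(s.image.transpose(2, 0, 1), dtype=np.float32)
                / 255.0
                for s in batch
            ]
        )
        targets: list[Assignment] = []
        image_ids: list[int] = []
        anchor_groups = cfg.anchor_set().to_anchor_priors()
        for i, s in enumerate(batch):
            t = build_targets(
                s.boxes,
                anchor_groups,
                cfg.grids(),
                extended=True,
                input_size=cfg.input_size,
                ratio_threshold=cfg.ratio_threshold,
            )
            targets.extend(t)
            image_ids.extend([i] * len(t))
        self.model.train() if train_mode else self.model.eval()
        heads = self.model(Tensor(imgs))
        loss, _ = detection_loss(heads, targets, image_ids, cfg)
        return loss

    def _resize(self, scene: Scene) -> Scene:
        size = self.cfg.input_size
        if scene.image.shape[:2] == (size, size):
            return scene
        from skimage.transform import resize as _r

        img = np.clip(
            _r(scene.image, (size, size), preserve_range=True, anti_aliasing=False),
            0,
            255,
        ).astype(np.uint8)
        return Scene(image=img, boxes=scene.boxes, masks=None)

    def _recalibrate_bn(self) -> None:
        """Refresh BatchNorm running statistics with the final weights.

        During training the running averages chase a moving target; a few
        plain forward passes over the (unaugmented) training set with a
        cumulative-average update leave eval-mode statistics that match the
        converged network.
        """
        from .nn.layers import BatchNorm2d

        bns = [m for m in self.model.modules() if isinstance(m, BatchNorm2d)]
        if not bns:
            return
        for bn in bns:
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 0.0
        self.model.train()
        cfg = self.cfg
        batch_no = 0
        for start in range(0, len(self.scenes), cfg.batch_size):
            for bn in bns:
                bn.momentum = 1.0 / (batch_no + 1)  # cumulative average
            batch = [self._resize(s) for s in self.scenes[start : start + cfg.batch_size]]
            imgs = np.stack(
                [
                    np.ascontiguousarray(s.image.transpose(2, 0, 1), dtype=np.float32)
                    / 255.0
                    for s in batch
                ]
            )
            self.model(Tensor(imgs))
            batch_no += 1
        for bn in bns:
            bn.momentum = 0.03

    def train(self, log_fn=None) -> TrainLog:
        cfg = self.cfg
        train_losses: list[float] = []
        val_losses: list[float] = []
        best_val = np.inf
        best_epoch = 0
        best_state = None
        bad_epochs = 0
        n = len(self.scenes)
        for epoch in range(cfg.epochs):
            self.optimizer.lr = self._lr_at(epoch)
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idxs = order[start : start + cfg.batch_size]
                batch = [self._resize(self._prepare_scene(i, epoch)) for i in idxs]
                loss = self._batch_loss(batch, train_mode=True)
                self.optimizer.zero_grad()
                loss.backward()
                self.optimizer.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            train_losses.append(epoch_loss / max(n_batches, 1))

            # validation loss uses batch statistics (running BN stats are still
            # converging early in training); stats are snapshotted and restored
            # so the validation pass has no side effects
            from .nn.layers import BatchNorm2d

            bns = [m for m in self.model.modules() if isinstance(m, BatchNorm2d)]
            snap = [(bn.running_mean.copy(), bn.running_var.copy()) for bn in bns]
            val_pool = self.val_scenes or self.scenes
            vloss = 0.0
            nv = 0
            for start in range(0, len(val_pool), cfg.batch_size):
                vb = [self._resize(s) for s in val_pool[start : start + cfg.batch_size]]
                vloss += float(self._batch_loss(vb, train_mode=True).data)
                nv += 1
            for bn, (m, v) in zip(bns, snap):
                bn.running_mean[...] = m
                bn.running_var[...] = v
            val_losses.append(vloss / max(nv, 1))
            if log_fn:
                log_fn(epoch, train_losses[-1], val_losses[-1])

            if val_losses[-1] < best_val - 1e-9:
                best_val = val_losses[-1]
                best_epoch = epoch
                best_state = {k: v.copy() for k, v in self.model.named_state().items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
        if best_state is not None:
            self.model.load_state(best_state)
        self._recalibrate_bn()
        return TrainLog(
            train_losses=train_losses,
            val_losses=val_losses,
            stopped_epoch=len(train_losses) - 1,
            best_epoch=best_epoch,
        )


def save_checkpoint(model: Detector, cfg: TrainConfig, path: str | Path) -> None:
    state = model.named_state()
    meta = json.dumps(asdict(cfg))
    np.savez_compressed(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **state)


def load_checkpoint(path: str | Path) -> tuple[Detector, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        meta["anchors"] = [[tuple(p) for p in g] for g in meta["anchors"]]
        for key in ("lr_decay_points", "obj_balance"):
            meta[key] = tuple(meta[key])
        cfg = TrainConfig(**meta)
        manual_seed(cfg.seed)
        builder = build_improved_model if cfg.improved else build_baseline_model
        model = builder(
            cfg.num_classes,
            anchors=cfg.anchor_set(),
            width_multiple=cfg.width_multiple,
            depth_multiple=cfg.depth_multiple,
        )
        state = {k: data[k] for k in data.files if k != "__config__"}
        model.load_state(state)
    return model, cfg
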