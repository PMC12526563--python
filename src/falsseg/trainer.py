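"""Training and inference entry points.

Training follows the anchor-free YOLOv8 recipe: a task-aligned assigner
(top-k 10, alpha 0.5, beta 6.0) picks the foreground anchors each step, the
box branch is optimised with CIoU + distribution-focal loss on the decoded
side distances, classification with BCE against the aligned soft scores, and
masks with box-cropped BCE between the assembled prototype combination and
the rasterised ground truth.  A config switch (``loss_mode="paper_eqs"``)
swaps in the printed formulation instead: summed squared coordinate errors,
plain cross-entropy, the same DFL term, and BCE+Dice on the masks.

Everything is deterministic for a fixed seed: weight init, batch shuffling
and the phantom data itself all derive from it.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import autograd as ag
from .autograd import SGD, Adam, Tensor
from .evaluation import GroundTruth, InstancePrediction, nms
from .lscshn import bce_with_logits, ciou_tensor, dfl_loss_tensor
from .model_zoo import FalsModel, build_model
from .phantoms import load_image, rasterize_polygon, read_yolo_seg_labels


@dataclass
class TrainConfig:
    epochs: int = 120
    batch: int = 32
    optimizer: str = "SGD"
    learning_rate: float = 0.001
    momentum: float = 0.973
    weight_decay: float = 0.0005
    workers: int = 4
    image_size: int = 640
    seed: int = 0
    loss_mode: str = "yolov8_default"  # or "paper_eqs"
    conf_floor: float = 0.001
    nms_iou: float = 0.7
    warmup_epochs: float = 1.0
    lr_final_frac: float = 0.1  # linear decay of lr to this fraction
    flip_augment: bool = True   # random horizontal/vertical flips
    mosaic: bool = False        # heavy augmentation off by default
    ema_decay: float = 0.99     # weight EMA used for validation/checkpoints
    grad_clip_norm: float = 10.0  # global gradient-norm clip (0 disables)
    cls_loss: str = "bce"       # "bce" or "varifocal" (IoU-aware ranking loss)
    varifocal_gamma: float = 2.0
    swa_epochs: int = 0         # average the weights of the last k epochs
    bn_recalibrate: bool = True  # refresh BN stats with the final weights
    # loss weights (box / cls / dfl / seg)
    w_box: float = 7.5
    w_cls: float = 0.5
    w_dfl: float = 1.5
    w_seg: float = 1.0

    def __post_init__(self):
        for name in ("epochs", "batch", "learning_rate", "momentum",
                     "weight_decay", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loss_mode not in ("yolov8_default", "paper_eqs"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")

    @classmethod
    def from_yaml(cls, path, **overrides):
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# anchors & target assignment
# ---------------------------------------------------------------------------


def make_anchors(size: int, strides=(8, 16, 32)) -> tuple[np.ndarray, np.ndarray]:
    """Anchor centre points in pixels and per-anchor stride."""
    pts, sts = [], []
    for s in strides:
        n = size // s
        xs, ys = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5)
        pts.append(np.stack([xs.ravel(), ys.ravel()], axis=1) * s)
        sts.append(np.full(n * n, s, np.float32))
    return np.concatenate(pts).astype(np.float32), np.concatenate(sts)


def task_aligned_assign(scores, pred_boxes, anchors, gt_boxes, gt_cls,
                        topk: int = 10, alpha: float = 0.5, beta: float = 6.0):
    """Task-aligned label assignment for one image.

    scores (A, nc) class probabilities, pred_boxes (A, 4) xyxy pixels,
    anchors (A, 2) centre points, gt_boxes (M, 4), gt_cls (M,).
    Returns (fg_idx, gt_idx per fg, target_scores (A, nc))."""
    a = anchors.shape[0]
    m = gt_boxes.shape[0]
    nc = scores.shape[1]
    target_scores = np.zeros((a, nc), np.float32)
    if m == 0:
        return np.empty(0, int), np.empty(0, int), target_scores
    inside = (
        (anchors[:, 0][:, None] > gt_boxes[None, :, 0])
        & (anchors[:, 0][:, None] < gt_boxes[None, :, 2])
        & (anchors[:, 1][:, None] > gt_boxes[None, :, 1])
        & (anchors[:, 1][:, None] < gt_boxes[None, :, 3])
    )  # (A, M)
    ious = _iou_matrix(pred_boxes, gt_boxes)  # (A, M)
    cls_p = scores[:, gt_cls]  # (A, M)
    align = (cls_p**alpha) * (ious**beta) * inside
    # top-k anchors per gt
    cand = np.zeros_like(inside)
    k = min(topk, a)
    top = np.argpartition(-align, k - 1, axis=0)[:k]
    for j in range(m):
        sel = top[:, j]
        sel = sel[align[sel, j] > 0]
        cand[sel, j] = True
    # resolve anchors claimed by several gts: keep highest IoU
    claimed = cand.sum(axis=1)
    multi = claimed > 1
    if multi.any():
        best = ious.argmax(axis=1)
        cand[multi] = False
        cand[np.nonzero(multi)[0], best[multi]] = True
    fg = cand.any(axis=1)
    fg_idx = np.nonzero(fg)[0]
    gt_idx = cand[fg_idx].argmax(axis=1)
    # normalised target scores
    pos_align = align * cand
    for j in range(m):
        amax = pos_align[:, j].max()
        if amax > 0:
            pos_align[:, j] *= ious[:, j][cand[:, j]].max() / amax
    target_scores[fg_idx, gt_cls[gt_idx]] = pos_align[fg_idx, gt_idx]
    return fg_idx, gt_idx, target_scores


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    aa = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    bb = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.maximum(aa[:, None] + bb[None, :] - inter, 1e-9)


# ---------------------------------------------------------------------------
# loss computation
# ---------------------------------------------------------------------------


def _flatten_outputs(out: dict, reg_max: int):
    """Per-scale maps -> concatenated (N, ..., A) tensors."""
    n = out["cls"][0].shape[0]
    box = ag.concat(
        [t.reshape(n, 4, reg_max, t.shape[2] * t.shape[3]) for t in out["box"]], axis=3
    )
    cls = ag.concat(
        [t.reshape(n, t.shape[1], t.shape[2] * t.shape[3]) for t in out["cls"]], axis=2
    )
    mc = ag.concat(
        [t.reshape(n, t.shape[1], t.shape[2] * t.shape[3]) for t in out["mc"]], axis=2
    )
    return box, cls, mc


def compute_loss(model: FalsModel, out: dict, targets: list[dict], size: int,
                 cfg: TrainConfig):
    """Batch loss; returns (total Tensor, components dict of floats)."""
    reg_max = model.head.cfg.reg_max
    box_t, cls_t, mc_t = _flatten_outputs(out, reg_max)
    proto_t = out["proto"]
    n, _, hp, wp = proto_t.shape
    anchors, strides = make_anchors(size, model.strides)
    a_grid = anchors / strides[:, None]  # grid units

    # decoded distances (expectation over bins) as a Tensor, (N, 4, A)
    dist_t = model.head.dfl(box_t)
    # pixel boxes for assignment (no grad needed)
    dist = dist_t.data
    boxes_px = np.stack(
        [
            anchors[None, :, 0] - dist[:, 0] * strides[None],
            anchors[None, :, 1] - dist[:, 1] * strides[None],
            anchors[None, :, 0] + dist[:, 2] * strides[None],
            anchors[None, :, 1] + dist[:, 3] * strides[None],
        ],
        axis=1,
    )  # (N, 4, A)
    probs = 1.0 / (1.0 + np.exp(-np.clip(cls_t.data, -60, 60)))  # (N, nc, A)

    total_cls = None
    total_box = None
    total_dfl = None
    total_seg = None
    score_sum = 0.0
    n_fg_total = 0
    for i in range(n):
        gt = targets[i]
        gt_boxes, gt_cls = gt["boxes"], gt["classes"]
        fg, gti, tscore = task_aligned_assign(
            probs[i].T, boxes_px[i].T, anchors, gt_boxes, gt_cls
        )
        score_sum += tscore.sum()
        n_fg_total += len(fg)
        # classification over every anchor
        cls_i = cls_t[i]  # (nc, A)
        tsT = tscore.T.astype(np.float32)
        bce = bce_with_logits(cls_i, tsT)
        if cfg.cls_loss == "varifocal":
            # positives weighted by their aligned quality, easy negatives
            # down-weighted by p^gamma (weights detached)
            p_det = 1.0 / (1.0 + np.exp(-np.clip(cls_i.data, -60, 60)))
            w = np.where(tsT > 0, tsT, p_det ** cfg.varifocal_gamma)
            bce = bce * Tensor(w.astype(np.float32))
        total_cls = bce.sum() if total_cls is None else total_cls + bce.sum()
        if len(fg) == 0:
            continue
        w = tscore[fg, gt_cls[gti]].astype(np.float32)
        gt_b = gt_boxes[gti]
        if cfg.loss_mode == "paper_eqs":
            # printed form: summed squared coordinate error (image-normalised)
            pb = _gather_boxes(dist_t, i, fg, anchors, strides)
            diff = (pb - Tensor(gt_b.astype(np.float32))) * (1.0 / size)
            box_l = (diff**2).sum()
        else:
            pb = _gather_boxes(dist_t, i, fg, anchors, strides)
            ciou = ciou_tensor(pb, gt_b)
            box_l = ((1.0 - ciou) * Tensor(w)).sum()
        total_box = box_l if total_box is None else total_box + box_l
        # DFL on the side distances in grid units
        g_ltrb = np.stack(
            [
                a_grid[fg, 0] - gt_b[:, 0] / strides[fg],
                a_grid[fg, 1] - gt_b[:, 1] / strides[fg],
                gt_b[:, 2] / strides[fg] - a_grid[fg, 0],
                gt_b[:, 3] / strides[fg] - a_grid[fg, 1],
            ],
            axis=1,
        )
        logits_fg = box_t[i].transpose(2, 0, 1)[fg]  # (F, 4, reg_max)
        dfl_l = dfl_loss_tensor(logits_fg, g_ltrb, w)
        total_dfl = dfl_l if total_dfl is None else total_dfl + dfl_l
        # mask loss
        seg_l = _mask_loss(proto_t, mc_t, i, fg, gti, gt, size, (hp, wp), cfg)
        total_seg = seg_l if total_seg is None else total_seg + seg_l

    denom = max(score_sum, 1.0)
    zero = Tensor(np.float32(0.0))
    comp = {
        "cls": (total_cls if total_cls is not None else zero) / denom,
        "box": (total_box if total_box is not None else zero) / denom,
        "dfl": (total_dfl if total_dfl is not None else zero) / denom,
        "seg": (total_seg if total_seg is not None else zero) / max(n_fg_total, 1),
    }
    total = (
        comp["box"] * cfg.w_box
        + comp["cls"] * cfg.w_cls
        + comp["dfl"] * cfg.w_dfl
        + comp["seg"] * cfg.w_seg
    )
    return total, {k: float(v.data) for k, v in comp.items()}


def _gather_boxes(dist_t: Tensor, i: int, fg: np.ndarray, anchors, strides) -> Tensor:
    d = dist_t[i].transpose(1, 0)[fg]  # (F, 4)
    ax = Tensor(anchors[fg].astype(np.float32))
    st = Tensor(strides[fg, None].astype(np.float32))
    x1 = ax[:, 0] - d[:, 0] * st[:, 0]
    y1 = ax[:, 1] - d[:, 1] * st[:, 0]
    x2 = ax[:, 0] + d[:, 2] * st[:, 0]
    y2 = ax[:, 1] + d[:, 3] * st[:, 0]
    return ag.stack([x1, y1, x2, y2], axis=1)


def _mask_loss(proto_t, mc_t, i, fg, gti, gt, size, proto_hw, cfg) -> Tensor:
    hp, wp = proto_hw
    protos = proto_t[i].reshape(proto_t.shape[1], hp * wp)  # (nm, P)
    coeffs = mc_t[i].transpose(1, 0)[fg]  # (F, nm)
    logits = coeffs.matmul(protos)  # (F, P)
    masks_small = gt["masks_small"][gti]  # (F, hp, wp) float
    boxes = gt["boxes"][gti] * (hp / size)  # proto-scale boxes
    yy, xx = np.mgrid[0:hp, 0:wp]
    inbox = (
        (xx[None] + 0.5 >= boxes[:, 0, None, None])
        & (xx[None] + 0.5 <= boxes[:, 2, None, None])
        & (yy[None] + 0.5 >= boxes[:, 1, None, None])
        & (yy[None] + 0.5 <= boxes[:, 3, None, None])
    ).astype(np.float32)
    area = np.maximum(inbox.reshape(len(fg), -1).sum(axis=1), 1.0)
    bce = bce_with_logits(logits, masks_small.reshape(len(fg), -1).astype(np.float32))
    per = (bce * Tensor(inbox.reshape(len(fg), -1))).sum(axis=1) / Tensor(
        area.astype(np.float32)
    )
    loss = per.sum()
    if cfg.loss_mode == "paper_eqs":
        # add the Dice term of the printed mask loss
        p = logits.sigmoid()
        msk = Tensor(masks_small.reshape(len(fg), -1).astype(np.float32))
        eps = 1.0
        dice = 1.0 - ((p * msk).sum() * 2.0 + eps) / (p.sum() + msk.sum() + eps)
        loss = loss + dice * len(fg)
    return loss


# ---------------------------------------------------------------------------
# data pipeline
# ---------------------------------------------------------------------------


def load_targets(entries, size: int):
    """(image path, instances) pairs -> arrays ready for the loss."""
    images, targets = [], []
    for img_path, instances in entries:
        images.append(load_image(img_path, size))
        boxes, classes, masks = [], [], []
        for inst in instances:
            poly = inst.polygon
            x1, y1 = poly.min(axis=0) * size
            x2, y2 = poly.max(axis=0) * size
            boxes.append([x1, y1, x2, y2])
            classes.append(inst.class_id)
            masks.append(rasterize_polygon(poly, size))
        targets.append(
            {
                "boxes": np.array(boxes, np.float32).reshape(-1, 4),
                "classes": np.array(classes, int),
                "masks": np.array(masks, bool).reshape(-1, size, size),
            }
        )
    return np.stack(images), targets


def _downsample_masks(targets, size: int, proto_hw):
    hp, wp = proto_hw
    f = size // hp
    for t in targets:
        m = t["masks"]
        if len(m):
            small = m.reshape(len(m), hp, f, wp, f).mean(axis=(2, 4))
            t["masks_small"] = (small >= 0.5).astype(np.float32)
        else:
            t["masks_small"] = np.zeros((0, hp, wp), np.float32)


def _flip_target(t: dict, size: int, hflip: bool, vflip: bool) -> dict:
    b = t["boxes"].copy()
    m = t["masks"]
    ms = t["masks_small"]
    if hflip:
        b = np.stack([size - t["boxes"][:, 2], b[:, 1], size - t["boxes"][:, 0], b[:, 3]], 1)
        m = np.flip(m, axis=-1)
        ms = np.flip(ms, axis=-1)
    if vflip:
        b = np.stack([b[:, 0], size - b[:, 3].copy(), b[:, 2], size - b[:, 1].copy()], 1)
        m = np.flip(m, axis=-2)
        ms = np.flip(ms, axis=-2)
    return {"boxes": np.ascontiguousarray(b), "classes": t["classes"],
            "masks": np.ascontiguousarray(m),
            "masks_small": np.ascontiguousarray(ms)}


def _flip_batch(xa, ta, size, rng):
    xa = xa.copy()
    out_t = []
    for i, t in enumerate(ta):
        hflip = bool(rng.random() < 0.5)
        vflip = bool(rng.random() < 0.5)
        if hflip:
            xa[i] = xa[i, :, :, ::-1]
        if vflip:
            xa[i] = xa[i, :, ::-1, :]
        out_t.append(_flip_target(t, size, hflip, vflip) if (hflip or vflip) else t)
    return xa, out_t


def _mosaic_batch(images, targets, n, size, rng):
    """Four half-scale phantoms tiled into one canvas per sample."""
    h2 = size // 2
    xa = np.zeros((n, 3, size, size), np.float32)
    out_t = []
    for i in range(n):
        picks = rng.integers(0, len(images), 4)
        boxes, classes, masks = [], [], []
        for q, j in enumerate(picks):
            oy, ox = (q // 2) * h2, (q % 2) * h2
            img = images[j].reshape(3, h2, 2, h2, 2).mean(axis=(2, 4))
            xa[i, :, oy : oy + h2, ox : ox + h2] = img
            t = targets[j]
            for b, c, m in zip(t["boxes"], t["classes"], t["masks"]):
                boxes.append(b * 0.5 + [ox, oy, ox, oy])
                classes.append(c)
                small = m.reshape(h2, 2, h2, 2).mean(axis=(1, 3)) >= 0.5
                full = np.zeros((size, size), bool)
                full[oy : oy + h2, ox : ox + h2] = small
                masks.append(full)
        t_new = {
            "boxes": np.array(boxes, np.float32).reshape(-1, 4),
            "classes": np.array(classes, int),
            "masks": np.array(masks, bool).reshape(-1, size, size),
        }
        _downsample_masks([t_new], size, (size // 4, size // 4))
        out_t.append(t_new)
    return xa, out_t


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


class NaNLossError(RuntimeError):
    pass


def train(variant_or_model, dataset_dir, cfg: TrainConfig, out_dir,
          log=print) -> dict:
    """Train on a YOLO-seg dataset; writes CSV logs and checkpoints.

    Returns {"history": per-epoch records, "best": path, "last": path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    if isinstance(variant_or_model, FalsModel):
        model = variant_or_model
    else:
        model = build_model(variant_or_model, seed=cfg.seed)
    size = cfg.image_size
    train_entries = read_yolo_seg_labels(dataset_dir, "train")
    val_entries = read_yolo_seg_labels(dataset_dir, "val")
    if not train_entries:
        raise ValueError(f"no training images found under {dataset_dir}")
    images, targets = load_targets(train_entries, size)
    vimages, vtargets = (load_targets(val_entries, size) if val_entries else (None, None))
    proto_hw = (size // 4, size // 4)
    _downsample_masks(targets, size, proto_hw)
    if vtargets:
        _downsample_masks(vtargets, size, proto_hw)

    if cfg.optimizer.lower() == "adam":
        opt = Adam(model.parameters(), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
    else:
        opt = SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum,
                  weight_decay=cfg.weight_decay)
    steps_per_epoch = int(np.ceil(len(images) / cfg.batch))
    warmup_steps = max(1, int(cfg.warmup_epochs * steps_per_epoch))
    total_steps = cfg.epochs * steps_per_epoch
    step = 0

    def lr_at(k: int) -> float:
        if k < warmup_steps:
            return cfg.learning_rate * (k + 1) / warmup_steps
        frac = (k - warmup_steps) / max(total_steps - warmup_steps, 1)
        return cfg.learning_rate * (1.0 - (1.0 - cfg.lr_final_frac) * frac)

    history = []
    ema = _EMA(model, cfg.ema_decay) if cfg.ema_decay else None
    swa_sum: dict | None = None
    swa_n = 0
    best_loss = np.inf
    csv_path = out / "losses.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "split", "box", "cls", "dfl", "seg", "total"])
        for epoch in range(cfg.epochs):
            t0 = time.time()
            order = rng.permutation(len(images))
            sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "seg": 0.0}
            nb = 0
            model.train()
            for start in range(0, len(order), cfg.batch):
                idx = order[start : start + cfg.batch]
                xa, ta = images[idx], [targets[j] for j in idx]
                if cfg.mosaic:
                    xa, ta = _mosaic_batch(images, targets, len(idx), size, rng)
                if cfg.flip_augment:
                    xa, ta = _flip_batch(xa, ta, size, rng)
                xb = Tensor(xa)
                tb = ta
                out_b = model(xb)
                total, comp = compute_loss(model, out_b, tb, size, cfg)
                if not np.isfinite(total.data):
                    raise NaNLossError(
                        f"non-finite loss at epoch {epoch}: {comp}"
                    )
                opt.zero_grad()
                total.backward()
                if cfg.grad_clip_norm:
                    _clip_grad_norm(model, cfg.grad_clip_norm)
                opt.lr = lr_at(step)
                opt.step()
                if ema is not None:
                    ema.update(model)
                step += 1
                for k in sums:
                    sums[k] += comp[k]
                nb += 1
            if cfg.swa_epochs and epoch >= cfg.epochs - cfg.swa_epochs:
                state = model.state_dict()
                if swa_sum is None:
                    swa_sum = {k: v.astype(np.float64) for k, v in state.items()}
                else:
                    for k, v in state.items():
                        if k.startswith("__bnstat"):
                            swa_sum[k] = v.astype(np.float64) * swa_n
                        swa_sum[k] += v
                swa_n += 1
            rec = {k: v / nb for k, v in sums.items()}
            rec.update(epoch=epoch, split="train",
                       total=sum(rec[k] for k in sums))
            history.append(rec)
            writer.writerow([epoch, "train", rec["box"], rec["cls"], rec["dfl"],
                             rec["seg"], rec["total"]])
            msg = (f"epoch {epoch}: box {rec['box']:.4f} cls {rec['cls']:.4f} "
                   f"dfl {rec['dfl']:.4f} seg {rec['seg']:.4f} "
                   f"({time.time()-t0:.1f}s)")
            if vtargets:
                eval_model = ema.applied(model) if ema is not None else model
                vrec = _eval_loss(eval_model, vimages, vtargets, size, cfg)
                vrec.update(epoch=epoch, split="val")
                history.append(vrec)
                writer.writerow([epoch, "val", vrec["box"], vrec["cls"],
                                 vrec["dfl"], vrec["seg"], vrec["total"]])
                msg += f" | val {vrec['total']:.4f}"
                if vrec["total"] < best_loss:
                    best_loss = vrec["total"]
                    save_checkpoint(eval_model, out / "best.npz", cfg)
            log(msg)
    if swa_sum is not None and swa_n > 0:
        final_model = build_model(model.variant, model.num_classes)
        final_model.load_state_dict(
            {k: (v / swa_n).astype(np.float32) for k, v in swa_sum.items()}
        )
    elif ema is not None:
        final_model = ema.applied(model)
    else:
        final_model = model
    if cfg.bn_recalibrate:
        recalibrate_bn(final_model, images, cfg.batch)
    save_checkpoint(final_model, out / "last.npz", cfg)
    if not (out / "best.npz").exists():
        save_checkpoint(final_model, out / "best.npz", cfg)
    return {"history": history, "best": out / "best.npz", "last": out / "last.npz",
            "model": final_model, "raw_model": model}


def recalibrate_bn(model: FalsModel, images: np.ndarray, batch: int = 8):
    """Recompute BatchNorm running statistics with the final weights.

    Running stats accumulated during training trail the weights (and are
    meaningless after weight averaging); one pass over the training images
    replaces them with the plain average of the per-batch statistics."""
    from .nn_primitives import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    sums = [(np.zeros_like(b.running_mean), np.zeros_like(b.running_var)) for b in bns]
    saved = [(b.running_mean.copy(), b.running_var.copy(), b.momentum) for b in bns]
    for b in bns:
        b.momentum = 1.0  # each forward stores the batch stats verbatim
    model.train()  # BN uses batch statistics only on the train-mode path
    n = 0
    for start in range(0, len(images), batch):
        xb = Tensor(images[start : start + batch])
        for b, (sm, sv) in zip(bns, sums):
            b.running_mean[...] = 0
            b.running_var[...] = 0
        model(xb)
        for b, (sm, sv) in zip(bns, sums):
            sm += b.running_mean
            sv += b.running_var
        n += 1
    for b, (sm, sv), (m0, v0, mom) in zip(bns, sums, saved):
        b.momentum = mom
        if n:
            b.running_mean[...] = sm / n
            b.running_var[...] = sv / n
        else:
            b.running_mean[...] = m0
            b.running_var[...] = v0
    return model


def _clip_grad_norm(model: FalsModel, max_norm: float):
    sq = 0.0
    grads = [p.grad for p in model.parameters() if p.grad is not None]
    for g in grads:
        sq += float((g.astype(np.float64) ** 2).sum())
    norm = np.sqrt(sq)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale


class _EMA:
    """Exponential moving average of the weights; evaluation and saved
    checkpoints use the averaged model (steadier than the raw iterate on
    short runs).  BatchNorm running statistics are copied, not averaged."""

    def __init__(self, model: FalsModel, decay: float):
        self.decay = decay
        self.shadow = {k: v.copy() for k, v in model.state_dict().items()}

    def update(self, model: FalsModel):
        d = self.decay
        for k, v in model.state_dict().items():
            if k.startswith("__bnstat"):
                self.shadow[k][...] = v
            else:
                self.shadow[k] *= d
                self.shadow[k] += (1.0 - d) * v

    def applied(self, model: FalsModel) -> FalsModel:
        clone = build_model(model.variant, model.num_classes)
        clone.load_state_dict(self.shadow)
        return clone


def _eval_loss(model, images, targets, size, cfg):
    sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "seg": 0.0}
    nb = 0
    model.eval()
    with ag.no_grad():
        for start in range(0, len(images), cfg.batch):
            xb = Tensor(images[start : start + cfg.batch])
            tb = targets[start : start + cfg.batch]
            out_b = model(xb)
            _, comp = compute_loss(model, out_b, tb, size, cfg)
            for k in sums:
                sums[k] += comp[k]
            nb += 1
    model.train()
    rec = {k: v / nb for k, v in sums.items()}
    rec["total"] = sum(rec.values())
    return rec


def save_checkpoint(model: FalsModel, path, cfg: TrainConfig | None = None):
    state = model.state_dict()
    meta = {"variant": model.variant, "num_classes": model.num_classes}
    if cfg is not None:
        meta["image_size"] = cfg.image_size
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> FalsModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    model = build_model(meta["variant"], meta["num_classes"])
    state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict_array(model: FalsModel, image: np.ndarray, conf_thr: float = 0.25,
                  nms_iou: float = 0.7, conf_floor: float | None = None,
                  max_det: int = 300) -> list[InstancePrediction]:
    """Run the model on one (3, H, W) image array; returns NMS-filtered
    instance predictions with binary masks at image resolution."""
    model.eval()
    size = image.shape[-1]
    thr = conf_thr if conf_floor is None else conf_floor
    with ag.no_grad():
        out = model(Tensor(image[None]))
    reg_max = model.head.cfg.reg_max
    box_l, cls_l, mc_l = [], [], []
    for b, c, m in zip(out["box"], out["cls"], out["mc"]):
        hw = b.shape[2] * b.shape[3]
        box_l.append(b.data.reshape(4, reg_max, hw))
        cls_l.append(c.data.reshape(c.shape[1], hw))
        mc_l.append(m.data.reshape(m.shape[1], hw))
    box = np.concatenate(box_l, axis=2)
    cls = np.concatenate(cls_l, axis=1)
    mc = np.concatenate(mc_l, axis=1)
    proto = out["proto"].data[0]  # (nm, hp, wp)
    anchors, strides = make_anchors(size, model.strides)
    dist = model.head.dfl.decode_np(box.transpose(2, 0, 1))  # (A, 4)
    boxes = np.stack(
        [
            anchors[:, 0] - dist[:, 0] * strides,
            anchors[:, 1] - dist[:, 1] * strides,
            anchors[:, 0] + dist[:, 2] * strides,
            anchors[:, 1] + dist[:, 3] * strides,
        ],
        axis=1,
    )
    probs = 1.0 / (1.0 + np.exp(-np.clip(cls, -60, 60)))  # (nc, A)
    conf = probs.max(axis=0)
    cids = probs.argmax(axis=0)
    keep = conf >= thr
    if not keep.any():
        return []
    boxes, conf, cids, mcs = boxes[keep], conf[keep], cids[keep], mc[:, keep].T
    kept = nms(boxes, conf, cids, nms_iou, max_det)
    preds = []
    hp, wp = proto.shape[1:]
    nm = proto.shape[0]
    proto_flat = proto.reshape(nm, hp * wp)
    for i in kept:
        logits = np.clip((mcs[i] @ proto_flat).reshape(hp, wp), -60.0, 60.0)
        msk = 1.0 / (1.0 + np.exp(-logits))
        # crop to the (proto-scale) box, then upsample to image size
        sb = boxes[i] * (hp / size)
        yy, xx = np.mgrid[0:hp, 0:wp]
        inside = ((xx + 0.5 >= sb[0]) & (xx + 0.5 <= sb[2])
                  & (yy + 0.5 >= sb[1]) & (yy + 0.5 <= sb[3]))
        msk = msk * inside
        full = _resize_bilinear_np(msk, size) > 0.5
        preds.append(InstancePrediction(boxes[i].copy(), int(cids[i]),
                                        float(conf[i]), full))
    return preds


def _resize_bilinear_np(m: np.ndarray, size: int) -> np.ndarray:
    t = ag.bilinear_resize(Tensor(m[None, None]), (size, size))
    return t.data[0, 0]


def ground_truths_from_instances(instances, size: int) -> list[GroundTruth]:
    gts = []
    for inst in instances:
        poly = inst.polygon
        box = np.array([*(poly.min(axis=0) * size), *(poly.max(axis=0) * size)])
        gts.append(GroundTruth(box, inst.class_id, rasterize_polygon(poly, size)))
    return gts


def predict_file(model: FalsModel, image_path, size: int | None = None, **kw):
    arr = load_image(image_path, size)
    return predict_array(model, arr, **kw)
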