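"""Segmentation heads and the training loss suite.

Two heads share one output schema (per-scale box-distribution logits, class
logits, mask coefficients, plus image-level prototype masks):

* `SegmentHead` — the standard decoupled YOLOv8n-Seg head (per-scale conv
  towers, BatchNorm convs), kept as the baseline;
* `LSCSHN` — the lightweight shared-convolution head: per-scale 1x1 Conv_GN
  compressors into one hidden width, a single weight-shared stack of two 3x3
  Conv_GN layers applied at every scale, one shared 1x1 regression final whose
  output is adjusted per scale by a learnable Scale scalar, one shared 1x1
  classification final, and per-scale mask-coefficient towers (1x1 Conv_GN,
  3x3 Conv_GN, 1x1 conv) fed by the raw neck features.  Prototype masks come
  from P3 through the usual Proto stack (3x3 conv, 2x transposed-conv
  upsample, 3x3 conv, 1x1 conv).

The loss functions of the printed formulation (sum-of-squares box loss,
cross-entropy classification, distribution focal loss, BCE+Dice mask loss)
are exposed as plain functions; the trainer may instead use the conventional
CIoU/BCE/task-aligned path (see trainer.py).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn_primitives import (
    DFL,
    Conv,
    Conv2d,
    ConvGN,
    ConvTranspose2d,
    Module,
    Scale,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class HeadConfig:
    num_classes: int = 3
    reg_max: int = 16
    num_mask_coeffs: int = 32
    proto_channels: int = 64
    hidden_width: int = 64
    gn_groups: int = 16

    def __post_init__(self):
        if self.num_classes < 1 or self.num_mask_coeffs < 1:
            raise ValueError("num_classes and num_mask_coeffs must be >= 1")
        if self.hidden_width % self.gn_groups:
            raise ValueError("hidden_width must be divisible by gn_groups")


# ---------------------------------------------------------------------------
# prototype masks
# ---------------------------------------------------------------------------


def _cls_bias(nc: int, stride: int, img: int = 640) -> float:
    """Prior-probability bias for classification logits (about 5 objects per
    640px image), which keeps the initial BCE loss from swamping training."""
    return float(np.log(5.0 / nc / (img / stride) ** 2))


class Proto(Module):
    """Prototype-mask generator on P3: two 3x3 convs around a 2x transposed
    convolution, then a 1x1 projection to the coefficient dimension."""

    def __init__(self, cin: int, cmid: int, nm: int, rng=None):
        super().__init__()
        self.cv1 = Conv(cin, cmid, 3, 1, rng=rng)
        self.upsample = ConvTranspose2d(cmid, cmid, 2, 2, bias=True, rng=rng)
        self.cv2 = Conv(cmid, cmid, 3, 1, rng=rng)
        self.cv3 = Conv(cmid, nm, 1, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.cv3(self.cv2(self.upsample(self.cv1(x))))


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------


class SegmentHead(Module):
    """Standard decoupled detection+segmentation head (baseline)."""

    def __init__(self, ch=(64, 128, 256), cfg: HeadConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or HeadConfig(num_mask_coeffs=32)
        self.cfg = cfg
        nc, rm, nm = cfg.num_classes, cfg.reg_max, cfg.num_mask_coeffs
        c2 = max(16, ch[0] // 4, rm * 4)
        c3 = max(ch[0], min(nc, 100))
        c4 = max(ch[0] // 4, nm)
        self.cv2 = [
            _Seq(Conv(x, c2, 3, rng=rng), Conv(c2, c2, 3, rng=rng),
                 Conv2d(c2, 4 * rm, 1, bias=True, rng=rng))
            for x in ch
        ]
        self.cv3 = [
            _Seq(Conv(x, c3, 3, rng=rng), Conv(c3, c3, 3, rng=rng),
                 Conv2d(c3, nc, 1, bias=True, rng=rng))
            for x in ch
        ]
        self.cv4 = [
            _Seq(Conv(x, c4, 3, rng=rng), Conv(c4, c4, 3, rng=rng),
                 Conv2d(c4, nm, 1, bias=True, rng=rng))
            for x in ch
        ]
        self.proto = Proto(ch[0], cfg.proto_channels, nm, rng=rng)
        self.dfl = DFL(rm)
        for m, s in zip(self.cv2, (8, 16, 32)):
            m.layers[-1].bias.data[...] = 1.0
        for m, s in zip(self.cv3, (8, 16, 32)):
            m.layers[-1].bias.data[...] = _cls_bias(nc, s)

    def __call__(self, feats: list[Tensor]) -> dict:
        out = {
            "box": [m(f) for m, f in zip(self.cv2, feats)],
            "cls": [m(f) for m, f in zip(self.cv3, feats)],
            "mc": [m(f) for m, f in zip(self.cv4, feats)],
            "proto": self.proto(feats[0]),
        }
        return out


class _Seq(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x):
        for l in self.layers:
            x = l(x)
        return x


class LSCSHN(Module):
    """Lightweight shared-convolution segmentation head."""

    def __init__(self, ch=(64, 128, 256), cfg: HeadConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or HeadConfig()
        self.cfg = cfg
        nc, rm, nm = cfg.num_classes, cfg.reg_max, cfg.num_mask_coeffs
        hw, g = cfg.hidden_width, cfg.gn_groups
        self.compress = [ConvGN(x, hw, 1, groups=g, rng=rng) for x in ch]
        self.share_conv = [ConvGN(hw, hw, 3, groups=g, rng=rng),
                           ConvGN(hw, hw, 3, groups=g, rng=rng)]
        self.conv_reg = Conv2d(hw, 4 * rm, 1, bias=True, rng=rng)  # shared
        self.scales = [Scale(1.0) for _ in ch]
        self.conv_cls = Conv2d(hw, nc, 1, bias=True, rng=rng)      # shared
        c4 = max(ch[0] // 4, nm)
        self.mask_tower = [
            _Seq(ConvGN(x, c4, 1, groups=min(g, c4), rng=rng),
                 ConvGN(c4, c4, 3, groups=min(g, c4), rng=rng),
                 Conv2d(c4, nm, 1, bias=True, rng=rng))
            for x in ch
        ]
        self.proto = Proto(ch[0], cfg.proto_channels, nm, rng=rng)
        self.dfl = DFL(rm)
        self.conv_reg.bias.data[...] = 1.0
        self.conv_cls.bias.data[...] = _cls_bias(nc, 16)  # middle stride

    def shared_feature_stack(self, feats: list[Tensor]) -> list[Tensor]:
        out = []
        for comp, f in zip(self.compress, feats):
            y = comp(f)
            for sc in self.share_conv:
                y = sc(y)
            out.append(y)
        return out

    def __call__(self, feats: list[Tensor]) -> dict:
        enhanced = self.shared_feature_stack(feats)
        return {
            "box": [s(self.conv_reg(y)) for s, y in zip(self.scales, enhanced)],
            "cls": [self.conv_cls(y) for y in enhanced],
            "mc": [m(f) for m, f in zip(self.mask_tower, feats)],
            "proto": self.proto(feats[0]),
        }


def proto_masks(p3: Tensor, cfg: HeadConfig, rng=None) -> Tensor:
    """Standalone prototype computation (stride-4 resolution for a stride-8
    input feature map)."""
    return Proto(p3.shape[1], cfg.proto_channels, cfg.num_mask_coeffs, rng=rng)(p3)


def assemble_instance_masks(prototypes: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """sigmoid(sum_k coeff_k * proto_k); prototypes (nm, H, W), coeffs (..., nm)."""
    nm, h, w = prototypes.shape
    logits = np.tensordot(coeffs, prototypes.reshape(nm, h * w), axes=([-1], [0]))
    logits = np.clip(logits, -60.0, 60.0)
    return (1.0 / (1.0 + np.exp(-logits))).reshape(*coeffs.shape[:-1], h, w)


# ---------------------------------------------------------------------------
# loss functions — printed formulation
# ---------------------------------------------------------------------------


def bbox_regression_loss(gt: np.ndarray, pred: np.ndarray) -> float:
    """Sum of squared coordinate differences over matched box pairs."""
    gt = np.asarray(gt, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    return float(((gt - pred) ** 2).sum())


def classification_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Cross-entropy -sum_c y_oc log p_oc, probabilities clipped to
    [1e-7, 1-1e-7]."""
    p = np.clip(np.asarray(p, dtype=np.float64), 1e-7, 1.0 - 1e-7)
    return float(-(np.asarray(y, dtype=np.float64) * np.log(p)).sum())


def dfl_target_distribution(target: float, reg_max: int) -> np.ndarray:
    """Linear-interpolation target over the two integer bins bracketing the
    continuous distance."""
    t = float(target)
    if not 0.0 <= t <= reg_max - 1:
        warnings.warn(f"DFL target {t} outside [0, {reg_max - 1}]; clamping")
        t = float(np.clip(t, 0.0, reg_max - 1))
    lo = int(np.floor(t))
    hi = min(lo + 1, reg_max - 1)
    q = np.zeros(reg_max)
    q[lo] += (hi - t) if hi != lo else 1.0
    q[hi] += t - lo
    return q


def distribution_focal_loss(logits: np.ndarray, target: float) -> float:
    """sum_i -log(p_i) * q_i with p = softmax(logits) and q the bracketing
    target distribution."""
    logits = np.asarray(logits, dtype=np.float64)
    reg_max = logits.shape[-1]
    z = logits - logits.max()
    p = np.exp(z) / np.exp(z).sum()
    q = dfl_target_distribution(target, reg_max)
    mask = q > 0
    return float(-(np.log(np.clip(p[mask], 1e-12, None)) * q[mask]).sum())


def segmentation_loss(pred: np.ndarray, gt: np.ndarray, eps: float = 1.0) -> float:
    """BCE + Dice loss between a predicted soft mask and a binary mask."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    p = np.clip(pred, 1e-7, 1.0 - 1e-7)
    bce = float(-(gt * np.log(p) + (1 - gt) * np.log(1 - p)).mean())
    dice = 1.0 - (2.0 * (pred * gt).sum() + eps) / (pred.sum() + gt.sum() + eps)
    return bce + float(dice)


# ---------------------------------------------------------------------------
# differentiable loss pieces for the trainer
# ---------------------------------------------------------------------------


def bce_with_logits(z: Tensor, y: np.ndarray | Tensor, weight=None) -> Tensor:
    """Numerically stable elementwise BCE on logits; returns the elementwise
    loss tensor (caller reduces)."""
    yt = y if isinstance(y, Tensor) else Tensor(np.asarray(y, np.float32))
    zero = Tensor(np.zeros(1, np.float32))
    loss = ag.maximum(z, zero) - z * yt + ((-(z.abs())).exp() + 1.0).log()
    if weight is not None:
        loss = loss * weight
    return loss


def dfl_loss_tensor(logits: Tensor, target: np.ndarray, weight: np.ndarray) -> Tensor:
    """Distribution focal loss over matched anchors.

    logits (N, 4, reg_max); target (N, 4) continuous distances in bin units;
    weight (N,) per-anchor weights.  Returns the weighted sum.
    """
    n, _, reg_max = logits.shape
    t = np.clip(target, 0, reg_max - 1 - 1e-3)
    lo = np.floor(t).astype(int)
    hi = lo + 1
    wl = (hi - t).astype(np.float32)
    wh = (t - lo).astype(np.float32)
    logp = logits - ((logits - logits.data.max(axis=-1, keepdims=True)).exp().sum(
        axis=-1, keepdims=True)).log() - Tensor(logits.data.max(axis=-1, keepdims=True))
    ii = np.arange(n)[:, None]
    jj = np.arange(4)[None, :]
    nll = -(logp[ii, jj, lo] * Tensor(wl) + logp[ii, jj, hi] * Tensor(wh))
    return (nll.mean(axis=1) * Tensor(weight.astype(np.float32))).sum()


def ciou_tensor(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Complete-IoU between predicted boxes (N,4 xyxy, Tensor) and fixed
    ground-truth boxes (N,4 xyxy)."""
    g = Tensor(np.asarray(gt, np.float32))
    px1, py1, px2, py2 = (pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3])
    gx1, gy1, gx2, gy2 = (g[:, 0], g[:, 1], g[:, 2], g[:, 3])
    ix1 = ag.maximum(px1, gx1)
    iy1 = ag.maximum(py1, gy1)
    ix2 = _minimum(px2, gx2)
    iy2 = _minimum(py2, gy2)
    zero = Tensor(np.zeros(1, np.float32))
    iw = ag.maximum(ix2 - ix1, zero)
    ih = ag.maximum(iy2 - iy1, zero)
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter + 1e-7
    iou = inter / union
    # enclosing box diagonal + centre distance
    cx1 = _minimum(px1, gx1)
    cy1 = _minimum(py1, gy1)
    cx2 = ag.maximum(px2, gx2)
    cy2 = ag.maximum(py2, gy2)
    c2 = (cx2 - cx1) ** 2 + (cy2 - cy1) ** 2 + 1e-7
    rho2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) * 0.25
    # aspect-ratio term
    wg = gx2 - gx1 + 1e-7
    hg = gy2 - gy1 + 1e-7
    wp = px2 - px1 + 1e-7
    hp = py2 - py1 + 1e-7
    v = (_atan(wg / hg) - _atan(wp / hp)) ** 2 * (4.0 / np.pi**2)
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + 1e-7))
    return iou - rho2 / c2 - v * alpha


def _minimum(a: Tensor, b: Tensor) -> Tensor:
    return -ag.maximum(-a, -b)


def _atan(x: Tensor) -> Tensor:
    d = np.arctan(x.data)
    grad_fac = 1.0 / (1.0 + x.data**2)

    def backward(g):
        x._accumulate(g * grad_fac)

    return Tensor._make(d, (x,), backward)
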