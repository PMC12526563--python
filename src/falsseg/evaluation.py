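"""Detection/segmentation metrics: PR curves, AP, mAP@0.5, confusion matrix.

Precision = TP/(TP+FP) and Recall = TP/(TP+FN); AP integrates the
monotone-envelope precision over recall (all-point interpolation, the
continuous form of the PR integral); mAP@0.5 averages per-class APs at an
IoU threshold of 0.5.  Matching is greedy in descending confidence with each
ground truth consumed at most once; IoU is computed on boxes (task "box") or
binary masks (task "mask").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class InstancePrediction:
    box: np.ndarray            # xyxy pixels
    class_id: int
    confidence: float
    mask: np.ndarray | None = None  # binary HxW


@dataclass
class GroundTruth:
    box: np.ndarray
    class_id: int
    mask: np.ndarray | None = None


@dataclass
class MetricCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


def box_iou(a: np.ndarray, b: np.ndarray) -> float:
    x1 = max(a[0], b[0]); y1 = max(a[1], b[1])
    x2 = min(a[2], b[2]); y2 = min(a[3], b[3])
    inter = max(0.0, x2 - x1) * max(0.0, y2 - y1)
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


def _pair_iou(p: InstancePrediction, g: GroundTruth, task: str) -> float:
    if task == "mask":
        if p.mask is None or g.mask is None:
            return 0.0
        return mask_iou(p.mask, g.mask)
    return box_iou(p.box, g.box)


def match_instances(preds, gts, iou_thr: float = 0.5, task: str = "box"):
    """Greedy per-image matching; returns (MetricCounts, outcomes) where
    outcomes is the confidence-sorted list of (confidence, is_tp) used for
    the PR curve.  Class-aware: a prediction can only match a ground truth of
    its own class."""
    order = np.argsort([-p.confidence for p in preds], kind="stable")
    used = [False] * len(gts)
    outcomes = []
    for i in order:
        p = preds[i]
        best, best_iou = -1, iou_thr
        for j, g in enumerate(gts):
            if used[j] or g.class_id != p.class_id:
                continue
            iou = _pair_iou(p, g, task)
            if iou >= best_iou:
                best, best_iou = j, iou
        if best >= 0:
            used[best] = True
            outcomes.append((p.confidence, True))
        else:
            outcomes.append((p.confidence, False))
    tp = sum(1 for _, ok in outcomes if ok)
    counts = MetricCounts(tp=tp, fp=len(outcomes) - tp, fn=len(gts) - tp)
    return counts, outcomes


def precision_recall(counts: MetricCounts) -> tuple[float, float]:
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return p, r


def average_precision(outcomes, n_gt: int) -> float:
    """All-point interpolated AP from scored (confidence, is_tp) outcomes.

    Precision is replaced by its monotone non-increasing envelope and
    integrated over recall.  Undefined (returns nan) when n_gt == 0."""
    if n_gt == 0:
        warnings.warn("AP undefined for a class with no ground-truth instances")
        return float("nan")
    if not outcomes:
        return 0.0
    order = sorted(outcomes, key=lambda t: -t[0])
    tps = np.cumsum([1.0 if ok else 0.0 for _, ok in order])
    fps = np.cumsum([0.0 if ok else 1.0 for _, ok in order])
    recall = tps / n_gt
    precision = tps / np.maximum(tps + fps, 1e-12)
    # monotone envelope
    r = np.concatenate(([0.0], recall, [1.0]))
    p = np.concatenate(([1.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def mean_ap(per_class_aps) -> float:
    """Arithmetic mean over classes with defined (non-nan) AP."""
    vals = [a for a in per_class_aps if not np.isnan(a)]
    if not vals:
        raise ValueError("no class has a defined AP")
    return float(np.mean(vals))


@dataclass
class EvalResult:
    per_class: dict = field(default_factory=dict)  # cls -> (P, R, AP)
    map50: float = float("nan")


def evaluate(all_preds, all_gts, num_classes: int, iou_thr: float = 0.5,
             task: str = "box") -> EvalResult:
    """Dataset-level evaluation.

    all_preds / all_gts: lists over images of per-image instance lists."""
    res = EvalResult()
    aps = []
    for c in range(num_classes):
        outcomes = []
        n_gt = 0
        tp = fp = 0
        for preds, gts in zip(all_preds, all_gts):
            pc = [p for p in preds if p.class_id == c]
            gc = [g for g in gts if g.class_id == c]
            n_gt += len(gc)
            counts, outc = match_instances(pc, gc, iou_thr, task)
            outcomes.extend(outc)
            tp += counts.tp
            fp += counts.fp
        ap = average_precision(outcomes, n_gt)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / n_gt if n_gt else 0.0
        res.per_class[c] = (prec, rec, ap)
        aps.append(ap)
    defined = [a for a in aps if not np.isnan(a)]
    if defined:
        res.map50 = float(np.mean(defined))
    return res


def confusion_matrix(all_preds, all_gts, num_classes: int,
                     conf_thr: float = 0.25, iou_thr: float = 0.5,
                     task: str = "box") -> np.ndarray:
    """(num_classes+1) x (num_classes+1) matrix; rows = true class (last row
    background), columns = predicted class (last column background).
    Matching here ignores class so cross-class confusions are visible."""
    m = np.zeros((num_classes + 1, num_classes + 1), dtype=int)
    bg = num_classes
    for preds, gts in zip(all_preds, all_gts):
        preds = [p for p in preds if p.confidence >= conf_thr]
        order = np.argsort([-p.confidence for p in preds], kind="stable")
        used = [False] * len(gts)
        for i in order:
            p = preds[i]
            best, best_iou = -1, iou_thr
            for j, g in enumerate(gts):
                if used[j]:
                    continue
                iou = _pair_iou(p, g, task)
                if iou >= best_iou:
                    best, best_iou = j, iou
            if best >= 0:
                used[best] = True
                m[gts[best].class_id, p.class_id] += 1
            else:
                m[bg, p.class_id] += 1
        for j, g in enumerate(gts):
            if not used[j]:
                m[g.class_id, bg] += 1
    return m


def nms(boxes: np.ndarray, scores: np.ndarray, classes: np.ndarray,
        iou_thr: float = 0.7, max_det: int = 300) -> np.ndarray:
    """Class-aware non-maximum suppression; returns kept indices."""
    keep = []
    order = np.argsort(-scores, kind="stable")
    suppressed = np.zeros(len(boxes), bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        if len(keep) >= max_det:
            break
        for j in order:
            if suppressed[j] or j == i:
                continue
            if classes[j] == classes[i] and box_iou(boxes[i], boxes[j]) > iou_thr:
                suppressed[j] = True
    return np.array(keep, dtype=int)
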