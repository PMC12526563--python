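"""Metrics: matching rules, AP integration oracle, mAP arithmetic,
confusion-matrix conservation."""

import numpy as np
import pytest

from falsseg.evaluation import (
    GroundTruth,
    InstancePrediction,
    average_precision,
    box_iou,
    confusion_matrix,
    evaluate,
    mask_iou,
    match_instances,
    mean_ap,
    nms,
    precision_recall,
)

RNG = np.random.default_rng(17)


def pred(box, cls=0, conf=0.9, mask=None):
    return InstancePrediction(np.asarray(box, float), cls, conf, mask)


def gt(box, cls=0, mask=None):
    return GroundTruth(np.asarray(box, float), cls, mask)


class TestMatching:
    def test_clean_hit(self):
        counts, _ = match_instances([pred([0, 0, 10, 10])], [gt([0, 0, 10, 12])])
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)

    def test_duplicate_prediction_penalised(self):
        preds = [pred([0, 0, 10, 10], conf=0.9), pred([1, 0, 10, 10], conf=0.8)]
        counts, _ = match_instances(preds, [gt([0, 0, 10, 10])])
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)

    def test_wrong_class_never_matches(self):
        counts, _ = match_instances([pred([0, 0, 10, 10], cls=1)], [gt([0, 0, 10, 10], cls=0)])
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_mask_task_uses_mask_iou(self):
        a = np.zeros((20, 20), bool)
        a[:10] = True
        b = np.zeros((20, 20), bool)
        b[5:15] = True  # IoU = 5/15 < 0.5
        counts, _ = match_instances(
            [pred([0, 0, 20, 20], mask=a)], [gt([0, 0, 20, 20], mask=b)], task="mask"
        )
        assert counts.tp == 0

    def test_greedy_counts_match_bruteforce_assignment(self):
        """On small random scenes the greedy TP count equals the best
        achievable assignment (exhaustive over injective pred->gt maps)."""
        for trial in range(30):
            rng = np.random.default_rng(trial)
            gts = [gt(_rand_box(rng)) for _ in range(rng.integers(1, 4))]
            preds = [pred(_jitter(rng, g.box) if rng.random() < 0.7 else _rand_box(rng),
                          conf=float(rng.random()))
                     for g in gts for _ in range(rng.integers(1, 3))]
            counts, _ = match_instances(preds, gts, 0.5)
            best = _bruteforce_tp(preds, gts, 0.5)
            # greedy-by-confidence is optimal except for rare ambiguous
            # overlap patterns; require equality when unambiguous
            if not _ambiguous(preds, gts, 0.5):
                assert counts.tp == best

    def test_precision_recall_formulas(self):
        counts, _ = match_instances(
            [pred([0, 0, 10, 10]), pred([50, 50, 60, 60])], [gt([0, 0, 10, 10])]
        )
        p, r = precision_recall(counts)
        assert p == 0.5 and r == 1.0


def _rand_box(rng):
    x, y = rng.uniform(0, 50, 2)
    w, h = rng.uniform(10, 30, 2)
    return np.array([x, y, x + w, y + h])


def _jitter(rng, box):
    return box + rng.uniform(-2, 2, 4)


def _bruteforce_tp(preds, gts, thr):
    """Maximum-TP assignment: size of a maximum bipartite matching over
    admissible (same class, IoU >= thr) prediction/ground-truth pairs."""
    edges = [
        [g_i for g_i, g in enumerate(gts)
         if g.class_id == p.class_id and box_iou(p.box, g.box) >= thr]
        for p in preds
    ]
    match_of_gt = {}

    def try_assign(p_i, seen):
        for g_i in edges[p_i]:
            if g_i in seen:
                continue
            seen.add(g_i)
            if g_i not in match_of_gt or try_assign(match_of_gt[g_i], seen):
                match_of_gt[g_i] = p_i
                return True
        return False

    return sum(try_assign(p_i, set()) for p_i in range(len(preds)))


def _ambiguous(preds, gts, thr):
    # a gt reachable (>= thr) by two different predictions
    reach = np.zeros(len(gts), int)
    for g_i, g in enumerate(gts):
        for p in preds:
            if p.class_id == g.class_id and box_iou(p.box, g.box) >= thr:
                reach[g_i] += 1
    return (reach > 1).any()


class TestAveragePrecision:
    def test_perfect_detector(self):
        outcomes = [(0.9, True), (0.8, True)]
        assert average_precision(outcomes, 2) == pytest.approx(1.0)

    def test_total_miss(self):
        with np.errstate(all="ignore"):
            assert average_precision([], 1) == 0.0

    def test_hand_computed_envelope(self):
        # 2 GTs, ranked outcomes (TP, FP, TP): AP = 0.5*1 + 0.5*(2/3) = 5/6
        outcomes = [(0.9, True), (0.8, False), (0.7, True)]
        assert average_precision(outcomes, 2) == pytest.approx(5 / 6)

    def test_zero_gt_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(average_precision([(0.5, False)], 0))

    def test_matches_fine_grid_riemann_oracle(self):
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            n = int(rng.integers(3, 30))
            outcomes = [(float(rng.random()), bool(rng.random() < 0.6)) for _ in range(n)]
            n_gt = sum(ok for _, ok in outcomes) + int(rng.integers(0, 4))
            if n_gt == 0:
                continue
            got = average_precision(outcomes, n_gt)
            want = _riemann_ap(outcomes, n_gt, 100001)
            assert got == pytest.approx(want, abs=1e-4)


def _riemann_ap(outcomes, n_gt, grid):
    """Independent oracle: envelope precision sampled on a dense recall grid."""
    order = sorted(outcomes, key=lambda t: -t[0])
    tp = np.cumsum([1.0 if ok else 0.0 for _, ok in order])
    fp = np.cumsum([0.0 if ok else 1.0 for _, ok in order])
    rec = tp / n_gt
    prec = tp / np.maximum(tp + fp, 1e-12)
    rs = np.linspace(0, 1, grid)
    ps = np.zeros_like(rs)
    for i, r in enumerate(rs):
        cand = prec[rec >= r - 1e-12]
        ps[i] = cand.max() if len(cand) else 0.0
    return float(np.trapezoid(ps, rs))


class TestMeanAP:
    def test_published_per_class_mean(self):
        # the worked example: three per-class APs -> printed all-class mean
        assert mean_ap([0.811, 0.975, 0.959]) == pytest.approx(0.915, abs=5e-4)
        assert mean_ap([0.812, 0.975, 0.961]) == pytest.approx(0.916, abs=5e-4)

    def test_single_class(self):
        assert mean_ap([0.7]) == 0.7

    def test_permutation_invariant(self):
        aps = [0.1, 0.5, 0.9]
        assert mean_ap(aps) == mean_ap(aps[::-1])

    def test_nan_classes_omitted(self):
        assert mean_ap([0.8, float("nan")]) == pytest.approx(0.8)


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        preds = [[pred([0, 0, 10, 10], cls=c, conf=0.9) for c in range(3)]]
        gts = [[gt([0, 0, 10, 10], cls=c) for c in range(3)]]
        # separate the boxes so matching is unambiguous
        for i, (p, g) in enumerate(zip(preds[0], gts[0])):
            p.box = p.box + 20 * i
            g.box = g.box + 20 * i
        m = confusion_matrix(preds, gts, 3)
        assert np.array_equal(m[:3, :3], np.eye(3, dtype=int))

    def test_cross_class_swap_recorded(self):
        m = confusion_matrix([[pred([0, 0, 10, 10], cls=1, conf=0.9)]],
                             [[gt([0, 0, 10, 11], cls=0)]], 3)
        assert m[0, 1] == 1

    def test_row_sums_conserve_gt_counts(self):
        rng = np.random.default_rng(2)
        preds, gts = [], []
        for _ in range(10):
            gs = [gt(_rand_box(rng), cls=int(rng.integers(0, 3))) for _ in range(rng.integers(0, 4))]
            ps = [pred(_jitter(rng, g.box) if rng.random() < 0.6 else _rand_box(rng),
                       cls=int(rng.integers(0, 3)), conf=float(rng.uniform(0.3, 1)))
                  for g in gs]
            preds.append(ps)
            gts.append(gs)
        m = confusion_matrix(preds, gts, 3)
        gt_counts = np.zeros(3, int)
        for gs in gts:
            for g in gs:
                gt_counts[g.class_id] += 1
        np.testing.assert_array_equal(m[:3].sum(axis=1), gt_counts)


class TestDatasetEvaluate:
    def test_perfect_predictions_map_one(self):
        preds, gts = [], []
        rng = np.random.default_rng(4)
        for _ in range(5):
            gs = [gt(_rand_box(rng), cls=int(rng.integers(0, 3))) for _ in range(2)]
            preds.append([pred(g.box.copy(), g.class_id, 0.9) for g in gs])
            gts.append(gs)
        res = evaluate(preds, gts, 3)
        assert res.map50 == pytest.approx(1.0)


class TestNMS:
    def test_suppresses_same_class_overlaps_only(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [0, 0, 10, 10]])
        scores = np.array([0.9, 0.8, 0.7])
        classes = np.array([0, 0, 1])
        keep = nms(boxes, scores, classes, 0.5)
        assert 0 in keep and 2 in keep and 1 not in keep

    def test_mask_iou(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[:2] = True
        b[1:3] = True
        assert mask_iou(a, b) == pytest.approx(4 / 12)
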