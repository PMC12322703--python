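"""Matching protocol, P/R conventions, AP against a brute-force oracle."""
import numpy as np
import pytest

from licodet.head import Detection, box_iou_matrix
from licodet.metrics import (ConfusionCounts, PRCurve, _class_pr_curve,
                             ap_from_curve, class_ap_table, f1_confidence_curve,
                             map50, map50_95, match_detections, precision_recall)


def det(box, cls=0, score=0.9):
    return Detection(np.array(box, dtype=float), cls, score)


def gt(box, cls=0):
    return (cls, np.array(box, dtype=float))


# -- matching ---------------------------------------------------------------

def test_single_true_positive():
    c = match_detections([det([0, 0, 10, 10])], [gt([0, 0, 10, 8])], 0.5)
    assert (c[0].tp, c[0].fp, c[0].fn) == (1, 0, 0)


def test_double_detection_counts_one_fp():
    dets = [det([0, 0, 10, 10], score=0.9), det([0, 0, 10, 9], score=0.8)]
    c = match_detections(dets, [gt([0, 0, 10, 10])], 0.5)
    assert (c[0].tp, c[0].fp, c[0].fn) == (1, 1, 0)


def test_wrong_class_never_matches():
    c = match_detections([det([0, 0, 10, 10], cls=1)], [gt([0, 0, 10, 10], cls=0)], 0.5)
    assert (c[1].tp, c[1].fp) == (0, 1)
    assert c[0].fn == 1


def test_precision_recall_conventions():
    assert precision_recall(ConfusionCounts(3, 1, 0)) == (0.75, 1.0)
    assert precision_recall(ConfusionCounts(3, 0, 1)) == (1.0, 0.75)
    assert precision_recall(ConfusionCounts(0, 0, 5)) == (1.0, 0.0)   # nothing predicted
    assert precision_recall(ConfusionCounts(0, 2, 0)) == (0.0, 0.0)   # nothing to find


# -- AP ---------------------------------------------------------------------

def test_perfect_single_detection_ap_is_one():
    dets = [[det([0, 0, 10, 10], score=0.99)]]
    gts = [[gt([0, 0, 10, 10])]]
    assert class_ap_table(dets, gts).ap[0] == pytest.approx(1.0)


def test_fp_before_tp_gives_half():
    dets = [[det([50, 50, 60, 60], score=0.9), det([0, 0, 10, 10], score=0.8)]]
    gts = [[gt([0, 0, 10, 10])]]
    assert class_ap_table(dets, gts).ap[0] == pytest.approx(0.5)


def test_class_without_gt_excluded_from_mean():
    dets = [[det([0, 0, 10, 10], cls=0, score=0.9), det([0, 0, 4, 4], cls=2, score=0.8)]]
    gts = [[gt([0, 0, 10, 10], cls=0)]]
    table = class_ap_table(dets, gts)
    assert set(table.ap) == {0}
    assert table.map == pytest.approx(1.0)


def brute_force_ap(dets_per_image, gts_per_image, cls, iou_thresh):
    """Independent oracle: evaluate (R, P) at every score cut by re-matching
    from scratch, then integrate the envelope over a dense recall grid."""
    scores = sorted({d.score for dets in dets_per_image for d in dets
                     if d.class_id == cls}, reverse=True)
    n_gt = sum(1 for gts in gts_per_image for g in gts if g[0] == cls)
    if n_gt == 0:
        return None
    points = []
    for cut in scores:
        tp = fp = 0
        for dets, gts in zip(dets_per_image, gts_per_image):
            kept = [d for d in dets if d.class_id == cls and d.score >= cut]
            kept.sort(key=lambda d: -d.score)
            gb = [np.asarray(g[1]) for g in gts if g[0] == cls]
            used = [False] * len(gb)
            for d in kept:
                best, best_iou = -1, iou_thresh
                for gi, b in enumerate(gb):
                    if used[gi]:
                        continue
                    iou = box_iou_matrix(d.box, b)[0, 0]
                    if iou >= best_iou:
                        best, best_iou = gi, iou
                if best >= 0:
                    used[best] = True
                    tp += 1
                else:
                    fp += 1
        points.append((tp / n_gt, tp / max(tp + fp, 1)))
    grid = np.linspace(0, 1, 2001)
    env = np.zeros_like(grid)
    for r, p in points:
        env[grid <= r + 1e-12] = np.maximum(env[grid <= r + 1e-12], p)
    return float(np.trapezoid(env, grid))


def _random_instance(rng, n_images=2, max_boxes=8):
    dets_all, gts_all = [], []
    for _ in range(n_images):
        dets, gts = [], []
        for _ in range(int(rng.integers(0, max_boxes + 1))):
            x0, y0 = rng.uniform(0, 80, 2)
            w, h = rng.uniform(4, 30, 2)
            gts.append((int(rng.integers(0, 3)), np.array([x0, y0, x0 + w, y0 + h])))
        for _ in range(int(rng.integers(0, max_boxes + 1))):
            if gts and rng.random() < 0.6:
                cls, base = gts[int(rng.integers(0, len(gts)))]
                jitter = rng.uniform(-6, 6, 4)
                box = base + jitter
            else:
                x0, y0 = rng.uniform(0, 80, 2)
                w, h = rng.uniform(4, 30, 2)
                box = np.array([x0, y0, x0 + w, y0 + h])
                cls = int(rng.integers(0, 3))
            box[2] = max(box[2], box[0] + 1)
            box[3] = max(box[3], box[1] + 1)
            dets.append(Detection(box, cls, float(rng.uniform(0.05, 1.0))))
        dets_all.append(dets)
        gts_all.append(gts)
    return dets_all, gts_all


def test_ap_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    for _case in range(200):
        dets_all, gts_all = _random_instance(rng)
        for cls in range(3):
            expected = brute_force_ap(dets_all, gts_all, cls, 0.5)
            if expected is None:
                continue
            curve, n_gt = _class_pr_curve(dets_all, gts_all, cls, 0.5)
            got = ap_from_curve(curve) if n_gt else None
            assert got == pytest.approx(expected, abs=2e-3)
            checked += 1
    assert checked > 200


def test_adding_top_tp_never_decreases_ap():
    rng = np.random.default_rng(7)
    for _case in range(30):
        dets_all, gts_all = _random_instance(rng, n_images=1)
        gts_all[0].append((0, np.array([200.0, 200.0, 220.0, 220.0])))
        before = class_ap_table(dets_all, gts_all).ap.get(0, 0.0)
        dets_all[0].append(Detection(np.array([200.0, 200.0, 220.0, 220.0]), 0, 1.0))
        after = class_ap_table(dets_all, gts_all).ap.get(0, 0.0)
        assert after >= before - 1e-9


def test_map50_95_averages_thresholds():
    # a det matching its GT at IoU ~0.7 counts below 0.7 and not above
    dets = [[det([0, 0, 10, 7], score=0.9)]]
    gts = [[gt([0, 0, 10, 10])]]
    m = map50_95(dets, gts)
    # IoU = 0.7 exactly: thresholds 0.50..0.70 (inclusive) pass, 5 of 10
    assert m == pytest.approx(np.mean([1.0] * 5 + [0.0] * 5))
    assert map50(dets, gts) == 1.0


# -- F1 curve ---------------------------------------------------------------

def test_f1_perfect_detector():
    dets = [[det([0, 0, 10, 10], score=0.8)]]
    gts = [[gt([0, 0, 10, 10])]]
    best, thresh, _ = f1_confidence_curve(dets, gts)
    assert best == pytest.approx(1.0)
    assert thresh < 0.8


def test_f1_no_detections_is_zero():
    best, _t, (grid, f1s) = f1_confidence_curve([[]], [[gt([0, 0, 10, 10])]])
    assert best == 0.0 and (f1s == 0).all()


def test_f1_hand_computed_two_class_case():
    # class 0: TP at 0.9, FP at 0.6; class 1: one GT missed entirely
    dets = [[det([0, 0, 10, 10], cls=0, score=0.9),
             det([40, 40, 50, 50], cls=0, score=0.6)]]
    gts = [[gt([0, 0, 10, 10], cls=0), gt([70, 70, 80, 80], cls=1)]]
    best, thresh, _ = f1_confidence_curve(dets, gts, grid=[0.5, 0.7])
    # at 0.7: class0 P=1 R=1 F1=1, class1 F1=0 -> macro 0.5
    # at 0.5: class0 P=.5 R=1 F1=2/3, class1 0 -> macro 1/3
    assert best == pytest.approx(0.5)
    assert thresh == pytest.approx(0.7)


# -- Grad-CAM ---------------------------------------------------------------

def test_grad_cam_shape_range_and_zero_case(sample_scene):
    from licodet import nn
    from licodet.metrics import grad_cam
    from licodet.model import Detector, ModelConfig
    model = Detector(ModelConfig.from_preset("resnet34-d"))
    img = sample_scene.image[:64, :64]
    heat = grad_cam(model, img, model.backbone.stages[-1])
    assert heat.shape == img.shape[:2]
    assert heat.min() >= 0.0 and heat.max() <= 1.0
    # zero the final head predictors: output ignores the input -> zero map
    for name, p in model.head.named_parameters():
        if "pred" in name:
            p.data[...] = 0.0
    heat0 = grad_cam(model, img, model.backbone.stages[-1])
    assert np.abs(heat0).max() == 0.0
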