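"""Detection evaluation: matching, precision/recall, AP/mAP, diagnostic
curves, and Grad-CAM.

Protocol: per class and IoU threshold, detections are matched greedily in
descending score order, each to the highest-IoU unmatched ground truth with
IoU >= threshold (one-to-one).  Precision = TP/(TP+FP) with the convention
P := 1 when nothing was predicted; Recall = TP/(TP+FN) with R := 0 when
there are no ground truths.  AP integrates the precision envelope over
recall (all-points interpolation); mAP50-95 averages the ten thresholds
0.50, 0.55, ..., 0.95.  Classes without ground truth are excluded from the
mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .head import Detection, box_iou_matrix

IOU_GRID_50_95 = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    scores: np.ndarray


@dataclass
class ClassAPTable:
    ap: dict[int, float] = field(default_factory=dict)

    @property
    def map(self) -> float:
        return float(np.mean(list(self.ap.values()))) if self.ap else 0.0


def _gt_arrays(gts):
    """gts: list of (class_id, xyxy) tuples -> (classes, boxes)."""
    if not gts:
        return np.zeros(0, dtype=np.int64), np.zeros((0, 4), dtype=np.float32)
    classes = np.array([g[0] for g in gts], dtype=np.int64)
    boxes = np.array([np.asarray(g[1], dtype=np.float32) for g in gts])
    return classes, boxes


def match_detections(dets: list[Detection], gts: list, iou_thresh: float,
                     n_classes: int = 3) -> dict[int, ConfusionCounts]:
    """Greedy one-to-one matching for a single image; dets sorted by score."""
    dets = sorted(dets, key=lambda d: -d.score)
    gcls, gbox = _gt_arrays(gts)
    counts = {c: ConfusionCounts() for c in range(n_classes)}
    matched = np.zeros(len(gcls), dtype=bool)
    for d in dets:
        cand = np.nonzero((gcls == d.class_id) & ~matched)[0]
        if cand.size:
            ious = box_iou_matrix(d.box, gbox[cand])[0]
            best = int(np.argmax(ious))
            if ious[best] >= iou_thresh:
                matched[cand[best]] = True
                counts[d.class_id].tp += 1
                continue
        counts[d.class_id].fp += 1
    for c in range(n_classes):
        counts[c].fn = int(((gcls == c) & ~matched).sum())
    return counts


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    p = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else 1.0
    r = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else 0.0
    return p, r


def _class_pr_curve(dets_per_image, gts_per_image, class_id: int, iou_thresh: float):
    """Pooled PR sweep for one class; returns (PRCurve, n_gt)."""
    rows = []   # (score, is_tp)
    n_gt = 0
    for dets, gts in zip(dets_per_image, gts_per_image):
        gcls, gbox = _gt_arrays(gts)
        sel = gcls == class_id
        n_gt += int(sel.sum())
        gb = gbox[sel]
        matched = np.zeros(len(gb), dtype=bool)
        for d in sorted([d for d in dets if d.class_id == class_id], key=lambda d: -d.score):
            tp = False
            if len(gb):
                ious = box_iou_matrix(d.box, gb)[0]
                ious[matched] = -1.0
                best = int(np.argmax(ious))
                if ious[best] >= iou_thresh:
                    matched[best] = True
                    tp = True
            rows.append((d.score, tp))
    if not rows:
        return PRCurve(np.zeros(0), np.zeros(0), np.zeros(0)), n_gt
    rows.sort(key=lambda r: -r[0])
    scores = np.array([r[0] for r in rows])
    tps = np.cumsum([r[1] for r in rows])
    fps = np.cumsum([not r[1] for r in rows])
    recall = tps / n_gt if n_gt else np.zeros_like(tps, dtype=float)
    precision = tps / np.maximum(tps + fps, 1)
    return PRCurve(recall, precision, scores), n_gt


def ap_from_curve(curve: PRCurve) -> float:
    """Area under the precision envelope (all-points interpolation)."""
    if curve.recall.size == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recall, [curve.recall[-1]]])
    p = np.concatenate([[1.0], curve.precision, [0.0]])
    # envelope: precision at recall x is the max precision at recall >= x
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    dr = np.diff(r)
    return float(np.sum(dr * p[1:]))


def class_ap_table(dets_per_image, gts_per_image, iou_thresh: float = 0.5,
                   n_classes: int = 3) -> ClassAPTable:
    table = ClassAPTable()
    for c in range(n_classes):
        curve, n_gt = _class_pr_curve(dets_per_image, gts_per_image, c, iou_thresh)
        if n_gt == 0:
            continue    # class absent from ground truth: excluded from mean
        table.ap[c] = ap_from_curve(curve)
    return table


def map50(dets_per_image, gts_per_image, n_classes: int = 3) -> float:
    return class_ap_table(dets_per_image, gts_per_image, 0.5, n_classes).map


def map50_95(dets_per_image, gts_per_image, n_classes: int = 3) -> float:
    vals = [class_ap_table(dets_per_image, gts_per_image, t, n_classes).map
            for t in IOU_GRID_50_95]
    return float(np.mean(vals))


def f1_confidence_curve(dets_per_image, gts_per_image, grid=None, n_classes: int = 3,
                        iou_thresh: float = 0.5):
    """Macro-averaged F1 over a confidence grid; returns (best F1, best
    threshold, (grid, f1 values))."""
    if grid is None:
        grid = np.linspace(0.01, 0.99, 99)
    grid = np.asarray(grid, dtype=float)
    f1s = np.zeros_like(grid)
    for gi, thresh in enumerate(grid):
        per_class = []
        for c in range(n_classes):
            total = ConfusionCounts()
            for dets, gts in zip(dets_per_image, gts_per_image):
                kept = [d for d in dets if d.score >= thresh]
                counts = match_detections(kept, gts, iou_thresh, n_classes)[c]
                total = total + counts
            if total.tp + total.fn == 0:
                continue
            p, r = precision_recall(total)
            per_class.append(2 * p * r / (p + r) if (p + r) else 0.0)
        f1s[gi] = float(np.mean(per_class)) if per_class else 0.0
    best = int(np.argmax(f1s))
    return float(f1s[best]), float(grid[best]), (grid, f1s)


def detections_to_gts(labels, image_size) -> list:
    """BoxLabel list -> (class_id, xyxy) ground-truth tuples."""
    ih, iw = (image_size, image_size) if isinstance(image_size, int) else image_size
    return [(lb.class_id, np.array(lb.to_xyxy(iw, ih), dtype=np.float32)) for lb in labels]


# -- plots ------------------------------------------------------------------

def plot_pr_curves(dets_per_image, gts_per_image, path: str, n_classes: int = 3,
                   class_names=("uralensis", "glabra", "inflata")) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in range(n_classes):
        curve, n_gt = _class_pr_curve(dets_per_image, gts_per_image, c, 0.5)
        if n_gt and curve.recall.size:
            ax.plot(curve.recall, curve.precision,
                    label=f"{class_names[c]} AP={ap_from_curve(curve):.3f}")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    if ax.get_legend_handles_labels()[0]:
        ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_f1_confidence(dets_per_image, gts_per_image, path: str, n_classes: int = 3) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    best_f1, best_t, (grid, f1s) = f1_confidence_curve(dets_per_image, gts_per_image,
                                                       n_classes=n_classes)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(grid, f1s)
    ax.axvline(best_t, ls="--", c="gray")
    ax.set_title(f"best F1 {best_f1:.3f} @ conf {best_t:.3f}")
    ax.set_xlabel("Confidence threshold")
    ax.set_ylabel("Macro F1")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# -- Grad-CAM ---------------------------------------------------------------

def grad_cam(model, image: np.ndarray, target_layer) -> np.ndarray:
    """Gradient-weighted class-activation heatmap in [0, 1], input-sized.

    The scalar objective is the sum of all sigmoid class scores, so the map
    highlights everything the detector considers plant-like at the chosen
    layer.  A layer whose gradient vanishes yields an all-zero map.
    """
    from .model import preprocess
    from .nn.tensor import Tensor
    captured = {}

    def hook(_mod, _args, out):
        out.retains_grad = True
        captured["act"] = out

    target_layer._fwd_hooks.append(hook)
    try:
        model.eval()
        x = preprocess(image)
        raw = model(x)
        score = None
        for _box, cls in raw:
            s = cls.sigmoid().sum()
            score = s if score is None else score + s
        model.zero_grad()
        score.backward()
    finally:
        target_layer._fwd_hooks.remove(hook)
    act = captured["act"]
    if act.grad is None:
        h, w = image.shape[:2]
        return np.zeros((h, w), dtype=np.float32)
    weights = act.grad.mean(axis=(2, 3), keepdims=True)
    cam = np.maximum((weights * act.data).sum(axis=1), 0.0)[0]     # (h', w')
    h, w = image.shape[:2]
    from .nn.tensor import resize_bilinear
    cam_t = resize_bilinear(Tensor(cam[None, None]), h, w).data[0, 0]
    lo, hi = cam_t.min(), cam_t.max()
    if hi - lo < 1e-12:
        return np.zeros((h, w), dtype=np.float32)
    return ((cam_t - lo) / (hi - lo)).astype(np.float32)
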