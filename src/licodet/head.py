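"""Decoupled anchor-free detection head, box codec, assignment and loss.

Per pyramid level (strides 8/16/32) the head runs two parallel branches —
classification and box regression — each made of two 3x3 conv+BN+ReLU
layers and a final plain 1x1 convolution.  Boxes are parameterised as
non-negative (softplus) left/top/right/bottom distances from the cell
centre, in stride units; confidence is the per-class sigmoid probability
(no separate objectness branch).

Training targets: a cell is positive when its centre lies inside a
ground-truth box and within 2.5 stride units of the box centre per axis;
ties go to the smallest-area box.  The loss is binary cross-entropy over
all class logits plus (1 - CIoU) on positives, weighted 1 : 5 and reduced
by the positive count.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .flops import conv_spec
from .nn import Tensor, concat, minimum, maximum

STRIDES = (8, 16, 32)
HEAD_WIDTHS = (96, 200, 256)   # per-scale branch widths
CENTER_RADIUS = 2.5
CLS_WEIGHT, BOX_WEIGHT = 1.0, 5.0


@dataclass
class Detection:
    box: np.ndarray        # pixel xyxy, 0-based half-open, clipped
    class_id: int
    score: float


class _Branch(nn.Module):
    def __init__(self, cin: int, width: int, cout: int):
        super().__init__()
        self.conv1 = nn.ConvBNAct(cin, width)
        self.conv2 = nn.ConvBNAct(width, width)
        self.pred = nn.Conv2d(width, cout, 1)
        self.cin, self.width, self.cout = cin, width, cout

    def forward(self, x):
        return self.pred(self.conv2(self.conv1(x)))

    def flop_specs(self, in_shape):
        c, h, w = in_shape
        return [conv_spec("branch.conv1", 3, self.cin, self.width, h, w),
                conv_spec("branch.conv2", 3, self.width, self.width, h, w),
                conv_spec("branch.pred", 1, self.width, self.cout, h, w)], (self.cout, h, w)


class DetectHead(nn.Module):
    def __init__(self, in_channels: tuple[int, int, int] = (128, 256, 512),
                 widths: tuple[int, int, int] = HEAD_WIDTHS, n_classes: int = 3,
                 strides: tuple[int, int, int] = STRIDES):
        super().__init__()
        self.n_classes = n_classes
        self.strides = strides
        for i, (c, w) in enumerate(zip(in_channels, widths)):
            self._modules[f"cls{i}"] = _Branch(c, w, n_classes)
            self._modules[f"box{i}"] = _Branch(c, w, 4)

    def forward(self, features: list[Tensor]) -> list[tuple[Tensor, Tensor]]:
        """``features`` ordered by ascending stride (8, 16, 32).

        Returns per level ``(box_map, cls_map)``: (N,4,H,W) non-negative
        ltrb distances in stride units, and (N,n_classes,H,W) logits.
        """
        out = []
        for i, f in enumerate(features):
            box = self._modules[f"box{i}"](f).softplus()
            cls = self._modules[f"cls{i}"](f)
            out.append((box, cls))
        return out

    def flop_specs(self, feature_shapes):
        specs = []
        for i, shape in enumerate(feature_shapes):
            for kind in ("cls", "box"):
                sub, _ = self._modules[f"{kind}{i}"].flop_specs(shape)
                from dataclasses import replace
                specs.extend(replace(s, name=f"head.{kind}{i}.{s.name}") for s in sub)
        return specs, feature_shapes


# -- codec ------------------------------------------------------------------

def cell_centers(h: int, w: int, stride: int) -> np.ndarray:
    """(H, W, 2) array of cell centre pixel coordinates (x, y)."""
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float32)
    return np.stack([(xs + 0.5) * stride, (ys + 0.5) * stride], axis=-1)


def decode_boxes(box_map: np.ndarray, stride: int) -> np.ndarray:
    """(4,H,W) ltrb map in stride units -> (H,W,4) pixel xyxy."""
    _, h, w = box_map.shape
    ctr = cell_centers(h, w, stride)
    l, t, r, b = box_map * stride
    return np.stack([ctr[..., 0] - l, ctr[..., 1] - t,
                     ctr[..., 0] + r, ctr[..., 1] + b], axis=-1)


def encode_box(box_xyxy, i: int, j: int, stride: int) -> np.ndarray:
    """ltrb (stride units) of a pixel box relative to cell (i, j)."""
    cx, cy = (j + 0.5) * stride, (i + 0.5) * stride
    x0, y0, x1, y1 = box_xyxy
    return np.array([cx - x0, cy - y0, x1 - cx, y1 - cy], dtype=np.float32) / stride


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU between (Na,4) and (Nb,4) xyxy arrays."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        ious = box_iou_matrix(boxes[i], boxes[order[1:]])[0]
        order = order[1:][ious < iou_thresh]
    return keep


def decode(raw: list[tuple[np.ndarray, np.ndarray]], conf_thresh: float = 0.25,
           nms_iou: float = 0.5, image_size: int | tuple[int, int] = 640,
           strides: tuple[int, ...] = STRIDES, max_dets: int = 300) -> list[Detection]:
    """Raw per-scale maps for ONE image -> final detections.

    ``raw`` holds (box_map (4,H,W) ltrb-in-strides, cls_map (C,H,W) logits).
    """
    ih, iw = (image_size, image_size) if isinstance(image_size, int) else image_size
    all_boxes, all_scores, all_cls = [], [], []
    for (box_map, cls_map), stride in zip(raw, strides):
        box_map = getattr(box_map, "data", box_map)
        cls_map = getattr(cls_map, "data", cls_map)
        boxes = decode_boxes(np.asarray(box_map), stride).reshape(-1, 4)
        logits = np.clip(np.asarray(cls_map, dtype=np.float64), -60, 60)
        probs = 1.0 / (1.0 + np.exp(-logits))
        c, h, w = cls_map.shape
        probs = probs.reshape(c, -1).T                       # (cells, classes)
        cls_id = probs.argmax(axis=1)
        score = probs.max(axis=1)
        m = score >= conf_thresh
        if m.any():
            all_boxes.append(boxes[m])
            all_scores.append(score[m])
            all_cls.append(cls_id[m])
    if not all_boxes:
        return []
    boxes = np.concatenate(all_boxes)
    boxes[:, [0, 2]] = np.clip(boxes[:, [0, 2]], 0, iw)
    boxes[:, [1, 3]] = np.clip(boxes[:, [1, 3]], 0, ih)
    scores = np.concatenate(all_scores)
    cls = np.concatenate(all_cls)
    dets: list[Detection] = []
    for cid in np.unique(cls):
        sel = np.nonzero(cls == cid)[0]
        keep = nms(boxes[sel], scores[sel], nms_iou)
        for i in keep:
            b = boxes[sel[i]]
            if b[2] > b[0] and b[3] > b[1]:
                dets.append(Detection(b.copy(), int(cid), float(scores[sel[i]])))
    dets.sort(key=lambda d: -d.score)
    return dets[:max_dets]


# -- assignment and loss ----------------------------------------------------

def assign_targets(gt_boxes: np.ndarray, gt_classes: np.ndarray, grid_h: int,
                   grid_w: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell assignment for one level.

    Returns ``(assigned, cls_target)``: ``assigned`` is (H, W) int index into
    the ground-truth list (-1 for negative), positives being cells whose
    centre lies inside a box and within 2.5 strides of its centre per axis,
    ties resolved to the smallest-area box.
    """
    assigned = np.full((grid_h, grid_w), -1, dtype=np.int64)
    if gt_boxes.size == 0:
        return assigned, np.zeros((grid_h, grid_w), dtype=np.int64)
    ctr = cell_centers(grid_h, grid_w, stride)
    cxs, cys = ctr[..., 0], ctr[..., 1]
    best_area = np.full((grid_h, grid_w), np.inf)
    for gi, (x0, y0, x1, y1) in enumerate(gt_boxes):
        bx, by = (x0 + x1) / 2, (y0 + y1) / 2
        inside = (cxs > x0) & (cxs < x1) & (cys > y0) & (cys < y1)
        near = (np.abs(cxs - bx) <= CENTER_RADIUS * stride) & \
               (np.abs(cys - by) <= CENTER_RADIUS * stride)
        area = (x1 - x0) * (y1 - y0)
        m = inside & near & (area < best_area)
        assigned[m] = gi
        best_area[m] = area
    cls_target = np.where(assigned >= 0, gt_classes[np.clip(assigned, 0, None)], 0)
    return assigned, cls_target


def _ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between (P,4) predicted and (P,4) target xyxy boxes."""
    t = Tensor(target)
    eps = 1e-7
    ix0 = maximum(pred[:, 0], t[:, 0])
    iy0 = maximum(pred[:, 1], t[:, 1])
    ix1 = minimum(pred[:, 2], t[:, 2])
    iy1 = minimum(pred[:, 3], t[:, 3])
    iw = (ix1 - ix0).clamp_min(0.0)
    ih = (iy1 - iy0).clamp_min(0.0)
    inter = iw * ih
    area_p = (pred[:, 2] - pred[:, 0]).clamp_min(0.0) * (pred[:, 3] - pred[:, 1]).clamp_min(0.0)
    area_t = (t[:, 2] - t[:, 0]) * (t[:, 3] - t[:, 1])
    union = area_p + area_t - inter + eps
    iou = inter / union
    # centre distance over enclosing diagonal
    cxp = (pred[:, 0] + pred[:, 2]) * 0.5
    cyp = (pred[:, 1] + pred[:, 3]) * 0.5
    cxt = (t[:, 0] + t[:, 2]) * 0.5
    cyt = (t[:, 1] + t[:, 3]) * 0.5
    ex0 = minimum(pred[:, 0], t[:, 0])
    ey0 = minimum(pred[:, 1], t[:, 1])
    ex1 = maximum(pred[:, 2], t[:, 2])
    ey1 = maximum(pred[:, 3], t[:, 3])
    diag = (ex1 - ex0).pow(2.0) + (ey1 - ey0).pow(2.0) + eps
    dist = (cxp - cxt).pow(2.0) + (cyp - cyt).pow(2.0)
    # aspect-ratio consistency
    wp = (pred[:, 2] - pred[:, 0]).clamp_min(eps)
    hp = (pred[:, 3] - pred[:, 1]).clamp_min(eps)
    wt = t[:, 2] - t[:, 0]
    ht = t[:, 3] - t[:, 1]
    v = (4.0 / np.pi ** 2) * ((wt / ht).arctan() - (wp / hp).arctan()).pow(2.0)
    alpha = (v.data / np.maximum(1.0 - iou.data + v.data, eps))   # no grad through alpha
    return iou - dist / diag - Tensor(alpha) * v


def assign_and_loss(raw: list[tuple[Tensor, Tensor]], targets: list[list],
                    image_size: int = 640, strides: tuple[int, ...] = STRIDES
                    ) -> tuple[Tensor, dict[str, float]]:
    """Total loss for a batch.

    ``targets``: per image, a list of BoxLabels (normalised) or (class,
    x0, y0, x1, y1) pixel tuples.  Returns (loss Tensor, components dict).
    """
    n = raw[0][0].shape[0]
    n_classes = raw[0][1].shape[1]
    cls_losses, box_losses = [], []
    total_pos = 0
    bce_all = []
    for img in range(n):
        gt = targets[img]
        if gt and hasattr(gt[0], "to_xyxy"):
            boxes = np.array([lb.to_xyxy(image_size, image_size) for lb in gt], dtype=np.float32)
            classes = np.array([lb.class_id for lb in gt])
        elif gt:
            arr = np.asarray(gt, dtype=np.float32)
            boxes, classes = arr[:, 1:5], arr[:, 0].astype(np.int64)
        else:
            boxes = np.zeros((0, 4), dtype=np.float32)
            classes = np.zeros(0, dtype=np.int64)
        for (box_map, cls_map), stride in zip(raw, strides):
            h, w = box_map.shape[2], box_map.shape[3]
            assigned, cls_t = assign_targets(boxes, classes, h, w, stride)
            onehot = np.zeros((n_classes, h, w), dtype=np.float32)
            pos = assigned >= 0
            if pos.any():
                ii, jj = np.nonzero(pos)
                onehot[cls_t[pos], ii, jj] = 1.0
            logits = cls_map[img]
            bce = logits.softplus() - logits * Tensor(onehot)
            bce_all.append(bce.sum())
            npos = int(pos.sum())
            total_pos += npos
            if npos:
                ii, jj = np.nonzero(pos)
                ctr = cell_centers(h, w, stride)
                pred_ltrb = box_map[img][:, ii, jj].transpose(1, 0) * float(stride)
                cx = ctr[ii, jj, 0][:, None]
                cy = ctr[ii, jj, 1][:, None]
                base = np.concatenate([cx, cy, cx, cy], axis=1)
                sign = np.array([-1.0, -1.0, 1.0, 1.0], dtype=np.float32)
                pred_boxes = Tensor(base) + pred_ltrb * Tensor(sign)
                ciou = _ciou(pred_boxes, boxes[assigned[pos]])
                box_losses.append((1.0 - ciou).sum())
    n_cells = sum(bm.shape[2] * bm.shape[3] for bm, _ in raw) * n * n_classes
    denom = float(max(total_pos, 1))
    cls_loss = sum(bce_all[1:], bce_all[0])
    cls_loss = cls_loss * (1.0 / denom) if total_pos else cls_loss * (1.0 / n_cells)
    if box_losses:
        box_loss = sum(box_losses[1:], box_losses[0]) * (1.0 / denom)
    else:
        box_loss = Tensor(0.0)
    total = cls_loss * CLS_WEIGHT + box_loss * BOX_WEIGHT
    return total, {"cls": float(cls_loss.data), "box": float(box_loss.data),
                   "num_pos": total_pos}


# -- export -----------------------------------------------------------------

def write_predictions_yolo(dets: list[Detection], path: str) -> None:
    with open(path, "w") as f:
        for d in dets:
            x0, y0, x1, y1 = d.box
            f.write(f"{d.class_id} {d.score:.6f} {x0:.2f} {y0:.2f} {x1:.2f} {y1:.2f}\n")


def write_predictions_coco(dets_per_image: dict[str, list[Detection]], path: str) -> None:
    rows = []
    for image_id, dets in dets_per_image.items():
        for d in dets:
            x0, y0, x1, y1 = [float(v) for v in d.box]
            rows.append({"image_id": image_id, "category_id": d.class_id,
                         "bbox": [x0, y0, x1 - x0, y1 - y0], "score": d.score})
    with open(path, "w") as f:
        json.dump(rows, f)
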