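"""Dataset pipeline: YOLO label I/O, frame tiling, 8:1:1 split, augmentation.

Coordinate conventions: on disk, boxes are YOLO-normalised centre format
``class cx cy w h``; in memory, pixel boxes are xyxy, 0-based, half-open.
Large UAV frames (e.g. 8192x5460) are tiled to 640x640 on a non-overlapping
grid; a clipped box survives a tile iff it keeps at least ``min_area_frac``
of its original area.  The split is drawn before augmentation so no
augmented copy of a validation/test image can leak into training.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

VALID_CLASSES = (0, 1, 2)
CLASS_NAMES = ("uralensis", "glabra", "inflata")
AUG_OPS = ("mirror", "rotate", "brightness", "translate")
DEFAULT_MIN_AREA_FRAC = 0.3


@dataclass(frozen=True)
class BoxLabel:
    """One normalised ground-truth box (class, centre, size; all in [0,1])."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self, tol: float = 1e-6) -> "BoxLabel":
        if self.class_id not in VALID_CLASSES:
            raise ValueError(f"class_id {self.class_id} outside {VALID_CLASSES}")
        if not (0 - tol <= self.cx <= 1 + tol and 0 - tol <= self.cy <= 1 + tol):
            raise ValueError(f"box centre ({self.cx}, {self.cy}) outside [0,1]")
        if not (0 < self.w <= 1 + tol and 0 < self.h <= 1 + tol):
            raise ValueError(f"box size ({self.w}, {self.h}) outside (0,1]")
        return self

    def to_xyxy(self, width: int, height: int) -> tuple[float, float, float, float]:
        return ((self.cx - self.w / 2) * width, (self.cy - self.h / 2) * height,
                (self.cx + self.w / 2) * width, (self.cy + self.h / 2) * height)


def xyxy_to_label(class_id: int, x0: float, y0: float, x1: float, y1: float,
                  width: int, height: int) -> BoxLabel:
    return BoxLabel(class_id, (x0 + x1) / 2 / width, (y0 + y1) / 2 / height,
                    (x1 - x0) / width, (y1 - y0) / height)


@dataclass
class ImageRecord:
    image_path: str
    labels: list[BoxLabel]
    split_tag: str = "unassigned"
    image: np.ndarray | None = None       # optional materialised pixels

    def load(self) -> np.ndarray:
        if self.image is None:
            from PIL import Image
            self.image = np.asarray(Image.open(self.image_path).convert("RGB"))
        return self.image


# -- YOLO label files -------------------------------------------------------

def read_yolo_labels(path: str) -> list[BoxLabel]:
    labels = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: unparseable field ({e})") from e
            labels.append(BoxLabel(cid, *vals).validate())
    return labels


def write_yolo_labels(labels: list[BoxLabel], path: str) -> None:
    with open(path, "w") as f:
        for lb in labels:
            f.write(f"{lb.class_id} {lb.cx:.6f} {lb.cy:.6f} {lb.w:.6f} {lb.h:.6f}\n")


# -- tiling -----------------------------------------------------------------

def tile_image(image: np.ndarray, labels: list[BoxLabel], tile_size: int = 640,
               min_area_frac: float = DEFAULT_MIN_AREA_FRAC
               ) -> list[tuple[np.ndarray, list[BoxLabel]]]:
    """Cut a frame into a non-overlapping top-left-anchored grid of tiles.

    Remainder tiles on the right/bottom are zero-padded to ``tile_size``.
    Each source box is clipped to every tile it intersects and kept when the
    clipped area is at least ``min_area_frac`` of the original.
    """
    H, W = image.shape[:2]
    nx = -(-W // tile_size)
    ny = -(-H // tile_size)
    boxes = [lb.to_xyxy(W, H) for lb in labels]
    out = []
    for ty in range(ny):
        for tx in range(nx):
            ox, oy = tx * tile_size, ty * tile_size
            tile = image[oy:oy + tile_size, ox:ox + tile_size]
            if tile.shape[0] != tile_size or tile.shape[1] != tile_size:
                pad = np.zeros((tile_size, tile_size) + image.shape[2:], dtype=image.dtype)
                pad[:tile.shape[0], :tile.shape[1]] = tile
                tile = pad
            kept = []
            for lb, (x0, y0, x1, y1) in zip(labels, boxes):
                cx0, cy0 = max(x0, ox), max(y0, oy)
                cx1, cy1 = min(x1, ox + tile_size), min(y1, oy + tile_size)
                if cx1 <= cx0 or cy1 <= cy0:
                    continue
                area = (x1 - x0) * (y1 - y0)
                if area <= 0 or (cx1 - cx0) * (cy1 - cy0) / area < min_area_frac:
                    continue
                kept.append(xyxy_to_label(lb.class_id, cx0 - ox, cy0 - oy,
                                          cx1 - ox, cy1 - oy, tile_size, tile_size))
            out.append((tile, kept))
    return out


# -- splitting --------------------------------------------------------------

@dataclass
class SplitManifest:
    ratios: tuple[float, float, float]
    seed: int
    assignment: dict[int, str]            # record index -> split tag
    class_counts: dict[str, dict[int, int]] = field(default_factory=dict)

    def indices(self, tag: str) -> list[int]:
        return [i for i, t in sorted(self.assignment.items()) if t == tag]


def _dominant_class(record: ImageRecord) -> int:
    if not record.labels:
        return -1
    counts = np.bincount([lb.class_id for lb in record.labels], minlength=3)
    return int(counts.argmax())


def split_dataset(records: list[ImageRecord], ratios=(0.8, 0.1, 0.1), seed: int = 0,
                  stratify_by_class: bool = False) -> SplitManifest:
    """Assign every record to train/val/test.

    Counts follow ``round(n * ratio)`` for val and test with the remainder in
    train; deterministic under ``seed``.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[int, str] = {}

    def allocate(indices: list[int]):
        idx = np.array(indices)
        rng.shuffle(idx)
        n = len(idx)
        n_val = int(round(n * ratios[1]))
        n_test = int(round(n * ratios[2]))
        n_val = min(n_val, n)
        n_test = min(n_test, n - n_val)
        for i in idx[:n_val]:
            assignment[int(i)] = "val"
        for i in idx[n_val:n_val + n_test]:
            assignment[int(i)] = "test"
        for i in idx[n_val + n_test:]:
            assignment[int(i)] = "train"

    if stratify_by_class:
        buckets: dict[int, list[int]] = {}
        for i, r in enumerate(records):
            buckets.setdefault(_dominant_class(r), []).append(i)
        for key in sorted(buckets):
            allocate(buckets[key])
    else:
        allocate(list(range(len(records))))

    for i, rec in enumerate(records):
        rec.split_tag = assignment[i]
    counts: dict[str, dict[int, int]] = {t: {c: 0 for c in VALID_CLASSES} for t in ("train", "val", "test")}
    for i, rec in enumerate(records):
        for lb in rec.labels:
            counts[assignment[i]][lb.class_id] += 1
    return SplitManifest(tuple(ratios), seed, assignment, counts)


# -- augmentation -----------------------------------------------------------

def _transform_box_k90(lb: BoxLabel, k: int) -> BoxLabel:
    cx, cy, w, h = lb.cx, lb.cy, lb.w, lb.h
    for _ in range(k % 4):
        cx, cy, w, h = 1.0 - cy, cx, h, w      # 90 degrees clockwise
    return BoxLabel(lb.class_id, cx, cy, w, h)


def _rotate_arbitrary(img: np.ndarray, labels: list[BoxLabel], angle_deg: float,
                      min_area_frac: float) -> tuple[np.ndarray, list[BoxLabel]]:
    """Rotate about the image centre; boxes become the clipped axis-aligned
    enclosure of their rotated corners (necessarily loose)."""
    from PIL import Image
    H, W = img.shape[:2]
    new_img = np.asarray(Image.fromarray(img).rotate(-angle_deg, resample=Image.BILINEAR))
    th = np.deg2rad(angle_deg)
    ct, st = np.cos(th), np.sin(th)
    cx0, cy0 = W / 2, H / 2
    out = []
    for lb in labels:
        x0, y0, x1, y1 = lb.to_xyxy(W, H)
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]]) - (cx0, cy0)
        rot = corners @ np.array([[ct, st], [-st, ct]]).T + (cx0, cy0)
        nx0, ny0 = rot.min(axis=0)
        nx1, ny1 = rot.max(axis=0)
        kx0, ky0 = max(nx0, 0.0), max(ny0, 0.0)
        kx1, ky1 = min(nx1, float(W)), min(ny1, float(H))
        if kx1 <= kx0 or ky1 <= ky0:
            continue
        if (kx1 - kx0) * (ky1 - ky0) / ((x1 - x0) * (y1 - y0)) < min_area_frac:
            continue
        out.append(xyxy_to_label(lb.class_id, kx0, ky0, kx1, ky1, W, H))
    return new_img, out


def augment_record(record: ImageRecord, op: str, rng: np.random.Generator,
                   min_area_frac: float = DEFAULT_MIN_AREA_FRAC,
                   arbitrary_rotation: bool = False) -> ImageRecord:
    """Return a transformed copy of ``record`` with boxes kept consistent.

    Rotation defaults to k*90 degrees (axis-aligned boxes stay tight);
    ``arbitrary_rotation=True`` draws an angle in +/-30 degrees and
    recomputes each box as the enclosure of its rotated corners.
    """
    if op not in AUG_OPS:
        raise ValueError(f"unknown augmentation op {op!r}; expected one of {AUG_OPS}")
    img = record.load()
    labels = record.labels

    if op == "mirror":
        new_img = img[:, ::-1].copy()
        new_labels = [BoxLabel(lb.class_id, 1.0 - lb.cx, lb.cy, lb.w, lb.h) for lb in labels]
    elif op == "rotate" and arbitrary_rotation:
        angle = float(rng.uniform(-30.0, 30.0))
        new_img, new_labels = _rotate_arbitrary(img, labels, angle, min_area_frac)
    elif op == "rotate":
        k = int(rng.integers(1, 4))
        new_img = np.rot90(img, k=-k).copy()   # np.rot90 is CCW; -k is CW
        new_labels = [_transform_box_k90(lb, k) for lb in labels]
    elif op == "brightness":
        factor = float(rng.uniform(0.6, 1.4))
        new_img = np.clip(img.astype(np.float32) * factor, 0, 255).astype(img.dtype)
        new_labels = list(labels)
    else:  # translate
        H, W = img.shape[:2]
        dx = int(round(rng.uniform(-0.2, 0.2) * W))
        dy = int(round(rng.uniform(-0.2, 0.2) * H))
        new_img = np.zeros_like(img)
        sx0, sx1 = max(0, -dx), min(W, W - dx)
        sy0, sy1 = max(0, -dy), min(H, H - dy)
        new_img[sy0 + dy:sy1 + dy, sx0 + dx:sx1 + dx] = img[sy0:sy1, sx0:sx1]
        new_labels = []
        for lb in labels:
            x0, y0, x1, y1 = lb.to_xyxy(W, H)
            nx0, ny0, nx1, ny1 = x0 + dx, y0 + dy, x1 + dx, y1 + dy
            cx0, cy0 = max(nx0, 0.0), max(ny0, 0.0)
            cx1, cy1 = min(nx1, float(W)), min(ny1, float(H))
            if cx1 <= cx0 or cy1 <= cy0:
                continue
            if (cx1 - cx0) * (cy1 - cy0) / ((x1 - x0) * (y1 - y0)) < min_area_frac:
                continue
            new_labels.append(xyxy_to_label(lb.class_id, cx0, cy0, cx1, cy1, W, H))

    return ImageRecord(image_path=record.image_path + f"#{op}",
                       labels=new_labels, split_tag=record.split_tag, image=new_img)


def expand_dataset(records: list[ImageRecord], ops: tuple[str, ...] = AUG_OPS,
                   seed: int = 0, splits: tuple[str, ...] = ("train", "val", "test")
                   ) -> list[ImageRecord]:
    """Each original yields itself plus one copy per augmentation op.

    Augmentation runs within each split independently (tags are preserved),
    so the partition drawn by :func:`split_dataset` is never crossed.  By
    default all three splits are expanded, mirroring the augmented counts of
    the source protocol; pass ``splits=("train",)`` to restrict augmentation
    to training data (recommended practice).
    """
    out = []
    rng = np.random.default_rng(seed)
    for rec in records:
        out.append(rec)
        if rec.split_tag not in splits:
            continue
        for op in ops:
            out.append(augment_record(rec, op, rng))
    return out


def write_dataset(records: list[ImageRecord], out_dir: str) -> str:
    """Materialise records as images/{split}/, labels/{split}/ plus a log."""
    from PIL import Image
    for tag in ("train", "val", "test"):
        os.makedirs(os.path.join(out_dir, "images", tag), exist_ok=True)
        os.makedirs(os.path.join(out_dir, "labels", tag), exist_ok=True)
    lines = []
    for i, rec in enumerate(records):
        tag = rec.split_tag if rec.split_tag != "unassigned" else "train"
        ip = os.path.join(out_dir, "images", tag, f"{i:06d}.png")
        lp = os.path.join(out_dir, "labels", tag, f"{i:06d}.txt")
        Image.fromarray(rec.load()).save(ip)
        write_yolo_labels(rec.labels, lp)
        lines.append(f"{ip}\t{lp}\t{tag}")
    log = os.path.join(out_dir, "dataset_log.txt")
    with open(log, "w") as f:
        f.write("\n".join(lines) + "\n")
    return log
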