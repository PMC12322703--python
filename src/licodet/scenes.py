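"""Synthetic UAV-like vegetation scenes with YOLO box labels.

Real wild-licorice imagery shows three visually similar plant species on
cluttered arid backgrounds, with large within-class scale variation, weedy
distractors whose colour overlaps the species bands, and partial mutual
occlusion.  The generator emulates exactly those statistics so that the whole
detection stack (tiling, augmentation, training, evaluation) is exercisable
without any field data:

* a plant is a rosette of overlapping elliptical leaves; the species is
  encoded as a (hue band, leaf count, leaf aspect ratio) triplet, so classes
  are separable but only by fine-grained appearance;
* weeds are irregular blobs whose hue is drawn across all species bands
  (hard negatives);
* the background is a low-frequency brownish field plus speckle.

Every scene is a deterministic function of ``(spec.seed, index)``.
"""
from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .data import BoxLabel, write_yolo_labels

# species appearance: (hue centre, hue half-width, leaf count, leaf aspect)
CLASS_APPEARANCE = (
    (0.26, 0.025, 6, 2.4),   # uralensis
    (0.33, 0.025, 9, 3.2),   # glabra
    (0.205, 0.025, 13, 4.5),  # inflata
)
WEED_HUE_RANGE = (0.17, 0.38)  # spans all three class bands
PLANT_HUE_RANGE = (0.15, 0.40)  # what counts as "plant-coloured"

MIN_VISIBLE_FRAC = 0.25


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic scene distribution."""

    image_size: int = 640
    n_classes: int = 3
    plants_per_image: tuple[int, int] = (3, 8)
    plant_radius: tuple[int, int] = (12, 220)
    weed_density: int = 25
    occlusion_prob: float = 0.3
    brightness_jitter: tuple[float, float] = (0.85, 1.15)
    seed: int = 0

    def validate(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.n_classes != 3:
            raise ValueError("the scene model has exactly 3 plant classes")
        for name in ("plants_per_image", "plant_radius", "brightness_jitter"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} range must be non-empty and non-negative")
        if self.plant_radius[0] <= 0:
            raise ValueError("plant_radius must be positive")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must lie in [0, 1]")
        if self.weed_density < 0:
            raise ValueError("weed_density must be non-negative")


@dataclass
class SceneSample:
    image: np.ndarray           # H x W x 3 uint8
    labels: list[BoxLabel]


def _low_freq_field(rng: np.random.Generator, size: int, cells: int = 16) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, (cells + 1, cells + 1))
    t = np.linspace(0, cells, size)
    i0 = np.minimum(t.astype(int), cells - 1)
    f = t - i0
    rows = coarse[i0, :] * (1 - f)[:, None] + coarse[i0 + 1, :] * f[:, None]
    field = rows[:, i0] * (1 - f)[None, :] + rows[:, i0 + 1] * f[None, :]
    return field


def _render_rosette(hsv, zbuf, zid, cx, cy, radius, leaves, aspect, hue, rng):
    """Draw one rosette; paints hsv in-place and stamps ``zid`` into zbuf."""
    size = zbuf.shape[0]
    r = int(np.ceil(radius))
    x0, x1 = max(0, int(cx) - r), min(size, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(size, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    mask = np.zeros(dx.shape, dtype=bool)
    base_angle = rng.uniform(0, 2 * np.pi)
    leaf_len = radius
    for k in range(leaves):
        ang = base_angle + 2 * np.pi * k / leaves + rng.normal(0, 0.08)
        ca, sa = np.cos(ang), np.sin(ang)
        # leaf centred halfway along its axis
        lx, ly = 0.5 * leaf_len * ca, 0.5 * leaf_len * sa
        u = (dx - lx) * ca + (dy - ly) * sa
        v = -(dx - lx) * sa + (dy - ly) * ca
        a = 0.5 * leaf_len * rng.uniform(0.85, 1.0)
        b = max(1.2, a / aspect)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        return
    ys, xs = np.nonzero(mask)
    rr = np.sqrt(dx[ys, xs] ** 2 + dy[ys, xs] ** 2) / max(radius, 1.0)
    hsv[0][y0:y1, x0:x1][mask] = hue + rng.normal(0, 0.006, ys.size)
    hsv[1][y0:y1, x0:x1][mask] = np.clip(0.55 + 0.25 * (1 - rr) + rng.normal(0, 0.04, ys.size), 0.3, 1.0)
    hsv[2][y0:y1, x0:x1][mask] = np.clip(0.35 + 0.35 * rr + rng.normal(0, 0.05, ys.size), 0.12, 0.95)
    zbuf[y0:y1, x0:x1][mask] = zid


def _render_blob(hsv, zbuf, zid, cx, cy, radius, hue, rng):
    size = zbuf.shape[0]
    r = int(np.ceil(radius * 1.6))
    x0, x1 = max(0, int(cx) - r), min(size, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(size, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ang = np.arctan2(dy, dx)
    wobble = 1.0 + 0.35 * np.sin(ang * rng.integers(3, 7) + rng.uniform(0, 2 * np.pi))
    mask = dx ** 2 + dy ** 2 <= (radius * wobble) ** 2
    if not mask.any():
        return
    n = int(mask.sum())
    hsv[0][y0:y1, x0:x1][mask] = hue + rng.normal(0, 0.01, n)
    hsv[1][y0:y1, x0:x1][mask] = np.clip(0.45 + rng.normal(0, 0.06, n), 0.25, 0.9)
    hsv[2][y0:y1, x0:x1][mask] = np.clip(0.35 + rng.normal(0, 0.08, n), 0.1, 0.8)
    zbuf[y0:y1, x0:x1][mask] = zid


def generate_scene(spec: SceneSpec, index: int) -> SceneSample:
    """Render scene ``index`` of the dataset defined by ``spec``."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, int(index)])
    size = spec.image_size

    h = np.clip(0.07 + 0.02 * _low_freq_field(rng, size), 0.02, 0.13)
    s = np.clip(0.35 + 0.10 * _low_freq_field(rng, size), 0.05, 0.6)
    v = np.clip(0.45 + 0.12 * _low_freq_field(rng, size) + rng.normal(0, 0.035, (size, size)), 0.05, 0.9)
    hsv = [h, s, v]
    zbuf = np.zeros((size, size), dtype=np.int32)   # 0 = background

    n_plants = int(rng.integers(spec.plants_per_image[0], spec.plants_per_image[1] + 1))
    rmin, rmax = spec.plant_radius
    rmax_eff = min(rmax, size // 2)
    plants = []
    for i in range(n_plants):
        radius = float(np.exp(rng.uniform(np.log(rmin), np.log(max(rmin, rmax_eff)))))
        margin = 0.4 * radius
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
        cls = int(rng.integers(0, spec.n_classes))
        hue0, hw, leaves, aspect = CLASS_APPEARANCE[cls]
        hue = rng.uniform(hue0 - hw, hue0 + hw)
        occluded = rng.random() < spec.occlusion_prob
        plants.append((i + 1, cls, cx, cy, radius, leaves, aspect, hue, occluded))

    for (zid, cls, cx, cy, radius, leaves, aspect, hue, _) in plants:
        _render_rosette(hsv, zbuf, zid, cx, cy, radius, leaves, aspect, hue, rng)
    full_masks = {zid: (zbuf == zid).sum() for (zid, *_rest) in plants}

    # weed distractors; occluders are drawn across a plant's edge
    weed_id = n_plants + 1
    for (zid, cls, cx, cy, radius, leaves, aspect, hue, occluded) in plants:
        if occluded:
            ang = rng.uniform(0, 2 * np.pi)
            wx = cx + 0.6 * radius * np.cos(ang)
            wy = cy + 0.6 * radius * np.sin(ang)
            whue = rng.uniform(*WEED_HUE_RANGE)
            _render_blob(hsv, zbuf, weed_id, wx, wy, 0.55 * radius, whue, rng)
            weed_id += 1
    for _ in range(int(spec.weed_density)):
        wx, wy = rng.uniform(0, size, 2)
        wr = rng.uniform(3, 18)
        whue = rng.uniform(*WEED_HUE_RANGE)
        _render_blob(hsv, zbuf, weed_id, wx, wy, wr, whue, rng)
        weed_id += 1

    labels: list[BoxLabel] = []
    for (zid, cls, *_rest) in plants:
        visible = zbuf == zid
        n_vis = int(visible.sum())
        if full_masks[zid] == 0 or n_vis / full_masks[zid] < MIN_VISIBLE_FRAC:
            continue
        ys, xs = np.nonzero(visible)
        x0, x1 = xs.min(), xs.max() + 1
        y0, y1 = ys.min(), ys.max() + 1
        if x1 - x0 < 2 or y1 - y0 < 2:
            continue
        labels.append(BoxLabel(cls, (x0 + x1) / 2 / size, (y0 + y1) / 2 / size,
                               (x1 - x0) / size, (y1 - y0) / size))

    bright = rng.uniform(*spec.brightness_jitter)
    hsv_arr = np.stack([np.mod(hsv[0], 1.0), np.clip(hsv[1], 0, 1),
                        np.clip(hsv[2] * bright, 0, 1)], axis=-1)
    rgb = hsv_to_rgb(hsv_arr)
    image = np.clip(rgb * 255.0 + 0.5, 0, 255).astype(np.uint8)
    return SceneSample(image=image, labels=labels)


def box_contains_plant(image: np.ndarray, label: BoxLabel, min_pixels: int = 1) -> bool:
    """Label/image consistency probe: does the box contain plant-coloured pixels?

    Plant-coloured means hue inside the green vegetation band with
    non-trivial saturation — true for every rendered species (and for weeds,
    which intentionally share the band).
    """
    size_h, size_w = image.shape[:2]
    x0 = int(np.floor((label.cx - label.w / 2) * size_w))
    x1 = int(np.ceil((label.cx + label.w / 2) * size_w))
    y0 = int(np.floor((label.cy - label.h / 2) * size_h))
    y1 = int(np.ceil((label.cy + label.h / 2) * size_h))
    crop = image[max(0, y0):min(size_h, y1), max(0, x0):min(size_w, x1)].astype(np.float32) / 255.0
    if crop.size == 0:
        return False
    mx = crop.max(axis=-1)
    mn = crop.min(axis=-1)
    delta = mx - mn
    green_dominant = (crop[..., 1] >= crop[..., 0]) & (crop[..., 1] >= crop[..., 2])
    saturated = delta > 0.08
    return int((green_dominant & saturated).sum()) >= min_pixels


def generate_dataset(spec: SceneSpec, n_images: int, out_dir: str) -> list[tuple[str, str]]:
    """Write ``n_images`` scenes as PNG + YOLO label pairs; return the manifest.

    Re-running with the same spec reproduces identical files.  The manifest
    (``manifest.txt``) lists one ``<image>\\t<labels>`` pair per line.
    """
    spec.validate()
    img_dir = os.path.join(out_dir, "images")
    lab_dir = os.path.join(out_dir, "labels")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(lab_dir, exist_ok=True)
    manifest: list[tuple[str, str]] = []
    for i in range(n_images):
        sample = generate_scene(spec, i)
        ip = os.path.join(img_dir, f"scene_{i:05d}.png")
        lp = os.path.join(lab_dir, f"scene_{i:05d}.txt")
        try:
            Image.fromarray(sample.image).save(ip)
            write_yolo_labels(sample.labels, lp)
        except OSError as e:
            raise OSError(f"failed writing scene {i} under {out_dir}: {e}") from e
        manifest.append((ip, lp))
    mpath = os.path.join(out_dir, "manifest.txt")
    with open(mpath, "w") as f:
        for ip, lp in manifest:
            f.write(f"{ip}\t{lp}\n")
    with open(os.path.join(out_dir, "spec.txt"), "w") as f:
        for field in dataclasses.fields(spec):
            f.write(f"{field.name}: {getattr(spec, field.name)}\n")
    return manifest
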