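"""Label I/O, tiling geometry, split arithmetic, augmentation consistency."""
import numpy as np
import pytest

from licodet.data import (AUG_OPS, BoxLabel, ImageRecord, augment_record,
                          expand_dataset, read_yolo_labels, split_dataset,
                          tile_image, write_yolo_labels)
from licodet.scenes import box_contains_plant, generate_scene


# -- YOLO files -------------------------------------------------------------

def test_yolo_roundtrip(tmp_path):
    labels = [BoxLabel(0, 0.5, 0.5, 0.2, 0.1), BoxLabel(2, 0.25, 0.75, 0.5, 0.5),
              BoxLabel(1, 0.1, 0.1, 0.05, 0.05)]
    p = tmp_path / "l.txt"
    write_yolo_labels(labels, str(p))
    assert read_yolo_labels(str(p)) == labels


def test_yolo_single_line_and_empty(tmp_path):
    p = tmp_path / "one.txt"
    p.write_text("0 0.5 0.5 0.2 0.1\n")
    assert read_yolo_labels(str(p)) == [BoxLabel(0, 0.5, 0.5, 0.2, 0.1)]
    (tmp_path / "empty.txt").write_text("")
    assert read_yolo_labels(str(tmp_path / "empty.txt")) == []


@pytest.mark.parametrize("content,msg", [
    ("0 0.5 0.5 0.2\n", "expected 5 fields"),
    ("0 0.5 x 0.2 0.1\n", "unparseable"),
    ("7 0.5 0.5 0.2 0.1\n", "class_id"),
])
def test_yolo_malformed_lines_rejected(tmp_path, content, msg):
    p = tmp_path / "bad.txt"
    p.write_text(content)
    with pytest.raises(ValueError, match=msg):
        read_yolo_labels(str(p))


# -- tiling -----------------------------------------------------------------

def test_tile_count_matches_uav_frame_arithmetic():
    frame = np.zeros((5460, 8192), dtype=np.uint8)     # full-frame sensor size
    tiles = tile_image(frame, [], tile_size=640)
    assert len(tiles) == 13 * 9
    assert all(t.shape == (640, 640) for t, _ in tiles)


def test_box_inside_single_tile_unchanged():
    img = np.zeros((1280, 1280, 3), dtype=np.uint8)
    lb = BoxLabel(1, 0.25, 0.25, 0.1, 0.1)             # fully inside tile (0, 0)
    tiles = tile_image(img, [lb], tile_size=640)
    with_boxes = [(i, t) for i, (im, t) in enumerate(tiles) if t]
    assert len(with_boxes) == 1 and with_boxes[0][0] == 0
    out = with_boxes[0][1][0]
    assert out.class_id == 1
    np.testing.assert_allclose([out.cx, out.cy, out.w, out.h], [0.5, 0.5, 0.2, 0.2], atol=1e-6)


def test_straddling_box_kept_only_where_area_fraction_passes():
    img = np.zeros((640, 1280, 3), dtype=np.uint8)
    # box x in [512, 672]: 80% of area in tile 0, 20% in tile 1
    lb = BoxLabel(0, 592 / 1280, 0.5, 160 / 1280, 0.25)
    tiles = tile_image(img, [lb], tile_size=640, min_area_frac=0.3)
    assert len(tiles[0][1]) == 1 and len(tiles[1][1]) == 0
    kept = tiles[0][1][0]
    np.testing.assert_allclose(kept.w * 640, 128, atol=1e-3)   # clipped at tile edge


def test_tiling_conserves_labelled_area():
    rng = np.random.default_rng(0)
    img = np.zeros((900, 1500, 3), dtype=np.uint8)
    labels = [BoxLabel(int(rng.integers(3)),
                       float(rng.uniform(0.1, 0.9)), float(rng.uniform(0.1, 0.9)),
                       float(rng.uniform(0.02, 0.3)), float(rng.uniform(0.02, 0.3)))
              for _ in range(20)]
    tiles = tile_image(img, labels, tile_size=640, min_area_frac=0.0)
    total_orig = sum(lb.w * 1500 * lb.h * 900 for lb in labels)
    total_tiles = sum(lb.w * 640 * lb.h * 640 for _, tl in tiles for lb in tl)
    # min_area_frac 0 keeps every clip: area is conserved up to boundary clipping
    assert total_tiles <= total_orig + 1e-3
    assert total_tiles >= 0.95 * total_orig


# -- split ------------------------------------------------------------------

def test_split_811_arithmetic_full_scale():
    records = [ImageRecord(f"r{i}", []) for i in range(10260)]
    m = split_dataset(records, seed=0)
    sizes = {t: len(m.indices(t)) for t in ("train", "val", "test")}
    assert sizes == {"train": 8208, "val": 1026, "test": 1026}


def test_split_small_and_deterministic():
    records = [ImageRecord(f"r{i}", []) for i in range(10)]
    m1 = split_dataset(records, seed=3)
    m2 = split_dataset([ImageRecord(f"r{i}", []) for i in range(10)], seed=3)
    assert {t: len(m1.indices(t)) for t in ("train", "val", "test")} == \
        {"train": 8, "val": 1, "test": 1}
    assert m1.assignment == m2.assignment
    # partition: every record in exactly one split
    assert sorted(m1.assignment) == list(range(10))


def test_split_rejects_bad_input():
    with pytest.raises(ValueError):
        split_dataset([])
    with pytest.raises(ValueError):
        split_dataset([ImageRecord("r", [])], ratios=(0.5, 0.2, 0.2))


def test_stratified_split_balances_classes():
    records = []
    for c in range(3):
        for i in range(40 + 10 * c):
            records.append(ImageRecord(f"c{c}_{i}", [BoxLabel(c, 0.5, 0.5, 0.1, 0.1)]))
    m = split_dataset(records, seed=0, stratify_by_class=True)
    for c in range(3):
        n_c = 40 + 10 * c
        val_c = sum(1 for i in m.indices("val") if records[i].labels[0].class_id == c)
        assert abs(val_c - round(n_c * 0.1)) <= 1


# -- augmentation -----------------------------------------------------------

@pytest.fixture(scope="module")
def scene_record(small_spec):
    s = generate_scene(small_spec, 2)
    return ImageRecord("mem", s.labels, split_tag="train", image=s.image)


def test_mirror_flips_cx(scene_record):
    rng = np.random.default_rng(0)
    out = augment_record(scene_record, "mirror", rng)
    for lb_in, lb_out in zip(scene_record.labels, out.labels):
        assert lb_out.cx == pytest.approx(1.0 - lb_in.cx)
        assert (lb_out.cy, lb_out.w, lb_out.h) == (lb_in.cy, lb_in.w, lb_in.h)


def test_rotate90_coordinate_identity():
    from licodet.data import _transform_box_k90
    lb = BoxLabel(1, 0.3, 0.6, 0.2, 0.1)
    out = _transform_box_k90(lb, 1)
    assert (out.cx, out.cy, out.w, out.h) == pytest.approx((0.4, 0.3, 0.1, 0.2))


def test_brightness_scales_mean_and_keeps_labels(scene_record):
    img = np.full((32, 32, 3), 100, dtype=np.uint8)
    rec = ImageRecord("gray", [BoxLabel(0, 0.5, 0.5, 0.5, 0.5)], image=img)

    class FixedRng:
        def uniform(self, lo, hi):
            return 1.3
    out = augment_record(rec, "brightness", FixedRng())
    assert out.image.mean() == pytest.approx(130, abs=0.5)
    assert out.labels == rec.labels


@pytest.mark.parametrize("op", AUG_OPS)
def test_augmented_boxes_still_cover_plants(scene_record, op):
    rng = np.random.default_rng(7)
    out = augment_record(scene_record, op, rng)
    assert out.labels, f"{op} dropped every box"
    for lb in out.labels:
        assert box_contains_plant(out.image, lb)


def test_unknown_op_rejected(scene_record):
    with pytest.raises(ValueError, match="unknown augmentation"):
        augment_record(scene_record, "cutmix", np.random.default_rng(0))


def test_expand_dataset_counts_and_no_leakage(small_spec):
    records = []
    for i in range(6):
        s = generate_scene(small_spec, i)
        records.append(ImageRecord(f"img{i}", s.labels, image=s.image))
    split_dataset(records, seed=0)
    out = expand_dataset(records, seed=0)
    assert len(out) == 6 * (1 + len(AUG_OPS))
    by_orig = {}
    for rec in out:
        base = rec.image_path.split("#")[0]
        by_orig.setdefault(base, set()).add(rec.split_tag)
    # split tags preserved: each original and all its copies share one tag
    assert all(len(tags) == 1 for tags in by_orig.values())


def test_arbitrary_rotation_encloses_rotated_boxes(scene_record):
    class FixedAngle:
        def uniform(self, lo, hi):
            return 20.0
    out = augment_record(scene_record, "rotate", FixedAngle(), arbitrary_rotation=True)
    assert out.labels
    # enclosing boxes are looser, never tighter, than the originals
    for lb_in, lb_out in zip(scene_record.labels, out.labels):
        assert lb_out.w * lb_out.h >= 0.8 * lb_in.w * lb_in.h
    for lb in out.labels:
        assert box_contains_plant(out.image, lb)
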