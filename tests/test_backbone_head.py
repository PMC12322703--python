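"""Backbone pyramid geometry, ablation flags, head codec, assignment, loss."""
import numpy as np
import pytest

from licodet import nn
from licodet.backbone import BackboneConfig, ResNetAL
from licodet.head import (DetectHead, assign_and_loss, assign_targets, decode,
                          decode_boxes, encode_box, nms)
from licodet.model import Detector, ModelConfig, PRESETS
from licodet.nn.tensor import Tensor


@pytest.fixture(scope="module")
def plain_backbone():
    with nn.init_seed(0):
        return ResNetAL(BackboneConfig(enable_absm=False, enable_lmsm=False)).eval()


def test_pyramid_shapes(plain_backbone, rng):
    x = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
    p = plain_backbone(x)
    assert p.a.shape == (1, 512, 4, 4)
    assert p.b.shape == (1, 256, 8, 8)
    assert p.c.shape == (1, 128, 16, 16)


def test_indivisible_input_rejected(plain_backbone, rng):
    with pytest.raises(ValueError, match="divisible by 32"):
        plain_backbone(Tensor(rng.normal(size=(1, 3, 100, 100)).astype(np.float32)))


def test_forward_finite_over_seeds():
    for seed in range(3):
        with nn.init_seed(seed):
            bb = ResNetAL(BackboneConfig()).eval()
        x = Tensor(np.random.default_rng(seed).normal(size=(1, 3, 64, 64)).astype(np.float32))
        p = bb(x)
        for t in (p.a, p.b, p.c):
            assert np.isfinite(t.data).all()


def test_ablation_chain_constructible_by_flags():
    assert set(PRESETS) == {"resnet34-d", "resnet34-ad", "resnet34-ald", "alpd-net"}
    for name, kw in PRESETS.items():
        cfg = ModelConfig.from_preset(name)
        assert (cfg.enable_absm, cfg.enable_lmsm, cfg.enable_pffm) == \
            (kw["enable_absm"], kw["enable_lmsm"], kw["enable_pffm"])
        assert cfg.preset_name == name
    with pytest.raises(ValueError):
        ModelConfig.from_preset("resnet50")


def test_block_count_matches_resnet34(plain_backbone):
    from licodet.backbone import BasicBlock
    blocks = [m for m in plain_backbone.modules() if isinstance(m, BasicBlock)]
    assert len(blocks) == 16
    assert all(b.absm is None for b in blocks)


# -- head -------------------------------------------------------------------

def test_head_map_shapes_and_cell_count(rng):
    with nn.init_seed(0):
        head = DetectHead()
    feats = [Tensor(rng.normal(size=(1, c, 640 // s, 640 // s)).astype(np.float32))
             for c, s in zip((128, 256, 512), (8, 16, 32))]
    raw = head(feats)
    cells = 0
    for (box, cls) in raw:
        assert box.shape[1] == 4 and cls.shape[1] == 3
        assert (box.data >= 0).all()              # softplus keeps distances non-negative
        cells += box.shape[2] * box.shape[3]
    assert cells == 80 ** 2 + 40 ** 2 + 20 ** 2 == 8400


def test_decode_formula_and_clipping():
    bm = np.zeros((4, 2, 2), dtype=np.float32)
    bm[:, 0, 0] = 1.0                              # ltrb = (1,1,1,1) at cell (0,0)
    cm = np.full((3, 2, 2), -20.0, dtype=np.float32)
    cm[1, 0, 0] = 4.0
    dets = decode([(bm, cm)], conf_thresh=0.5, nms_iou=0.5, image_size=640, strides=(8,))
    assert len(dets) == 1
    np.testing.assert_allclose(dets[0].box, [0, 0, 12, 12])   # (-4,-4,12,12) clipped
    assert dets[0].class_id == 1


def test_decode_empty_below_threshold():
    bm = np.ones((4, 4, 4), dtype=np.float32)
    cm = np.zeros((3, 4, 4), dtype=np.float32)     # all scores sigmoid(0) = 0.5
    assert decode([(bm, cm)], conf_thresh=0.6, nms_iou=0.5, strides=(8,)) == []
    assert len(decode([(bm, cm)], conf_thresh=0.5, nms_iou=0.99, strides=(8,))) > 0


def test_nms_suppresses_overlap():
    boxes = np.array([[0, 0, 10, 10], [0.5, 0, 10.5, 10], [20, 20, 30, 30]], dtype=float)
    scores = np.array([0.9, 0.8, 0.7])
    keep = nms(boxes, scores, 0.5)
    assert keep == [0, 2]


def test_encode_decode_identity(rng):
    for _ in range(50):
        stride = int(rng.choice([8, 16, 32]))
        i, j = int(rng.integers(0, 10)), int(rng.integers(0, 10))
        cx, cy = (j + 0.5) * stride, (i + 0.5) * stride
        box = np.array([cx - rng.uniform(1, 40), cy - rng.uniform(1, 40),
                        cx + rng.uniform(1, 40), cy + rng.uniform(1, 40)])
        ltrb = encode_box(box, i, j, stride)
        assert (ltrb >= 0).all()
        grid = np.zeros((4, 12, 12), dtype=np.float32)
        grid[:, i, j] = ltrb
        dec = decode_boxes(grid, stride)[i, j]
        np.testing.assert_allclose(dec, box, atol=1e-3)


def test_assignment_center_radius_rule():
    # a box containing exactly one cell centre
    gt = np.array([[2.0, 2.0, 11.0, 11.0]])
    assigned, _ = assign_targets(gt, np.array([0]), 4, 4, 8)
    assert np.argwhere(assigned >= 0).tolist() == [[0, 0]]
    # a huge box: the radius rule limits positives to cells near its centre
    gt = np.array([[0.0, 0.0, 320.0, 320.0]])
    assigned, _ = assign_targets(gt, np.array([1]), 40, 40, 8)
    ii, jj = np.nonzero(assigned >= 0)
    ctr = (320 / 2) / 8 - 0.5                      # cell-index of box centre
    assert np.abs(ii - ctr).max() <= 2.5 and np.abs(jj - ctr).max() <= 2.5


def test_smaller_box_wins_ties():
    gt = np.array([[0.0, 0.0, 64.0, 64.0], [24.0, 24.0, 40.0, 40.0]])
    assigned, cls_t = assign_targets(gt, np.array([0, 2]), 8, 8, 8)
    assert assigned[4, 4] == 1 and cls_t[4, 4] == 2


def test_zero_target_loss_closed_form():
    raw = [(Tensor(np.zeros((1, 4, 4, 4))), Tensor(np.zeros((1, 3, 4, 4)), requires_grad=True))]
    loss, comps = assign_and_loss(raw, [[]], image_size=32, strides=(8,))
    assert comps["cls"] == pytest.approx(np.log(2), rel=1e-5)
    assert comps["box"] == 0.0
    loss.backward()     # finite gradients on a target-free image


def test_perfect_prediction_near_zero_loss():
    from licodet.data import BoxLabel
    lb = BoxLabel(2, 0.5, 0.5, 0.25, 0.25)         # 16x16 box centred in a 64 image
    box_map = np.zeros((1, 4, 8, 8), dtype=np.float32)
    cls_map = np.full((1, 3, 8, 8), -40.0, dtype=np.float32)
    x0, y0, x1, y1 = lb.to_xyxy(64, 64)
    for i in range(8):
        for j in range(8):
            cx, cy = (j + 0.5) * 8, (i + 0.5) * 8
            if x0 < cx < x1 and y0 < cy < y1:
                box_map[0, :, i, j] = encode_box((x0, y0, x1, y1), i, j, 8)
                cls_map[0, 2, i, j] = 40.0
    loss, comps = assign_and_loss([(Tensor(box_map), Tensor(cls_map))], [[lb]],
                                  image_size=64, strides=(8,))
    assert float(loss.data) < 1e-4


def test_loss_decreases_when_overfitting_tiny_model():
    from licodet.train import smoke_overfit
    r = smoke_overfit(n_images=1, size=64, max_steps=30, batch_size=1, lr=0.01,
                      eval_every=1000, model="resnet34-d")
    assert r["losses"][-1] < r["losses"][0] * 0.5
    assert np.isfinite(r["losses"]).all()
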