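# licodet

Single-stage detection of wild licorice (*Glycyrrhiza uralensis*,
*G. glabra*, *G. inflata*) in UAV imagery.

Wild licorice grows scattered through arid, weed-cluttered rangeland, and
the three species look alike from the air; telling them apart — and telling
any of them from surrounding weeds — is a fine-grained detection problem
with heavy background interference, large within-class scale variation and
mutual occlusion.  `licodet` implements a detector built for exactly that
setting, together with the complete surrounding pipeline: frame tiling,
YOLO-format label handling, 8:1:1 splitting, box-aware augmentation,
training with early stopping, mAP evaluation, FLOP accounting, Grad-CAM
diagnostics, and a synthetic scene generator so that every stage is testable
without field data.

## The model

The detector is anchor-free and single-stage, with three components on top
of a ResNet34 backbone and a decoupled classification/regression head:

* **ABSM** (adaptive background suppression, inside every residual block):
  channels of a compressed feature map become attention tokens; multi-head
  channel attention followed by a softmax produces channel weights `w`
  (Σw = 1), and the block is rescaled by `C·w`.  A coordinate gate
  `sigmoid(p_h + p_w)` built from pooled directional profiles, and a second
  sigmoid gate from a 1×1 convolution, then suppress background locations
  multiplicatively.
* **LMSM** (lightweight multi-scale extraction, after every backbone
  stage): a 1×1 reduction splits into four groups convolved at dilations
  1–4 (receptive fields 3–9 px per axis), gated by a pooled channel branch;
  the block is residual and costs ~0.13 % of total FLOPs.
* **PFFM / WSAF** (progressive fusion neck): with the backbone pyramid
  `(a, b, c)` at strides 32/16/8, five weighted self-attention fusion units
  compute

      A = WSAF(a, WSAF(b, c))
      B = WSAF(WSAF(a, b), WSAF(b, c))
      C = WSAF(c, WSAF(a, b))

  where `WSAF(F01, F02) = z + MHSA(z) + DWConv(z)` with
  `F1 = W1·F01 + W2·aligned(F02)`, `z = sigmoid(GAP(F1))·F1 + F1`, learnable
  scalars `W1, W2`, and keys/values pooled to ≤441 tokens.

The ablation chain is reproducible by flags: `resnet34-d` (baseline) →
`resnet34-ad` (+ABSM) → `resnet34-ald` (+LMSM) → `alpd-net` (full model).

Everything — convolutions, attention, batch-norm, the optimisers and the
reverse-mode autodiff underneath — is implemented in this package on
numpy, so the library has no deep-learning framework dependency.

## Worked example

```python
from licodet import Detector, count_flops
from licodet.scenes import SceneSpec, generate_scene
from licodet.model import preprocess
from licodet.head import decode

gflops, table = count_flops(Detector("alpd-net"), 640)
print(f"{gflops:.1f} GFLOPs over {len(table)} counted layers")

scene = generate_scene(SceneSpec(image_size=256, seed=0), index=0)
model = Detector("alpd-net").eval()
raw = model(preprocess(scene.image))
dets = decode([(b.data[0], c.data[0]) for b, c in raw],
              conf_thresh=0.4, image_size=256)
print(f"{len(scene.labels)} plants labelled, {len(dets)} raw detections")
```

prints

```
83.1 GFLOPs over 240 counted layers
5 plants labelled, 87 raw detections
```

— 83.1 GFLOPs is the full model's one-pass cost at its native 640×640
input (the number is analytic, so it is identical on any machine), and an
untrained network fires indiscriminately: its class logits sit near zero,
so scores hover around 0.5 and survive a 0.4 confidence cut everywhere.
Training is what separates plants from background; a quick capability check
is

```python
from licodet.train import smoke_overfit
result = smoke_overfit(n_images=4, size=96, max_steps=60, batch_size=4,
                       lr=2e-3, model="resnet34-d")
print(round(result["map50"], 3), result["steps"])
```

which overfits four easy scenes to train-set `mAP50 = 1.0` by step 50 on
one CPU core (about a minute), printing `1.0 50`.

The command-line surface wraps the same functions:

```
licodet synth   --n 100 --seed 0 --out data/raw
licodet prepare --src data/raw --out data/prepared --seed 0
licodet train   --data data/prepared --model alpd-net --epochs 200 --out runs/full
licodet eval    --data data/prepared --ckpt runs/full/best.npz --out runs/full/eval
licodet flops   --model resnet34-ald --imgsz 640 --out runs/flops.csv
licodet cam     --ckpt runs/full/best.npz --image img.png --out cam.png
```

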