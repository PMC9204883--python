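# truss-seg

Identification of the **growing truss** — the young, actively growing
stem-and-leaf tip of a greenhouse tomato plant — in images taken by a
camera rig driving along the crop row. The truss is the part of the plant
the grower keeps nearest the camera line, so in a depth camera's colorized
range image (near → red, far → blue) it is simply the red object, and a
deterministic chain of HSV gating, Otsu binarization and morphology
extracts it. Because depth cameras lose focus at close range, the package
also provides a **CycleGAN** that translates plain RGB frames into
depth-colormap-style images, so the *same* extraction chain runs without
trusting the depth sensor. It is aimed at plant-phenotyping and
agricultural-robotics researchers who need truss masks from row-scanning
imagery.

## What is inside

- `truss_seg.synthetic` — a procedural generator of paired
  RGB / metric-depth / ground-truth scenes emulating the greenhouse
  regime (near truss, far cluttered canopy, optional depth-sensor
  defocus failures), so everything is testable without field data.
- `truss_seg.cyclegan` — the translation model: generators G: X→Y
  (RGB → depth colormap) and F: Y→X with 70×70 patch discriminators,
  least-squares adversarial + cycle-consistency losses
  (mean |F(G(x)) − x| and |G(F(y)) − y|, weight λ = 10), trained on
  *unpaired* domains. Pure numpy with gradient-checked layers;
  model/results style: `CycleGAN(xs, ys, ...).fit()` →
  `CycleGANResults` with `summary()`, `convert()`, `save()`.
- `truss_seg.segmentation` — the extraction chain: HSV gate (presets
  `a`/`b`/`c`; `c` = H 0–30, S 248–255, V 240–255 is production), Otsu
  threshold of the gated luma, closing + contour fill + one 3×3 erosion +
  small-object removal.
- `truss_seg.evaluation` — residual-ratio FN% = 100·|truth∖pred|/|truth|,
  FP% = 100·|pred∖truth|/|pred|, mIoU% = 100·|∩|/|∪|, mean ± SD
  aggregation, pixel-level ROC/AUC.
- `truss_seg.experiment` + the `truss-seg` CLI — the end-to-end protocol
  (simulate → train → convert → segment → evaluate → compare the
  depth-camera path against the translation path and a raw-RGB baseline).

## Worked example

```python
import numpy as np
from truss_seg import (
    SceneConfig, generate_scene, segment_truss, miou,
    CycleGAN, GeneratorConfig, TrainConfig,
)

# 20 synthetic scenes; segment the depth camera's own colormap
cfg = SceneConfig(defocus_prob=0.0, rng_seed=1)
scenes = [generate_scene(cfg, i) for i in range(20)]
vals = [miou(segment_truss(s.depth_colormap()), s.truth) for s in scenes]
print(f"depth-path mIoU: {np.mean(vals):.2f} +/- {np.std(vals, ddof=1):.2f} %")

# scaled-down unpaired training: RGB domain vs colormap domain
small = SceneConfig(image_size=64, defocus_prob=0.0, rng_seed=11)
train_scenes = [generate_scene(small, i) for i in range(20)]
model = CycleGAN(
    np.stack([s.rgb for s in train_scenes]),
    np.stack([s.depth_colormap() for s in train_scenes]),
    gen_config=GeneratorConfig(input_size=64, base_channels=8, transformer_blocks=4),
    train_config=TrainConfig(iterations=300, batch_size=5, rng_seed=7),
)
res = model.fit()
print(res.summary())
held = [generate_scene(small, i) for i in range(20, 26)]
gan = [miou(segment_truss(res.convert(s.rgb)), s.truth) for s in held]
raw = [miou(segment_truss(s.rgb), s.truth) for s in held]
print(f"translated-path mIoU on held-out scenes: {np.mean(gan):.1f} %")
print(f"raw-RGB-path mIoU on held-out scenes:    {np.mean(raw):.1f} %")
```

This prints (elided to the interesting lines):

```
depth-path mIoU: 91.09 +/- 1.11 %
...
cycle loss (fwd+rev), first 30 its: 1.0505
cycle loss (fwd+rev), last 30 its:  0.4437
final losses: g=6.0242 dx=0.1995 dy=0.0904
translated-path mIoU on held-out scenes: 21.9 %
raw-RGB-path mIoU on held-out scenes:    0.0 %
```

Reading: segmenting the true depth colormap recovers the ground-truth
truss almost exactly (the residual ~9 % is the deliberate 1-pixel erosion
rim of the cleanup stage). Unpaired training at desk scale halves the
round-trip cycle loss, and the translated RGB frames — unlike the raw
green-on-green RGB, which the red gate cannot segment at all — already
yield usable truss masks on scenes the model never saw.

The same flow from a shell:

```sh
truss-seg simulate --n 89 --seed 7 --size 64 --out data/   # 69 train / 20 test
truss-seg train --data data/ --iters 300 --batch 5 --seed 7 \
    --base-channels 8 --blocks 4 --out ck.npz
truss-seg segment --ckpt ck.npz --in data/rgb/scene_0080.png --out mask.png
truss-seg run --out runs/demo --seed 7 --n-scenes 26 --iters 300 \
    --size 64 --base-channels 8 --blocks 4
```

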