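# peelnet

Single-stage detection of **potato peel damage** (broken-skin regions).
Potatoes bruised during harvest and transport develop broken-skin patches
that shorten storage life and invite microbial rot; automated sorting needs
these low-contrast defects found quickly and located tightly. `peelnet`
implements a compact anchor-free detector with four architectural
enhancements over a stock backbone–neck–head design, the Wise-IoU v1
bounding-box regression loss, the full evaluation mathematics, and a
synthetic annotated-scene generator so that the entire pipeline runs and is
tested without any image download.

## The model

A stride-8/16/32 pyramid detector with:

- **C3k2-MLCA** backbone blocks — Mixed Local Channel Attention: local
  average pooling onto a k×k grid (LAP) and global average pooling (GAP),
  a shared circular 1-D convolution over the channel axis, then a sigmoid
  gate de-pooled back to full resolution and applied multiplicatively,
  `out = F ⊙ σ(conv1d(LAP(F)) + conv1d(GAP(F)))`.
- **EIEStem** input stem — the first two stride-2 convolutions are replaced
  by a stem whose second stage splits into a frozen **SobelConv** branch
  (per-channel Gx/Gy stencils, both directional maps kept as channels) and a
  zero-padded 3×3 max-pooling branch, concatenated and fused by 1×1 conv.
- **Re-Calibration FPN** neck — Selective Boundary Aggregation blocks built
  from Re-calibration Attention Units: semantic and boundary features are
  reduced to 32 channels, fused as `W ⊙ F_s′ + (1−W) ⊙ F_b′` with
  `W = σ(g(F_s′))`, run bidirectionally and merged by a 3×3 conv.
- **AFPN** head — asymptotic pyramid fusion: levels are merged progressively
  (P3+P4 first, then P5) with per-pixel softmax fusion weights that are
  nonnegative and sum to one across levels.
- **Wise-IoU v1** loss — `L = R · (1 − IoU)` with
  `R = exp(((x−x_gt)² + (y−y_gt)²) / (W_g² + H_g²)*)`, where `W_g, H_g` are
  the enclosing-box dimensions and the starred denominator is evaluated and
  then *detached* from differentiation. CIoU, DIoU, GIoU and EIoU are
  provided for comparison experiments.

Evaluation follows the standard detection protocol: greedy confidence-ordered
matching, P and R as percentages, `F1 = 2PR/(P+R)`, all-points interpolated
AP, mAP@0.5 and mAP@0.5:0.95, and run statistics
`SD = sqrt(Σ(xᵢ−x̄)²/(n−1))`, `CI = x̄ ± z·SD/√n` (z = 1.96).

Everything — including a small reverse-mode autodiff engine with conv/pool/
batch-norm primitives — is pure numpy/scipy, so the package trains and runs
on one CPU.

## Worked example

```python
import numpy as np
from peelnet import SceneSpec, generate_scene, ModelConfig
from peelnet.pipeline import micro_train_config, train, evaluate

scenes = [generate_scene(SceneSpec(), seed) for seed in range(8)]
model, history = train(micro_train_config(300, seed=0), scenes, ModelConfig())
report = evaluate(model, scenes, conf_thr=0.01)
print(f"loss {history[0]['loss']:.2f} -> {history[-1]['loss']:.2f}")
print(report.to_text())
```

prints (seed 0):

```
loss 24.75 -> 0.42
   p (%)    r (%)  mAP@0.5 (%)  mAP@0.5:0.95 (%)      F1
    94.7     94.7         94.2              74.0   0.947
```

i.e. after 300 iterations the full enhanced model has memorized the eight
synthetic scenes: at the best operating point 18 of 19 patches are found
with one false positive (P = R = 94.7 %, F1 = 0.947), the area under the
precision-recall envelope at IoU 0.5 is 94.2 %, and localization is tight
enough that averaging over the stricter 0.5:0.95 threshold ladder still
yields 74 %.

The same pipeline is scriptable from the shell:

```bash
peelnet generate data/ --n 100 --seed 0          # YOLO-layout dataset, 8:1:1
peelnet train data/ --out model.npz --epochs 20
peelnet eval model.npz data/ --split val --runs 5
peelnet compare-losses data/ --kinds wiou,ciou
peelnet ablate data/
```

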