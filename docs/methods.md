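# Methods

## Problem and scope

`peelnet` detects broken-skin (peel-damage) regions on potatoes as
axis-aligned boxes in RGB images. It is a desk-scale research tool: the goal is a
faithful, tested rendering of the architectural modules, the Wise-IoU v1
regression loss and the evaluation mathematics — not GPU-scale training on
a production image set.
All experiments therefore run on synthetic scenes whose statistical
structure mimics a broken-skin inspection dataset.

## Numerical core

The detector runs on a small reverse-mode automatic-differentiation engine
(`peelnet.autodiff`) over float64 numpy arrays. Convolution, max/average
pooling, batch normalization, nearest-neighbour resizing and the circular
1-D channel convolution are primitives with hand-written backward passes;
everything else composes from elementwise operations. Engine gradients are
verified against central finite differences in the unit tests (tolerance
1e-5 relative; batch norm 2e-4 because its forward subtracts nearly equal
means). Float64 is deliberate: it keeps finite-difference checks sharp and
makes end-to-end runs bitwise reproducible for fixed seeds.

## Model

Layout (strides 8/16/32, default widths 12/24/40/56 for stem/P3/P4/P5):

    stem -> down(P3) -> C3k2[-MLCA] -> down(P4) -> C3k2[-MLCA]
         -> down(P5) -> C3k2[-MLCA] -> SPPF -> PSA block
         -> neck (Re-Calibration FPN | PAN) -> head (AFPN | plain)
         -> per-level decoupled 3x3+1x1 cls / reg branches

Decisions taken where the design was genuinely open:

- **MLCA fusion order.** The mechanism's narrative admits two orderings of
  "multiply with the input" and "add the global branch". We fix
  `out = F ⊙ σ(conv1d(LAP) + conv1d(GAP))`: gate after the add, multiply
  last. The alternative (gating before adding the global term) changes only
  the scale of the global contribution; the chosen form keeps the gate in
  (0,1) exactly, which the tests rely on.
- **MLCA grid and kernel.** Local grid k = 5; at deep levels whose feature
  maps are smaller than k the grid is clamped to the map size. The 1-D
  kernel length follows the channel-adaptive odd rule
  `ks = nearest odd to log2(C)/2 + 1/2`, floored at 3. The kernel is
  initialized to a centered delta so the initial gate is a mild squashing of
  the channel mean rather than noise.
- **MLCA placement.** Inside each backbone C3k2, applied to the output of
  the last bottleneck before the 1×1 fusion conv. Setting `attn = None`
  recovers a plain C3k2 bit-for-bit (tested), which is what the ablation
  toggles.
- **De-pooling** is nearest-neighbour resizing: parameter-free and
  gate-range preserving.
- **EIEStem.** Sobel stencils are grouped 2-D convolutions (the numerically
  identical reading of a "3-D group convolution" over the two stencils);
  responses are kept as separate Gx/Gy channels, not collapsed to a
  magnitude. The Sobel input is replicate-padded so a constant image yields
  an exactly zero edge response including the border. The edge branch passes
  through batch norm + SiLU to match the scale of the pooling branch
  (zero-padded 3×3 max pool, stride 1). Kernels live in buffers and receive
  no updates (tested bit-identical across a training step).
- **Re-Calibration FPN pairing.** The neck pairs deep→shallow:
  N3 = SBA(P4, P3), N4 = SBA(P5, P4), N5 = conv(P5), keeping three output
  scales. The RAU gate is computed from the reduced *semantic* (deeper)
  feature; the "reverse operation" is `1 − W` routing attention to the
  boundary stream. Channel reduction is fixed at 32; the SBA fusion conv is
  3×3 + BN + ReLU on the 64-channel concatenation.
- **AFPN.** Stage 1 fuses P3 and P4 (each updated at its own resolution from
  the originals); stage 2 folds P5 in across all three levels. The
  three-level stage is iterated (default 2) with weights shared across
  iterations — the refinement is a fixed-point-style update, and sharing
  keeps the head compact. Fusion weights are per-pixel softmaxes of 1×1-conv
  scores, so they are nonnegative and sum to one by construction.
- **PSA block.** The attention block over the SPPF output is implemented at
  contract level: 1×1 projection, sigmoid gate, residual 3×3 mix.
- **Decoding** is anchor-free: each location regresses four nonnegative
  left/top/right/bottom distances (softplus, in stride units) around its
  cell center; class-wise greedy NMS (default conf 0.25, IoU 0.45) follows.

## Losses

`wiou_v1(pred, gt) = exp(d²/ (W_g²+H_g²)*) · (1 − IoU)`, with the starred
enclosing-box term evaluated and then treated as a constant during
differentiation ("detached"). `L_IoU = 1 − IoU` is the standard plain IoU
loss. The test suite checks the detachment contract two ways: the analytic
gradient matches finite differences of the function with the denominator
frozen, and a variant that differentiates the denominator produces a
measurably different gradient. GIoU, DIoU, CIoU (aspect-ratio weight α
treated as a constant, as in its original formulation) and EIoU use their
published closed forms. A small epsilon (1e-10) guards empty-union and
zero-area denominators; loss values are therefore exact to ~1e-11 relative.

## Training

Loss = BCE(class logits, targets)/max(N_pos, 1) + 7.5 · box loss on positive
cells. Label assignment is dynamic: candidates are cells whose center lies
inside a ground-truth box (nearest-cell fallback for sub-cell boxes); each
ground truth keeps its top-10 candidates ranked by IoU of the currently
decoded boxes; a contested cell goes to the box it overlaps most.
Classification targets are quality-aware — a positive cell's target is the
IoU of its decoded box with its ground truth (floored at 0.02) — so the
confidence ranking tracks localization quality and NMS keeps the
best-localized candidate. This measurably improves mAP@0.5:0.95 on the
micro-benchmark (the hard-target variant plateaus ~10 points lower).

`TrainConfig` defaults carry the reference training settings: Adam, initial learning
rate 1e-5, final 1e-4 (linear schedule; the increasing direction is kept at
face value and is overridable), weight decay 5e-4, batch 16. The
**micro-overfit recipe** (`micro_train_config`) used by the tests and the
acceptance script instead runs a constant Adam rate of 5e-3 for 300
iterations with batch = dataset (8 scenes at 128²): a 200-epoch
schedule topping out at 1e-4 cannot move a freshly initialized network in
300 steps, and the memorization experiment is about the architecture and
loss, not the production schedule.

## Synthetic scenes

`SceneSpec` defaults describe the emulated inspection conditions: 128×128
images, 1–2 elliptical tubers (semi-axes 22–40 % of the image side) with
low-frequency brown peel texture on a dark background, 1–3 irregular damage
patches per tuber covering 1–6 % of the tuber area each, colored in a
lighter/yellower band than the peel (the generator enforces this contrast —
broken skin exposes pale flesh), plus Gaussian pixel noise (σ = 0.015).
Patches are built by intersecting a disk with thresholded smoothed noise and
keeping the connected component at the sampled center; each annotation is
the tight bounding box of the patch mask (the generator also returns the
masks so tests can verify tightness exactly).

Augmentation implements the standard set — horizontal flip, translation,
rotation, brightness/contrast, scaling — with boxes transformed
consistently: rotation replaces a box by the axis-aligned hull of its
rotated corners, and boxes are clipped and dropped when less than 25 % of
their (hull) area stays visible. The default of two augmented copies per
original grows a dataset roughly threefold. Splits are 8:1:1
(largest-remainder apportionment, seeded shuffle).

What the generator does **not** emulate: soil and occlusion, specular
highlights, camera blur, multi-class defect taxonomies, and the long-tailed
shape variation of real damage. Passing the micro-benchmark therefore
demonstrates that the architecture, loss, assignment and evaluator work
end-to-end and can memorize realistic-looking annotated structure; it is not
evidence about accuracy on real potatoes.

## Evaluation

Greedy confidence-ordered matching (one match per ground truth; ties by
higher IoU then input order); P and R in percent with 0-denominator → 0 by
convention; F1 on the 0–1 scale; AP by all-points interpolation (the
monotone precision envelope integrated over recall — the continuous integral
ideal admits several discretizations and this is the one that equals the
brute-force rectangle sum, which the tests verify); mAP@0.5:0.95 averages
the ten-threshold ladder. Table-style P/R/F1 are reported at the score
threshold maximizing F1 over the detection sweep, since no fixed operating
point is canonical. Repeated-run spread uses the sample SD (n−1) and the
normal 95 % interval x̄ ± 1.96·SD/√n.

## Problem sizes

The test suite and the acceptance script run everything at small scale
chosen as a deliberate design point: 64–128 px images, widths 12/24/40/56
(~0.6 M parameters for the full model), 8-scene micro-overfit at 300
iterations (~3 minutes on one CPU), shortened 40-iteration runs for the
remaining ablation-lattice configurations, and a 10–12-iteration 64-px run
for the determinism checks.

## Known limitations

- The engine is single-threaded numpy; wall-clock scales roughly with
  channels² × pixels. It is a research desk tool, not a production trainer.
- Parameter counts are not comparable to any published model size: channel
  widths here are compact by design and the original widths are unpublished.
- WIoU v2/v3 focusing coefficients, ShapeIoU, rotated boxes, and COCO-JSON
  evaluation are out of scope.
- The increasing learning-rate schedule is kept as documented configuration,
  not endorsed; the micro recipe overrides it.
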