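# Methods

## Model

A patch classifier for multitissue H&E histopathology built as:
convolutional backbone (global average pooling removed; the spatial feature
map is flattened) → bank of m bilinear interaction nodes → soft-attention
gate → dense softmax head.

**Bilinear node.**  `y = b + wᵀx + xᵀFᵀFx` with `F ∈ R^{k×n}`.  The
quadratic form is positive semidefinite, so the interaction term is always
≥ 0 and the node reduces exactly to the linear node when `F = 0`.  The
implementation evaluates `xᵀFᵀFx` as `‖Fx‖²` (O(nk)); the O(n²k) expansion
`Σᵢⱼ ⟨fᵢ,fⱼ⟩xᵢxⱼ` over columns of `F` is retained purely as an independent
oracle, and their agreement (≤ 1e-9 relative on random instances) is a
tested invariant.  Each of the m output nodes carries its own `F` (the
faithful reading of the per-node formulation); a shared-F mode exists as a
memory-saving opt-in.

**Soft attention.**  The score vector is taken elementwise,
`eᵢ = wᵢ fᵢ`: the published formulation writes the score as a scalar sum
yet indexes `eᵢ` inside the softmax, and the elementwise reading is the
only one consistent with both (its sum reproduces the scalar).  Weights
`a = softmax(e)` use max-subtraction for finite-arithmetic stability.  Two
read-outs: the literal pooled scalar `c = Σ aᵢfᵢ` (kept as a reference
operation) and the gated vector `r = a ⊙ f` used by the network — a scalar
cannot feed a multiclass head, and the gated vector preserves
dimensionality while conserving `sum(r) = c` (a tested invariant).

**Backbone.**  `tiny_cnn`: three 3×3 conv + ReLU + 2×2 max-pool blocks
(16/32/32 channels, total stride 8, ~50k parameters), optionally followed
by a 1×1 channel reduction.  It exists so the full pipeline trains on one
CPU in minutes; input size must be a multiple of 8 (default 32 px
throughout the benchmarks).  No pretrained large backbone is bundled: the
package has no deep-learning-framework dependency, and its NumPy engine
(hand-derived backward passes for conv/pool/dense/bilinear/attention,
finite-difference-verified to 1e-4 relative) is the compute substrate.
The engine computes in float32 by default; every layer accepts
`dtype=float64`, which the gradient-check tests use.

## Training recipe

Cross-entropy on softmax outputs; Adam with lr 3e-4, β₁ = 0.9 (the natural
reading of "momentum 0.9" alongside Adam), β₂ = 0.999, L2 weight decay
1e-4 folded into the gradient; batch size 32; default 80 epochs.  Plateau
schedule: if the epoch-mean training loss sets no new minimum (tolerance
1e-4) for `plateau_patience` epochs (default 30), the learning rate is
multiplied by 0.1.  The recorded history holds per-epoch train loss, val
loss, val accuracy, and the LR used that epoch.  All randomness (init,
shuffling, augmentation) flows from caller-supplied integer seeds through
`numpy.random.Generator`; identical seeds give bit-identical initialization
and identical histories.

Augmentation: rotations by uniform multiples of 90° (avoiding
interpolation artifacts; the angle set is otherwise unconstrained by the
recipe), horizontal flip with p = 0.5, and "normalized colour appearance"
implemented as per-channel mean/std standardization of the patch (full
stain normalization such as Macenko is out of scope).  When colour
standardization is on during training it is recorded on the model and
applied identically at inference.  Augmentation must be label-preserving:
for texture classes *defined by orientation*, 90° rotations and flips move
patches across class boundaries, so the hard-preset benchmark trains with
geometric augmentation off.

Transfer learning: all weights are loaded from a checkpoint except the
dense head, which is re-initialized when the new class vocabulary differs
in size (with matching sizes the head is kept, so fine-tuning for zero
epochs is the identity).  Checkpoints are single `.npz` archives holding
parameters, model config, class vocabulary, preprocessing flag, and
pretraining provenance.

## Stage-2 segmentation

1. **Tissue mask.**  The slide is block-mean downsampled by an integer
   factor (default 32, edge-padded with replication so edge blocks are
   full) and thresholded.  Default: Otsu on the HSV saturation channel —
   robust when the background is bright/near-white, as in H&E;
   grayscale-Otsu and a fixed grayscale threshold are options.  A constant
   (blank) slide yields an all-zero mask with a warning, not an exception.
2. **Tiling.**  All windows of `tile_size` (default 224) at integer
   multiples of `stride` (default 128) that lie fully inside the slide
   (edge windows are dropped, not padded) and whose footprint is at least
   `tissue_frac_min` (default 0.5 — majority tissue) in the upsampled mask.
   Coordinates are 0-based, half-open, (row, col) everywhere.
3. **Classification.**  Tiles are batched through the model; an
   alternative coordinate-aware callable protocol admits the ground-truth
   oracle classifier used in pipeline tests.
4. **Stitching.**  Tile probability vectors are summed over their pixel
   footprints with a coverage count; covered pixels take the argmax of the
   coverage-averaged probabilities (ties to the lowest class id), uncovered
   pixels the reserved background label (−1).  Averaging is
   order-independent and smooths tile-boundary artifacts; with
   non-overlapping tiles it reduces exactly to per-tile argmax (tested).
   The result is patch-level, not pixel-level semantic segmentation.
5. **Overlay.**  Alpha-blended class colours over the slide; background
   rendered transparent; label maps are written as palette-indexed PNGs
   with a JSON legend.

The pipeline consumes plain RGB arrays; pyramidal WSI containers are out
of scope and can be adapted by reading a level into an array.

## Grad-CAM

Channel weights are spatial means of ∂(class logit)/∂(activation) at the
hooked layer — the pre-softmax logit, the standard choice; the bilinear and
attention modules are treated as part of the head, and the default hook is
the backbone's last convolutional layer.  The map is
`ReLU(Σ_c weight_c · activation_c)`, bilinearly upsampled to input
resolution and then min-max normalized (normalizing after upsampling keeps
the maximum exactly 1 unless the raw map is identically zero).

## Synthetic data

The generator emulates the statistical structure the method targets rather
than H&E stain physics or nuclei morphology.  Five texture families
(sinusoidal stripes, Gaussian blobs, checkerboard, smooth tint ramps,
noise) with per-class parameter intervals; each draw jitters orientation,
frequency, tint, phase, and contrast (large intraclass variability).
Presets:

* **easy** — six classes with disjoint ranges and distinct tints; linearly
  separable in practice and learnable to ≥ 95% quickly.
* **hard** — four stripe classes sharing one eosin-like tint and defined
  only by the *joint* orientation × frequency statistics (orientation
  0–35° vs 55–90°, frequency 0.06–0.10 vs 0.14–0.20 cycles/px): mean
  colour carries no class signal (a raw-pixel logistic regression stays
  near chance, tested), so second-order feature interactions are the
  natural discriminant.  The gaps between adjacent ranges are sized so a
  three-block CNN at 32 px can resolve them — with substantially narrower
  gaps no variant converges in the benchmark budget and the module
  comparison measures optimization noise instead of architecture.

Mosaic pseudo-slides place textured rectangles/polygons on a near-white
(245 ± noise) background with a pixel-exact ground-truth label map; the
quadrant layout aligns region edges to the mask downsampling grid so the
tissue-mask IoU measures thresholding, not grid quantization.  A
ground-truth oracle tile classifier (majority label in the tile footprint,
one-hot) isolates the tiling/stitching stages from model quality.

What passing on this data does *not* show: robustness to stain variation,
scanner artifacts, nuclei-level morphology, or class imbalance in real
slides — the generator has none of these.

## Pinned benchmark conditions

Chosen once, at desk scale, and shared by the test suite and
`scripts/acceptance.py` through `tissuegrid.benchmarks`:

* **easy learning** — 6 classes × 300 patches at 32 px, seed 7, 15 epochs,
  default augmentation; threshold: held-out accuracy ≥ 0.95.
* **ablation** — hard preset, 150 patches/class, 30 epochs, seeds 0–2,
  geometric augmentation off; full model mean accuracy must be within 0.02
  of (or above) every single-module variant.  The epoch budget is the
  smallest at which all bilinear-bearing variants reach their plateau.
* **mosaic** — 1024² canvas, four 480² quadrants inset 32 px, downsample
  32, tiles 224/stride 128, oracle classifier; mask IoU ≥ 0.95, ground
  truth agreement ≥ 0.99 on tissue pixels more than one tile size from any
  region boundary (Chebyshev distance).
* **Grad-CAM localization** — blob-vs-uniform task, 150 + 50 patches per
  class, 40 epochs; heat inside the blob bounding box must exceed outside
  for ≥ 90% of the 50 held-out blob patches.

## Metrics

Confusion matrix (rows = true, cols = predicted); per-class precision,
recall, F1 with zero-support / zero-prediction cases flagged and reported
as 0.  Macro averages are unweighted class means.  The reported **average
F1 is the harmonic mean of macro precision and macro recall** — the
convention that reproduces, to the printed 4 decimals, every row of the
published multitissue benchmark tables (all 14 rows are regression-tested);
the plain mean of per-class F1s does not, and is computed alongside under
`mean_f1`.

## Known limitations

* The `tiny_cnn` backbone is the only one provided; there is no large
  pretrained backbone, so absolute accuracies on real histopathology data
  are out of scope by design.
* The NumPy engine is single-threaded-friendly but not competitive with
  GPU frameworks; it is meant for desk-scale correctness, ablation, and
  pipeline work.
* Patch-level label maps only; no CRF refinement, no pixel-level
  segmentation.
* Synthetic textures do not model stain chemistry; conclusions about real
  H&E generalization require real data.
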