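# Methods

## Problem setting

Seven-way classification of strawberry leaf photographs: healthy leaves plus
six diseases (powdery mildew, leaf spot, *Botrytis cinerea*, anthracnose,
verticillium wilt, leaf scorch). Lesion color and texture carry most of the
discriminative signal, so the model front-loads two hand-crafted
descriptors — a local color correlogram and a rotation-invariant compensated
LBP — and lets a dual-branch residual network with a directional attention
block do the deep feature extraction.

## Color correlogram (color path)

For a quantized image (Q levels per channel, default Q = 64) the descriptor
counts ordered color pairs ⟨color_i, color_j⟩ over the 8 compass neighbours
at Chebyshev distance d (default d = 1, the literal 8-neighbourhood).
Choices that matter:

- **Per-channel tables.** Each of the three channels is counted into its own
  Q×Q table; a merged single-table mode (keyed on value alone) is available
  via `merge_channels`.
- **Border rule.** Out-of-bounds neighbours are skipped, no padding. This
  keeps every count interpretable as a genuine in-image pair; it also means
  the table is only approximately symmetric (the asymmetry is bounded by
  8 × the perimeter pixel count, which the tests assert).
- **Rendering.** Normalized tables are mapped through log(1 + p/ε), ε = 1e−6,
  then min-max scaled to [0, 255] and resized to the network input size.
  Correlogram mass concentrates on the diagonal (neighbouring pixels mostly
  share a quantized color), and linear scaling renders near-black images;
  the log transform is purely cosmetic-numerical and does not enter any
  counting contract.
- Exact invariances at d = 1: horizontal flip and 90° rotation permute the
  8-neighbourhood onto itself, so the table is bit-identical. Tests check
  both, plus equality with a brute-force pairwise counting oracle on small
  images.

## ACRI-LBP (texture path)

Pipeline per gray image (ITU-R BT.601 luma): per-pixel circular LBP code →
minimum over the cyclic-rotation orbit → add the pixel's region
compensation → clip to [0, 255] for rendering (the unclipped float raster
is what the network branch consumes).

- **Sampling.** P = 8 points on a radius-R ring (default R = 3, the radius
  that resolves lesion texture best at 224-pixel scale; R is exposed).
  Coordinates x_p = x_c + R·cos(2πp/P), y_p = y_c − R·sin(2πp/P) with x as
  column and y as row, so p advances counter-clockwise on screen. Fractional
  positions are bilinearly interpolated.
- **Tie rule.** A bit is set when sample ≥ center. Numerically the
  comparison is `sample >= center − 1e−9`: interpolated samples carry ~1e−13
  floating-point noise (weights summing to 1 − ε on constant regions) while
  genuine intensity differences are many orders of magnitude larger, so the
  tolerance recovers the exact-arithmetic tie rule. The per-pixel oracle in
  the tests applies the same documented rule.
- **Rotation invariance.** The minimum over all 8 cyclic bit-rotations. The
  orbit-invariance property is verified exhaustively over all 256 codes ×
  8 shifts, and the number of distinct minima equals the Burnside count of
  8-bit binary necklaces (36).
- **Compensation.** The image is tiled into non-overlapping 16×16 regions
  (edge tiles may be smaller); each region contributes
  Ac = (Ag_min/Ag_max)·Ag with Ag the mean gray, guarded to 0 when
  Ag_max = 0. Compensation is added *after* the minimum-rotation reduction.
  The code raster is invariant under uniform brightness changes (no
  clipping); the compensated raster deliberately is not — Ac scales with
  brightness. Tests assert exactly this split.
- **Borders.** Pixels whose ring does not fit entirely inside the image get
  code 0, producing the dark frame visible in rendered maps.

## Multi-directional attention (MDAM)

- **Shallow mining.** Two 3×3 convolutions with ELU precede the directional
  pooling.
- **Directional profiles.** The four node vectors are equal-weight band
  means: rows (horizontal), columns (vertical), main-diagonal and
  anti-diagonal bands. Each band counts once regardless of its pixel count,
  then pixels share the band's weight uniformly. With equal-sized bands
  (rows, columns) this reduces to the global spatial mean — an inherent
  degeneracy of mean-pooled profiles; the diagonal profiles remain
  informative because diagonal bands differ in size. The construction is the
  cheapest one consistent with "weights in the horizontal, vertical and
  diagonal directions", and it is isolated behind `directional_profiles` so
  alternatives can be swapped.
- **Attention.** GAT-style scoring: e_ij = LeakyReLU(a·[Wh_i ‖ Wh_j])
  (slope 0.2), softmax per node, C_i = Σ_j α_ij h_j. The additive form
  factors as e_ij = s1_i + s2_j. An explicit e-matrix override exists on
  `AttentionParams` for analysis.
- **Secondary weights.** C21 = C_h·C_v − min(C_h, C_v),
  C22 = max(C_h, C_v) + α·min(C_h, C_v), and C23/C24 likewise on the
  diagonal pair. α defaults to 0.3 — small α ignores the weaker direction,
  large α dilutes the dominant one — and must lie strictly in (0, 1).
- **Application to the tensor.** The elementwise max over {C21…C24}
  supplements each primary weight; the eight features are broadcast to
  spatial slabs, concatenated (exactly 8 slabs), projected by a 1×1
  convolution to one map, squashed by a logistic to a (0,1) gate and applied
  as a multiplicative residual F ⊙ gate + F. The residual form reweights
  without ever zeroing information. The supplement-and-gate semantics are
  design choices localized in `MDAM.forward`.

## Network (drnet)

- ResNeXt-50 (32×4d) layout: stem 7×7/2 + 2×2 max pool, stage block counts
  (3, 4, 6, 3), cardinality 32, stage outputs (256, 512, 1024, 2048),
  bottleneck widths (128, 256, 512, 1024). `width_mult` scales all channel
  counts (kept positive multiples of the cardinality); `stage_blocks` and
  `cardinality` are configurable for desk-scale runs. The stem pool is
  2×2/2 rather than an overlapping 3×3/2 — a simplification with no effect
  at the scales this package trains at.
- **No batch normalization.** ELU (α = 1) everywhere keeps deep stacks
  trainable without it; a `relu` config flag exists as the ablation hook.
- Branch inputs are computed on the fly from the raw image (correlogram
  rendering for the color branch, compensated ACRI-LBP raster for the
  texture branch, each scaled to [0, 1]) and memoized by image content;
  augmentation therefore invalidates nothing, since changed pixels simply
  miss the cache.
- **Optimization.** Adam (default lr 1e−4, weight decay 5e−4) with step
  decay ÷10 after epoch 60 and again after epoch 140; SGD with momentum 0.9
  is available. Both the Adam default and the momentum alternative are kept
  because practice reports in this area use either; Adam is the default as
  the more robust choice at small batch sizes.
- Weight init: fan-out-scaled normal, every draw from one Generator seeded
  by the config, so identical configs build bit-identical networks.
- The tensor machinery is a purpose-built reverse-mode autodiff over numpy
  (`autograd.py`): broadcasting arithmetic, grouped conv via sliding-window
  views, max pooling with tie-splitting gradients, fused softmax
  cross-entropy. All primitives are validated against central-difference
  numerical gradients in the test suite.

## Evaluation

Per-class one-vs-rest precision/recall/F1 from the confusion matrix
(rows = actual class). Accuracy is trace/total — the proportion of correctly
classified samples. Macro precision and recall are unweighted class means;
macro-F1 is the harmonic mean *of the two macro averages*, which differs
from the mean of per-class F1 values and is the convention the reported
tables follow. Zero-denominator ratios are reported as 0 with an explicit
flag so macro averages stay defined. Report percentages round half-up to two
decimals. Counting is delegated to scikit-learn's confusion matrix; the
metric arithmetic is authored here and cross-checked against loop oracles.

The ablation harness builds five structural variants from config flags —
bare backbone (raw-image branch), backbone + correlogram branch, backbone +
ACRI-LBP branch, backbone + MDAM, and the full dual-branch model — and
trains/evaluates each with an identical seed and budget, reporting metrics,
parameter counts and wall time per row. A variant that fails to construct is
reported in its row without aborting the run.

## Synthetic data

`fixtures.py` renders parametric leaves: a green blade (narrow HSV band,
soft diagonal illumination, vein lines, mild pixel noise) with lesions drawn
per class — white round spots; gray-centered snake-eye spots with a
purplish-brown ring; yellow-brown V-wedges; reddish-brown 3:1 spindles;
yellow-brown 6:1 strips; purple-brown blotches with a darkened shrivelling
halo. Background color is sampled tightly enough that the classes satisfy
the generator's separability contract (a nearest-mean-color classifier beats
chance), which is the precondition for any training test to be meaningful.
Lesion radii are specified at 224-pixel scale and scaled down with the
canvas, floored at 0.45 so lesions stay visible on small test canvases.

Every image is a pure function of (class spec, size, seed); the per-class
stream mixes a CRC of the class name into the seed. The 3:1:1
train/test/validation split rounds the two small partitions to the nearest
integer (half-up) and gives the remainder to training — the rule that
reproduces both reference splits (17,440 → 10,464/3,488/3,488 and
3,768 → 2,260/754/754).

What the generator does **not** model: leaf geometry and pose, specular
highlights, soil/background clutter, disease progression, co-occurring
diseases, camera noise. Passing tests on these fixtures demonstrates that
the descriptors, attention block, network and metrics behave per contract
and that the architecture can learn color/texture-separable classes; they
say nothing about accuracy on field photographs.

## Desk-scale problem sizes

Training-dependent tests run deliberately small: 48×48 canvases, 32×32
network input, width multiplier 1/16, cardinality 4, one block per stage,
batch 8, Adam at lr 1e−3 (the tiny network tolerates — and needs — a larger
step than the paper-scale default), 10 epochs on 70 images with 35 held out.
Held-out accuracy is compared against the 1/7 chance rate with a one-sided
binomial test. The ablation harness runs at width multiplier 0.25 with
construction-only budgets. Full-width 224-pixel configurations construct and
run but are not exercised in the test suite.

## Known limitations

- The numpy engine is single-threaded and desk-scale; paper-scale training
  (200 epochs, 17k images, 224×224) is out of its intended range.
- Directional profiles collapse horizontal and vertical information under
  uniform band sizes (see above); the attention block still trains because
  the gate projection and mining convolutions carry the burden.
- The correlogram render discards pair identity through min-max scaling; two
  images with proportional tables render identically by design.
- `Ac` compensation assumes 8-bit-range gray input; float images far outside
  [0, 255] render clipped (the unclipped raster is retained).
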