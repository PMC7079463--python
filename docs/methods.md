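# Methods

## Problem and model

The package segments wheat spikes (the grain-bearing ears) from side-view
RGB images of single potted plants on a uniform background, then counts
them.  Segmentation is pixel-wise binary classification carried out in two
stages:

1. **LPNet** operates on overlapping square patches so that local texture
   and context dominate the decision.  Its layer plan is three encoder
   blocks (each: two 3×3 convolutions with padding 1, each followed by ReLU
   then batch normalization; then 2×2 max-pool, stride 2) at widths 16, 64,
   128; a bottleneck of three hourglasses; and three decoder blocks
   mirroring the encoder at widths 128, 64, 16, each fed by a 3×3 stride-2
   transpose convolution and a channel concatenation with the matching
   pre-pool encoder feature map.  A 3×3 convolution to one channel with a
   sigmoid yields spike probabilities.
2. **GMRNet** refines the reassembled full-image probability map at global
   scale.  It is the same chassis with an empty bottleneck and a
   single-channel input (the merged map resized to the patch resolution).

Each hourglass preserves its input shape (`32×32×128` at default scale):
four residual modules down with 2×2 max-pooling between the first three,
four up with nearest-neighbour upsampling, and three long skip branches,
each passing through its own residual module before element-wise addition.
A residual module is 1×1 (reduce, width 128) → 3×3 (width 128) → 1×1
(expand, width 256) with an identity skip, or a 1×1 projection when the
channel counts differ; a final 1×1 projection returns the hourglass output
to 128 channels.  Between hourglasses one nearest-neighbour ×2 scale-up and
one 2×2 max-pool scale-down let the bottleneck relate features at two
scales.

Counting is connected-component labeling (flood fill) on the refined
binary mask; the per-plant count is the maximum over the three side views
(0°, 120°, 240°), since any single view may hide spikes behind foliage.

## Design choices where the design was open

- **Tile stride.**  "Overlapping patches" is realized as stride 100 at
  patch 256, the only reading that produces 15×12 = 180 tiles for a
  1656×1356 image.  When the stride does not land on the image edge, one
  final clamped tile is appended flush with the edge.
- **Overlap merging.**  Overlapping per-pixel probabilities are combined
  by arithmetic mean: deterministic, order-independent, and seam-free.
  Maximum is available as an option.
- **Transpose convolutions** use stride 2, padding 1, output padding 1 —
  the only setting that doubles 32→64 as the decoder tables require.
- **Output head** is a one-channel sigmoid; a softmax over a single
  channel is degenerate, and a two-channel softmax is mathematically
  identical to this head.
- **GMRNet training data.**  Inputs are the *continuous* merged
  probability maps of the trained stage-1 network, resized bilinearly;
  targets are ground-truth masks resized by nearest neighbour.
  Thresholding before refinement would discard calibration information,
  and letting ground truth leak into stage-2 inputs would make refinement
  trivial at train time and impossible at test time.
- **End-to-end fine-tuning** (optional, off by default): the merge is
  linear, so its adjoint distributes gradients over covering tiles divided
  by coverage; the resize is separable bilinear interpolation with a
  transposed-matrix adjoint.  One scene per optimization step.
- **Binarization** uses threshold 0.5 with ties counted as spike, applied
  only after refinement.
- **Counting defaults**: 8-connectivity (the common particle-analysis
  default); a `min_area` filter exists because refined low-resolution
  masks can carry single-pixel speckle (the end-to-end protocol uses
  `min_area=3`); no other size or shape filters.
- **Metric conventions**: E1 = (FP+FN)/total (the overall
  misclassification rate, consistent with wrong-pixel counts like
  105/65 536); E2 = ½(FPR+FNR).  When a confusion has no predicted (or no
  actual) positives, precision (recall) is 1.0 if the other side is empty
  too, else 0.0.  Dataset metrics are means of per-image metrics, not
  pooled confusions.  Implied wrong-pixel counts round to nearest.

## Training procedure

Splits are by plant — all three views travel together — with
|train| = ⌊0.85·n⌋.  Both stages use Adam (reference setting: learning
rate 5·10⁻⁴, batch 32, 200 epochs) minimizing unweighted pixel-wise binary
cross-entropy with probabilities clipped to [10⁻⁷, 1−10⁻⁷].  Stage 1
trains LPNet on image/mask tiles; stage 2 builds one merged map per
training image from the trained LPNet and fits GMRNet on
(merged map → resized mask) pairs.  Weight initialization is He-normal,
reproducible from a seed; shuffling is the only other randomness, so runs
are bit-for-bit repeatable.

All arithmetic is float64 numpy; convolutions are im2col matrix products,
their backward passes the exact adjoints (verified against central finite
differences in the test suite).

## Synthetic scenes

The generator emulates the structure the method needs, not photorealism:
a uniform light-grey background (intensity 205, additive Gaussian noise),
a green stem with Bézier-curved leaves, and spikes as rotated ellipses in
golden/khaki tones with sinusoidal banding along the major axis (a
spikelet-like texture) plus multiplicative roughness.  Spike centers are
rejection-sampled to be pairwise separated unless a configurable
`overlap_probability` deliberately places touching spikes; the mask marks
exactly the spike pixels, so with no overlap the mask has exactly
`n_spikes` 8-connected components.  Three views of a plant share the true
total; one randomly chosen view renders all spikes and the others show
each spike with probability 0.85, so the per-view maximum equals the
total.  Gamma re-illumination uses out = 255·(in/255)^(1/γ): γ<1 darkens,
γ>1 brightens, with levels 0.1–2.5.

What the scenes do **not** model: awn/spikelet geometry, leaf occlusion of
spikes within a view, perspective, shadows, soil/pot clutter, or the color
ambiguity of senescent leaves — so passing tests demonstrate that the
pipeline's mechanics and optimization work, not field-grade robustness.

Note on gamma quantization: strong darkening (γ well below 1) collapses
many dark 8-bit codes onto one, so the γ → 1/γ round trip is exactly
invertible only when at most one quantization step is applied (the
generator exposes `quantize=False` for this); brightening round trips
survive double quantization within ±2 levels.

## Scaled-down study sizes

The end-to-end protocol (`spikeseg.benchmark`) runs the whole method at
CPU scale: 160×128 scenes with 4 spikes (major semi-axis 11–16 px), 64-px
patches at stride 48 (9 tiles/scene), widths (4, 8, 16); 13 training
plants (39 scenes, 351 tiles) and 8 held-out plants; LPNet 20 epochs at
learning rate 2·10⁻³, GMRNet 30 epochs at 5·10⁻³ (stage 2 needs the larger
rate to converge within its short schedule), batch 16.  Held-out refined
masks are scored against nearest-resized ground truth at 64×64, and
counting uses the three-view max rule with `min_area=3`.

## Limitations

- Touching or overlapping spikes merge into one flood-fill object and are
  undercounted; no watershed-style splitting is attempted, by design.
- Counting happens at the refinement resolution, so object areas are in
  resized-pixel units and very thin spikes can vanish in the resize.
- The numpy engine is single-threaded BLAS-bound; reference-scale
  (256-px, widths 16/64/128, 200-epoch) training is out of its intended
  range, which is correctness, reproducibility and CPU-scale studies.
- Batch-norm inference uses running statistics accumulated during
  training; with very few training steps those statistics are noisy.
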