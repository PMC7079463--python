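# spikeseg

Segmentation and counting of wheat spikes (ears) in single-plant RGB
images, built for non-destructive phenotyping: spike number per plant is a
key yield component, and counting it by eye across hundreds of plants is
slow.  The package implements a two-stage convolutional encoder–decoder
pipeline plus flood-fill particle counting, with a synthetic scene
generator so that every stage is trainable and testable without any imaging
hardware or downloads.

## Method

**Stage 1 — local patch network (LPNet).**  A plant image is tiled into
overlapping `256×256` patches (stride 100; a `1656×1356` image yields
`15×12 = 180` tiles).  Each patch passes through three encoder blocks (two
3×3 conv → ReLU → batch-norm stages, widths 16/64/128, 2×2 max-pool), a
bottleneck of three stacked hourglasses at `32×32×128` (each a symmetric
tower of 1×1→3×3→1×1 residual modules with long skip additions, with one
scale-up and one scale-down between hourglasses), and a mirrored decoder
(stride-2 transpose convolutions, skip concatenations from the encoder,
widths 128/64/16) ending in a 3×3 sigmoid head.  Per-patch spike
probabilities are averaged over tile overlaps into a full-size merged map.

**Stage 2 — global mask refinement network (GMRNet).**  The merged map is
resized to `256×256` and refined by a second network with the identical
encoder/decoder but no hourglass bottleneck, trained on the *outputs* of
stage 1 (never on ground truth inputs).  Thresholding at 0.5 gives the
refined binary mask.

**Counting.**  Connected foreground components of the refined mask
(flood fill, 8-connectivity by default) are the detected spikes; touching
spikes merge into one object, the method's known undercount mode.  Because
no single side view shows every spike, a plant is photographed at 0°, 120°
and 240° and its count is the **maximum** of the three per-view counts.

**Metrics.**  Pixel level: precision, recall, accuracy,
F1 = 2PR/(P+R), Jaccard index JI = TP/(TP+FP+FN), overall error
E1 = (FP+FN)/total and class-balanced error E2 = (FPR+FNR)/2.  Object
level: the same formulas with TN ≡ 0, so accuracy = TP/(TP+FP+FN).

Both networks, including convolution/transpose-convolution arithmetic,
batch normalization, Adam, and backpropagation, are implemented in numpy
inside `spikeseg.nn`.

## Worked example

```python
from spikeseg.synthetic import small_scene_config, generate_plant_views
from spikeseg.counting import count_spikes_plant

cfg = small_scene_config()                       # 160x128 scenes, 4 spikes
views = generate_plant_views(cfg, seed=42, plant_id="demo")
print("plant total:", views[0].plant_total)
print("visible per view:", {v.view_angle: v.true_count for v in views})
result = count_spikes_plant([v.mask for v in views])
print("per-view particle counts:", result.per_view_counts)
print("final count (max rule):", result.final_count)
```

prints

```
plant total: 4
visible per view: {0: 4, 120: 3, 240: 4}
per-view particle counts: {0: 4, 120: 3, 240: 4}
final count (max rule): 4
```

The middle view misses one spike, but the max rule over the three views
recovers the true total — exactly the structure the counting stage relies
on.  The full pipeline is available either as a scikit-learn style
estimator,

```python
from spikeseg import SpikeSegNet
est = SpikeSegNet(patch_size=64, step=48, base_widths=(4, 8, 16),
                  lpnet_epochs=20, gmrnet_epochs=30, random_state=0)
est.fit(train_scenes)                  # scenes with paired masks
masks = est.predict([s.image for s in test_scenes])
count = est.count([v.image for v in views])
```

or through the CLI (`spikeseg synth / train-lpnet / train-gmrnet / segment /
count / evaluate / illuminate`), which writes PNG masks with the on-disk
polarity 0 = spike, 255 = background.

## Layout

- `spikeseg.synthetic` — scene generator, three-view plants, gamma
  re-illumination
- `spikeseg.patchwork` — overlapping tile grids, extraction, merging
- `spikeseg.nn` / `spikeseg.architecture` — network engine, declarative
  specs, shape tracing, parameter counting, checkpoints
- `spikeseg.training` — splits, BCE loss, multi-stage training
- `spikeseg.inference` — full-image segmentation pipeline
- `spikeseg.counting` — particle analysis and the three-view count
- `spikeseg.evaluation` — pixel/object metrics, error overlays
- `spikeseg.model` — the `SpikeSegNet` estimator
- `spikeseg.benchmark` — the scaled-down end-to-end study protocol

See `docs/methods.md` for modelling assumptions, parameter choices, and
known limitations.
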