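"""Data splitting, the pixel-wise binary cross-entropy loss, and the
multi-stage training procedure.

Stage 1 trains the local-patch network on overlapping image/mask tile
pairs.  Stage 2 freezes it, reassembles its per-tile predictions into
merged full-size probability maps, resizes those (bilinear) and the
ground-truth masks (nearest) to the refinement input size, and trains the
refinement network on the resulting pairs - so the second network sees
exactly what it will see at inference time, never the ground truth.  An
optional third stage fine-tunes both networks jointly, realizing the merge
as differentiable averaging and the resize as separable bilinear
interpolation; it is off by default.

Splits are by plant (all three views travel together), 85% training by
default, floor rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .architecture import (
    DEFAULT_WIDTHS,
    build_network,
    gmrnet_spec,
    lpnet_spec,
)
from .inference import resize_map
from .nn.optim import Adam
from .patchwork import extract_patches, merge_patches, plan_grid


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 5e-4
    epochs: int = 200
    batch_size: int = 32
    loss: str = "binary_cross_entropy"
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "binary_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class SplitSpec:
    train_fraction: float = 0.85
    seed: int = 0


@dataclass
class TrainHistory:
    losses: List[float] = field(default_factory=list)

    def __len__(self):
        return len(self.losses)


def split_dataset(plant_ids: Sequence, spec: SplitSpec) -> Tuple[list, list]:
    """Disjoint, exhaustive train/validation split *by plant*; |train| =
    floor(train_fraction * n); deterministic per seed."""
    ids = list(plant_ids)
    n = len(ids)
    if n < 2:
        raise ValueError(f"need at least 2 plants to split, got {n}")
    perm = np.random.default_rng(spec.seed).permutation(n)
    k = math.floor(spec.train_fraction * n)
    return [ids[i] for i in perm[:k]], [ids[i] for i in perm[k:]]


def bce_loss(predicted: np.ndarray, target: np.ndarray,
             eps: float = 1e-7) -> float:
    """Mean over all pixels of -[t log p + (1-t) log(1-p)], with p clipped
    to [eps, 1-eps]; every pixel contributes uniformly."""
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {target.shape}")
    p = np.clip(predicted, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1 - target) * np.log1p(-p)))


def bce_grad(predicted: np.ndarray, target: np.ndarray,
             eps: float = 1e-7) -> np.ndarray:
    """Gradient of :func:`bce_loss` w.r.t. the predicted probabilities."""
    p = np.clip(np.asarray(predicted, dtype=float), eps, 1.0 - eps)
    t = np.asarray(target, dtype=float)
    return (p - t) / (p * (1.0 - p)) / p.size


def train_network(model, inputs: np.ndarray, targets: np.ndarray,
                  config: TrainConfig) -> TrainHistory:
    """Mini-batch Adam training; per-epoch mean loss is recorded.

    Fully deterministic for a fixed config seed (shuffling is the only
    randomness; all arithmetic is numpy float64).
    """
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(inputs) == 0:
        raise ValueError("empty training dataset")
    if len(inputs) != len(targets):
        raise ValueError("inputs and targets differ in length")
    history = TrainHistory()
    if config.epochs == 0:
        return history
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(inputs)
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, tb = inputs[idx], targets[idx]
            pb = model.forward(xb, train=True)
            loss = bce_loss(pb, tb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"loss became non-finite ({loss}) at epoch "
                    f"{len(history) + 1}; lower the learning rate")
            epoch_loss += loss * len(idx)
            opt.zero_grad()
            model.backward(bce_grad(pb, tb))
            opt.step()
        history.losses.append(epoch_loss / n)
    return history


def _scene_arrays(sample):
    image = getattr(sample, "image", None)
    mask = getattr(sample, "mask", None)
    if image is None:
        image, mask = sample  # plain (image, mask) pair
    return np.asarray(image), np.asarray(mask)


def build_patch_dataset(samples, patch_size: int, step: int
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Stack image and mask tiles from scenes into training arrays."""
    xs, ys = [], []
    for sample in samples:
        image, mask = _scene_arrays(sample)
        grid = plan_grid(image.shape[0], image.shape[1], patch_size, step)
        xs.append(extract_patches(image, grid).astype(float) / 255.0)
        ys.append(extract_patches(mask, grid).astype(float))
    x = np.concatenate(xs).transpose(0, 3, 1, 2)
    y = np.concatenate(ys)[:, None]
    return x, y


def build_refinement_dataset(samples, lpnet, patch_size: int, step: int,
                             batch_size: int = 32
                             ) -> Tuple[np.ndarray, np.ndarray]:
    """Stage-2 pairs: merged probability maps (bilinear-resized) as inputs,
    nearest-resized ground-truth masks as targets."""
    from .inference import lpnet_probabilities

    size = patch_size
    xs, ys = [], []
    for sample in samples:
        image, mask = _scene_arrays(sample)
        grid = plan_grid(image.shape[0], image.shape[1], patch_size, step)
        merged = lpnet_probabilities(image, lpnet, grid, batch_size)
        xs.append(resize_map(merged, size, size, mode="bilinear"))
        ys.append(resize_map(mask.astype(float), size, size, mode="nearest"))
    return np.stack(xs)[:, None], np.stack(ys)[:, None]


def multistage_train(samples, lpnet_config: TrainConfig,
                     gmrnet_config: TrainConfig, patch_size: int = 256,
                     step: int = 100, base_widths=DEFAULT_WIDTHS,
                     end_to_end: bool = False,
                     end_to_end_config: TrainConfig = None):
    """Train the local-patch network, then the refinement network on its
    merged outputs; optionally fine-tune jointly.

    Returns ``(lpnet, gmrnet, lpnet_history, gmrnet_history)``.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no training scenes supplied")
    x1, y1 = build_patch_dataset(samples, patch_size, step)
    lpnet = build_network(lpnet_spec(base_widths, patch_size, 3),
                          seed=lpnet_config.seed)
    hist_lp = train_network(lpnet, x1, y1, lpnet_config)
    x2, y2 = build_refinement_dataset(samples, lpnet, patch_size, step,
                                      gmrnet_config.batch_size)
    gmrnet = build_network(gmrnet_spec(base_widths, patch_size, 1),
                           seed=gmrnet_config.seed)
    hist_gmr = train_network(gmrnet, x2, y2, gmrnet_config)
    if end_to_end:
        cfg = end_to_end_config or TrainConfig(
            learning_rate=lpnet_config.learning_rate / 5, epochs=2,
            batch_size=1, seed=lpnet_config.seed)
        finetune_end_to_end(lpnet, gmrnet, samples, cfg, patch_size, step)
    return lpnet, gmrnet, hist_lp, hist_gmr


def _bilinear_matrix(n_src: int, n_dst: int) -> np.ndarray:
    """Separable bilinear interpolation weights (half-pixel centers)."""
    w = np.zeros((n_dst, n_src))
    scale = n_src / n_dst
    for i in range(n_dst):
        pos = (i + 0.5) * scale - 0.5
        lo = int(np.floor(pos))
        frac = pos - lo
        lo_c = min(max(lo, 0), n_src - 1)
        hi_c = min(max(lo + 1, 0), n_src - 1)
        w[i, lo_c] += 1.0 - frac
        w[i, hi_c] += frac
    return w


def finetune_end_to_end(lpnet, gmrnet, samples, config: TrainConfig,
                        patch_size: int, step: int) -> TrainHistory:
    """Joint fine-tuning across the merge/resize boundary.

    The merge is differentiable averaging (gradients distribute over the
    tiles covering each pixel, divided by coverage) and the resize is
    separable bilinear interpolation, whose adjoint is the transposed
    weight matrices.  One scene per optimization step.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no scenes supplied")
    image0, _ = _scene_arrays(samples[0])
    grid = plan_grid(image0.shape[0], image0.shape[1], patch_size, step)
    size = gmrnet.spec.input_shape.height
    wr = _bilinear_matrix(grid.image_height, size)
    wc = _bilinear_matrix(grid.image_width, size)
    from .patchwork import coverage_map

    cov = coverage_map(grid)
    opt = Adam(lpnet.params() + gmrnet.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    p = patch_size
    targets = [
        resize_map(_scene_arrays(s)[1].astype(float), size, size, "nearest")
        for s in samples
    ]
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for si in rng.permutation(len(samples)):
            image, _ = _scene_arrays(samples[si])
            x = extract_patches(image, grid).astype(float) / 255.0
            probs = lpnet.forward(x.transpose(0, 3, 1, 2), train=True)[:, 0]
            merged = merge_patches(probs, grid)
            resized = wr @ merged @ wc.T
            pred = gmrnet.forward(resized[None, None], train=True)
            loss = bce_loss(pred[0, 0], targets[si])
            if not np.isfinite(loss):
                raise RuntimeError("joint fine-tune loss became non-finite")
            epoch_loss += loss
            opt.zero_grad()
            dresized = gmrnet.backward(
                bce_grad(pred, targets[si][None, None]))[0, 0]
            dmerged = (wr.T @ dresized @ wc) / cov
            dprobs = np.stack([dmerged[r:r + p, c:c + p]
                               for r, c in grid.tiles()])
            lpnet.backward(dprobs[:, None])
            opt.step()
        history.losses.append(epoch_loss / len(samples))
    return history
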