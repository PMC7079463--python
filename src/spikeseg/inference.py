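"""End-to-end segmentation of a full plant image into a refined mask.

Pipeline: plan the overlapping tile grid, run the local-patch network on
every tile, average the overlapping probabilities into a full-size merged
map, resize it (bilinear) to the refinement network's input size, refine,
and threshold.  The refined mask lives at the refinement resolution (256 x
256 at default scale); counting operates on it directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .patchwork import PatchGrid, extract_patches, merge_patches, plan_grid


@dataclass
class SegmentationResult:
    merged_map: np.ndarray    # full image size, probabilities in [0, 1]
    refined_map: np.ndarray   # refinement-resolution probabilities
    refined_mask: np.ndarray  # refined_map thresholded, {0, 1}
    grid: PatchGrid


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 where probability >= threshold, else 0 (ties count as spike)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


def resize_map(prob_map: np.ndarray, out_height: int, out_width: int,
               mode: str = "bilinear") -> np.ndarray:
    """Anisotropic resize (aspect ratio is not preserved); bilinear for
    probability maps, nearest for binary masks."""
    if out_height < 1 or out_width < 1:
        raise ValueError("target dims must be positive")
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.shape[:2] == (out_height, out_width):
        return prob_map.copy()
    order = {"bilinear": 1, "nearest": 0}.get(mode)
    if order is None:
        raise ValueError(f"unknown resize mode {mode!r}")
    return _sk_resize(prob_map, (out_height, out_width), order=order,
                      preserve_range=True, anti_aliasing=False)


def lpnet_probabilities(image: np.ndarray, lpnet, grid: PatchGrid,
                        batch_size: int = 32) -> np.ndarray:
    """Merged full-size spike-probability map from per-tile predictions."""
    patches = extract_patches(image, grid).astype(float) / 255.0
    x = patches.transpose(0, 3, 1, 2)
    probs = lpnet.predict(x, batch_size=batch_size)[:, 0]
    return merge_patches(probs, grid)


def segment_image(image: np.ndarray, lpnet, gmrnet, patch_size: int = None,
                  step: int = 100, threshold: float = 0.5,
                  batch_size: int = 32) -> SegmentationResult:
    """Full pipeline: tiles -> local-patch net -> merge -> resize -> refine
    -> threshold.  Deterministic for fixed weights and input."""
    if patch_size is None:
        patch_size = lpnet.spec.input_shape.height
    grid = plan_grid(image.shape[0], image.shape[1], patch_size, step)
    merged = lpnet_probabilities(image, lpnet, grid, batch_size)
    size = gmrnet.spec.input_shape.height
    resized = resize_map(merged, size, size, mode="bilinear")
    refined = gmrnet.predict(resized[None, None])[0, 0]
    return SegmentationResult(
        merged_map=merged,
        refined_map=refined,
        refined_mask=binarize(refined, threshold),
        grid=grid,
    )
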