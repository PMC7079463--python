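"""Overlapping-tile grids: planning, extraction, and probability merging.

Full plant images are segmented tile-by-tile: a regular grid of
``patch_size`` x ``patch_size`` tiles advances by ``step`` pixels (step <
patch size, so tiles overlap), with one final clamped offset whenever the
stride does not land exactly on the image edge.  At the reference scale
(1656x1356 image, 256-px patches, 100-px step) this yields the 15 x 12 =
180 tiles the method trains on.  Overlapping per-pixel probabilities are
reconciled by arithmetic mean (or maximum, if requested).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np


def _offsets(dim: int, patch_size: int, step: int, axis_name: str) -> List[int]:
    if dim < patch_size:
        raise ValueError(
            f"image {axis_name} ({dim}) is smaller than the patch size ({patch_size})")
    offs = list(range(0, dim - patch_size + 1, step))
    if offs[-1] != dim - patch_size:
        offs.append(dim - patch_size)  # clamped final tile flush with the edge
    return offs


@dataclass(frozen=True)
class PatchGrid:
    image_height: int
    image_width: int
    patch_size: int
    step: int
    row_offsets: tuple
    col_offsets: tuple

    @property
    def n_tiles(self) -> int:
        return len(self.row_offsets) * len(self.col_offsets)

    def tiles(self):
        """Row-major (top, left) corner coordinates."""
        for r in self.row_offsets:
            for c in self.col_offsets:
                yield r, c


def plan_grid(height: int, width: int, patch_size: int = 256,
              step: int = 100) -> PatchGrid:
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    rows = _offsets(height, patch_size, step, "height")
    cols = _offsets(width, patch_size, step, "width")
    return PatchGrid(height, width, patch_size, step, tuple(rows), tuple(cols))


def extract_patches(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Row-major stack of tiles; shape (n_tiles, patch, patch[, channels])."""
    if image.shape[:2] != (grid.image_height, grid.image_width):
        raise ValueError(
            f"image dims {image.shape[:2]} do not match grid "
            f"({grid.image_height}, {grid.image_width})")
    p = grid.patch_size
    return np.stack([image[r:r + p, c:c + p] for r, c in grid.tiles()])


def merge_patches(patch_maps: Sequence[np.ndarray], grid: PatchGrid,
                  reduce: str = "mean") -> np.ndarray:
    """Reassemble per-tile probability maps into a full-size map.

    Each output pixel is the arithmetic mean (default) or maximum of all
    tile values covering it; values stay in [0, 1].
    """
    patch_maps = np.asarray(patch_maps, dtype=float)
    if len(patch_maps) != grid.n_tiles:
        raise ValueError(
            f"got {len(patch_maps)} patch maps for a {grid.n_tiles}-tile grid")
    if reduce not in ("mean", "max"):
        raise ValueError(f"unknown overlap reduction {reduce!r}")
    p = grid.patch_size
    out_shape = (grid.image_height, grid.image_width) + patch_maps.shape[3:]
    if reduce == "max":
        out = np.full(out_shape, -np.inf)
        for (r, c), pm in zip(grid.tiles(), patch_maps):
            np.maximum(out[r:r + p, c:c + p], pm, out=out[r:r + p, c:c + p])
        return out
    acc = np.zeros(out_shape)
    cov = np.zeros((grid.image_height, grid.image_width))
    for (r, c), pm in zip(grid.tiles(), patch_maps):
        acc[r:r + p, c:c + p] += pm
        cov[r:r + p, c:c + p] += 1.0
    if acc.ndim > 2:
        cov = cov[..., None]
    return acc / cov


def coverage_map(grid: PatchGrid) -> np.ndarray:
    """Number of tiles covering each pixel (always >= 1 for a valid grid)."""
    cov = np.zeros((grid.image_height, grid.image_width))
    p = grid.patch_size
    for r, c in grid.tiles():
        cov[r:r + p, c:c + p] += 1.0
    return cov
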