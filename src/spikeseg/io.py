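"""PNG image/mask file handling with the on-disk mask polarity convention.

Masks on disk are 8-bit PNGs where black (0) marks spike pixels and white
(255) everything else; in memory masks are {0, 1} arrays with 1 = spike.
Reading is tolerant (luminance threshold at 128, so near-binary hand-made
masks load cleanly); a strict mode rejects anything but pure 0/255 files.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

#: luminance weights used to collapse RGB mask files
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path) -> np.ndarray:
    """Read an RGB image as (H, W, 3) uint8."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return img.astype(np.uint8)


def write_image(image: np.ndarray, path) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path, strict: bool = False) -> np.ndarray:
    """Read a mask PNG into a {0, 1} array with 1 = spike (dark on disk)."""
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., :3] @ _LUMA
    if strict and not np.isin(np.unique(raw), (0, 255)).all():
        raise ValueError(f"{path}: not a strictly binary mask file")
    return (raw < 128).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0, 1} mask as an 8-bit PNG, 0 where spike, 255 elsewhere."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    iio.imwrite(path, np.where(mask > 0, 0, 255).astype(np.uint8))
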