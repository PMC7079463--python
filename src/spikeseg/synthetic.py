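"""Synthetic single-plant scenes with known spike masks and counts.

Each scene emulates the imaging situation the method targets: one wheat-like
plant on a uniform light background, photographed from the side.  Spikes are
drawn as textured golden/khaki elliptical blobs (banded along their major
axis to suggest spikelets), the stem and leaves as green strokes, so a
learnable color/texture signal separates foreground from the rest.  The
ground-truth mask marks exactly the spike pixels and, when spikes are placed
without overlap, has exactly ``n_spikes`` connected components.

Three side views per plant (0, 120, 240 degrees) are generated such that a
view may miss some spikes but the maximum per-view visible count equals the
plant total - the structure the three-view counting rule exploits.

Gamma re-illumination (``out = 255 * (in/255)**(1/gamma)``) produces darker
(gamma < 1) to brighter (gamma > 1) variants for robustness protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from skimage.draw import disk, ellipse


class ConfigError(ValueError):
    """Scene configuration cannot be realized (e.g. spikes do not fit)."""


@dataclass
class SceneConfig:
    image_height: int = 1656
    image_width: int = 1356
    n_spikes: int = 6
    spike_axis_range: Tuple[int, int] = (40, 80)  # major semi-axis, px
    overlap_probability: float = 0.0
    n_leaves: int = 5
    background_intensity: int = 205
    noise_sd: float = 3.0
    seed: int = 0
    spike_rgb: Tuple[int, int, int] = (185, 157, 82)   # golden/khaki
    plant_rgb: Tuple[int, int, int] = (62, 128, 52)    # stem/leaf green
    minor_ratio: Tuple[float, float] = (0.30, 0.48)
    view_visibility: float = 0.85

    def __post_init__(self):
        if self.image_height < 8 or self.image_width < 8:
            raise ConfigError("image dims must be at least 8x8")
        if self.n_spikes < 0:
            raise ConfigError("n_spikes must be >= 0")
        if not 0.0 <= self.overlap_probability <= 1.0:
            raise ConfigError("overlap_probability must be in [0, 1]")
        lo, hi = self.spike_axis_range
        if not 1 <= lo <= hi:
            raise ConfigError("spike_axis_range must satisfy 1 <= min <= max")
        margin = hi + 2
        if self.n_spikes > 0 and (
                int(0.55 * self.image_height) <= margin
                or self.image_width - margin <= margin):
            raise ConfigError(
                f"image dims {self.image_height}x{self.image_width} too small "
                f"for spikes with major semi-axis up to {hi}")


@dataclass
class GammaLevel:
    gamma: float

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


#: Re-illumination levels of the robustness protocol, darker to brighter.
GAMMA_LEVELS = (0.1, 0.3, 0.5, 1.5, 2.0, 2.5)


@dataclass
class SceneSample:
    image: np.ndarray                  # (H, W, 3) uint8
    mask: np.ndarray                   # (H, W) uint8, 1 = spike
    true_count: int                    # spikes rendered in this view
    spike_centroids: List[Tuple[int, int]]
    view_angle: int = 0                # degrees, one of {0, 120, 240}
    plant_id: str = ""
    plant_total: Optional[int] = None  # spikes on the whole plant
    plant_mask: Optional[np.ndarray] = None  # stem+leaf pixels (uint8)


def small_scene_config(**overrides) -> SceneConfig:
    """CPU-scale preset: 160x128 scenes sized for 64-px patches (step 48)."""
    base = dict(
        image_height=160, image_width=128, n_spikes=4,
        spike_axis_range=(11, 16), n_leaves=4, noise_sd=2.0,
    )
    base.update(overrides)
    return SceneConfig(**base)


def _stamp_disks(img, plant, rows, cols, radius, color, rng):
    h, w = plant.shape
    for r, c in zip(rows, cols):
        rr, cc = disk((r, c), radius, shape=(h, w))
        shade = 1.0 + rng.normal(0.0, 0.08)
        img[rr, cc] = np.clip(np.asarray(color, float) * shade, 0, 255)
        plant[rr, cc] = 1


def _draw_plant(img, plant, cfg: SceneConfig, rng) -> None:
    h, w = plant.shape
    cx = w / 2 + rng.uniform(-w / 10, w / 10)
    r_top = int(0.22 * h)
    stem_r = max(1, round(min(h, w) / 60))
    amp = w / 40
    phase = rng.uniform(0, 2 * np.pi)
    rows = np.arange(h - 1, r_top, -1)
    cols = cx + amp * np.sin(2 * np.pi * rows / h * 1.3 + phase)
    _stamp_disks(img, plant, rows, np.clip(cols, 1, w - 2), stem_r,
                 cfg.plant_rgb, rng)
    stem_col = {int(r): float(c) for r, c in zip(rows, cols)}
    for _ in range(cfg.n_leaves):
        r0 = int(rng.uniform(0.45, 0.92) * h)
        c0 = stem_col.get(r0, cx)
        side = rng.choice((-1.0, 1.0))
        c2 = np.clip(c0 + side * rng.uniform(0.15, 0.45) * w, 1, w - 2)
        r2 = np.clip(r0 - rng.uniform(0.0, 0.25) * h, 1, h - 2)
        c1 = (c0 + c2) / 2 + side * rng.uniform(0, 0.1) * w
        r1 = min(r0, r2) - rng.uniform(0.02, 0.12) * h
        t = np.linspace(0.0, 1.0, 120)
        rr = (1 - t) ** 2 * r0 + 2 * t * (1 - t) * r1 + t ** 2 * r2
        cc = (1 - t) ** 2 * c0 + 2 * t * (1 - t) * c1 + t ** 2 * c2
        _stamp_disks(img, plant, np.clip(rr, 1, h - 2), np.clip(cc, 1, w - 2),
                     max(1, stem_r - 1), cfg.plant_rgb, rng)


def _place_spikes(cfg: SceneConfig, rng):
    """Choose centers/axes; non-touching unless the overlap draw fires."""
    h, w = cfg.image_height, cfg.image_width
    lo, hi = cfg.spike_axis_range
    margin = hi + 2
    r_lim = (margin, int(0.55 * h))
    c_lim = (margin, w - margin)
    gap = max(3, round(0.25 * lo))
    placed = []  # (r, c, major, minor, angle)
    for k in range(cfg.n_spikes):
        major = rng.uniform(lo, hi)
        minor = major * rng.uniform(*cfg.minor_ratio)
        angle = rng.normal(0.0, 0.25)
        if placed and rng.random() < cfg.overlap_probability:
            j = rng.integers(len(placed))
            rj, cj, aj = placed[j][0], placed[j][1], placed[j][2]
            theta = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(0.4, 0.9) * (aj + major)
            r = float(np.clip(rj + d * np.cos(theta), *r_lim))
            c = float(np.clip(cj + d * np.sin(theta), *c_lim))
            placed.append((r, c, major, minor, angle))
            continue
        ok = False
        for _ in range(4000):
            r = rng.uniform(*r_lim)
            c = rng.uniform(*c_lim)
            if all(np.hypot(r - pr, c - pc) >= major + pa + gap
                   for pr, pc, pa, _, _ in placed):
                ok = True
                break
        if not ok:
            raise ConfigError(
                f"could not place {cfg.n_spikes} non-touching spikes of "
                f"semi-axis up to {hi} on a {h}x{w} canvas")
        placed.append((r, c, major, minor, angle))
    return placed


def _draw_spikes(img, mask, placed, cfg: SceneConfig, rng) -> None:
    h, w = mask.shape
    base = np.asarray(cfg.spike_rgb, float)
    for r0, c0, major, minor, angle in placed:
        rr, cc = ellipse(r0, c0, major, minor, shape=(h, w), rotation=angle)
        mask[rr, cc] = 1
        u = (rr - r0) * np.cos(angle) + (cc - c0) * np.sin(angle)
        period = max(3.0, major / 3.5)
        band = 1.0 + 0.18 * np.sin(2 * np.pi * u / period)
        rough = rng.normal(1.0, 0.06, size=rr.shape)
        shade = (band * rough)[:, None]
        img[rr, cc] = np.clip(base[None, :] * shade, 0, 255)


def generate_scene(config: SceneConfig, seed: Optional[int] = None) -> SceneSample:
    """Render one deterministic scene for (config, seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.image_height, config.image_width
    img = np.full((h, w, 3), float(config.background_intensity))
    plant = np.zeros((h, w), dtype=np.uint8)
    mask = np.zeros((h, w), dtype=np.uint8)
    _draw_plant(img, plant, config, rng)
    placed = _place_spikes(config, rng)
    _draw_spikes(img, mask, placed, config, rng)
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, img.shape)
    plant[mask == 1] = 0  # spikes are drawn on top of foliage
    return SceneSample(
        image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        mask=mask,
        true_count=config.n_spikes,
        spike_centroids=[(int(round(p[0])), int(round(p[1]))) for p in placed],
        plant_mask=plant,
    )


def generate_plant_views(config: SceneConfig, seed: int,
                         plant_id: str = "plant") -> Tuple[SceneSample, ...]:
    """Three side views of one plant sharing a common true total count.

    One randomly chosen view renders every spike; in the other two, each
    spike is visible with probability ``config.view_visibility``.  The
    maximum per-view visible count therefore equals the plant total.
    """
    if config.n_spikes < 1:
        raise ValueError("a plant needs n_spikes >= 1")
    rng = np.random.default_rng(seed)
    full_view = int(rng.integers(3))
    views = []
    for i, angle in enumerate((0, 120, 240)):
        if i == full_view:
            visible = config.n_spikes
        else:
            visible = int(np.sum(rng.random(config.n_spikes) < config.view_visibility))
        view_seed = int(rng.integers(2 ** 31))
        sample = generate_scene(replace(config, n_spikes=visible), seed=view_seed)
        sample.view_angle = angle
        sample.plant_id = plant_id
        sample.true_count = visible
        sample.plant_total = config.n_spikes
        views.append(sample)
    return tuple(views)


def apply_gamma(image: np.ndarray, level, quantize: bool = True) -> np.ndarray:
    """Re-illuminate: out = 255 * (in/255)**(1/gamma), rounded and clipped.

    gamma < 1 darkens, gamma > 1 brightens; gamma = 1 is the identity.
    With ``quantize=False`` the float map is returned unrounded, which keeps
    the operation exactly invertible; note that strong darkening (gamma well
    below 1) is *not* invertible after 8-bit rounding, since many dark
    levels collapse onto the same code.
    """
    gamma = level.gamma if isinstance(level, GammaLevel) else float(level)
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    x = np.asarray(image, dtype=float)
    out = 255.0 * (x / 255.0) ** (1.0 / gamma)
    if not quantize:
        return out
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def write_scene_dataset(plants, out_dir) -> None:
    """Write paired PNGs per view plus a plain-text manifest.

    ``plants`` is an iterable of (views, seed) pairs as produced by
    :func:`generate_plant_views`; files follow the disk convention
    ``<plant>_<angle>.png`` / ``<plant>_<angle>_mask.png`` with mask
    polarity 0 = spike, 255 = background.
    """
    import os

    from .io import write_image, write_mask

    os.makedirs(out_dir, exist_ok=True)
    lines = ["plant_id\tangle\ttrue_count\tplant_total\tseed"]
    for views, seed in plants:
        for v in views:
            stem = f"{v.plant_id}_{v.view_angle:03d}"
            write_image(v.image, os.path.join(out_dir, stem + ".png"))
            write_mask(v.mask, os.path.join(out_dir, stem + "_mask.png"))
            lines.append(f"{v.plant_id}\t{v.view_angle}\t{v.true_count}"
                         f"\t{v.plant_total}\t{seed}")
    with open(os.path.join(out_dir, "manifest.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
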