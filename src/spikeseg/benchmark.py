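"""Scaled-down end-to-end study protocol on synthetic plants.

Runs the whole method at CPU scale: generate three-view plants from the
small preset, train both stages, then measure held-out segmentation quality
(pixel F1 of refined masks against nearest-resized ground truth) and
counting performance (three-view max rule vs the known plant totals).  Both
the test suite and the reproduction script drive this one entry point, so
the protocol is identical everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .counting import count_spikes_plant
from .evaluation import pixel_confusion, segmentation_metrics
from .inference import resize_map, segment_image
from .synthetic import generate_plant_views, small_scene_config
from .training import TrainConfig, TrainHistory, multistage_train

#: CPU-scale protocol settings (scene/tile geometry and training schedule).
SMALL_PROTOCOL = dict(
    patch_size=64,
    step=48,
    base_widths=(4, 8, 16),
    lpnet=dict(learning_rate=2e-3, epochs=20, batch_size=16),
    gmrnet=dict(learning_rate=5e-3, epochs=30, batch_size=16),
    n_train_plants=13,   # 39 training scenes
    n_heldout_plants=8,
    connectivity=8,
    min_area=3,          # suppress single-pixel speckle at the 64x64 scale
)


@dataclass
class BenchmarkResult:
    mean_f1: float
    count_agreement: float          # fraction of held-out plants counted exactly
    n_train_scenes: int
    n_heldout_plants: int
    per_view_f1: List[float] = field(default_factory=list)
    per_plant_counts: List[Dict] = field(default_factory=list)
    lpnet_history: TrainHistory = None
    gmrnet_history: TrainHistory = None
    lpnet: object = None
    gmrnet: object = None
    heldout_plants: list = None


def _derive_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def generate_plant_set(seed: int, n_plants: int, prefix: str = "plant",
                       **config_overrides) -> list:
    """Deterministic list of three-view plants from the small preset."""
    cfg = small_scene_config(**config_overrides)
    rng = np.random.default_rng(seed)
    return [
        generate_plant_views(cfg, int(rng.integers(2 ** 31)), f"{prefix}{i:03d}")
        for i in range(n_plants)
    ]


def run_small_benchmark(seed: int = 0, protocol: dict = None) -> BenchmarkResult:
    proto = dict(SMALL_PROTOCOL)
    if protocol:
        proto.update(protocol)
    scene_seed, holdout_seed, lp_seed, gmr_seed = _derive_seeds(seed, 4)
    train_plants = generate_plant_set(scene_seed, proto["n_train_plants"], "tr")
    heldout_plants = generate_plant_set(holdout_seed, proto["n_heldout_plants"], "ho")
    train_scenes = [v for views in train_plants for v in views]
    lp_cfg = TrainConfig(seed=lp_seed, **proto["lpnet"])
    gmr_cfg = TrainConfig(seed=gmr_seed, **proto["gmrnet"])
    lpnet, gmrnet, hist_lp, hist_gmr = multistage_train(
        train_scenes, lp_cfg, gmr_cfg, patch_size=proto["patch_size"],
        step=proto["step"], base_widths=proto["base_widths"])
    size = proto["patch_size"]
    f1s, plant_counts = [], []
    agree = 0
    for views in heldout_plants:
        masks = []
        for v in views:
            result = segment_image(v.image, lpnet, gmrnet, step=proto["step"])
            truth = resize_map(v.mask.astype(float), size, size,
                               mode="nearest").astype(np.uint8)
            f1s.append(segmentation_metrics(
                pixel_confusion(result.refined_mask, truth)).f1)
            masks.append(result.refined_mask)
        counted = count_spikes_plant(masks, proto["connectivity"],
                                     proto["min_area"])
        total = views[0].plant_total
        agree += int(counted.final_count == total)
        plant_counts.append({"true_total": total,
                             "per_view": counted.per_view_counts,
                             "final": counted.final_count})
    return BenchmarkResult(
        mean_f1=float(np.mean(f1s)),
        count_agreement=agree / len(heldout_plants),
        n_train_scenes=len(train_scenes),
        n_heldout_plants=len(heldout_plants),
        per_view_f1=f1s,
        per_plant_counts=plant_counts,
        lpnet_history=hist_lp,
        gmrnet_history=hist_gmr,
        lpnet=lpnet,
        gmrnet=gmrnet,
        heldout_plants=heldout_plants,
    )
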