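"""Scikit-learn style estimator bundling the full two-stage pipeline.

``SpikeSegNet`` is fit on full scenes with paired spike masks and predicts
refined masks (and spike counts) for new scenes.  It composes with sklearn
model selection (``get_params``/``set_params``/``clone``); the fitted
networks live in trailing-underscore attributes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .architecture import DEFAULT_WIDTHS
from .counting import PlantCountResult, count_spikes_plant
from .evaluation import pixel_confusion, segmentation_metrics
from .inference import SegmentationResult, resize_map, segment_image
from .training import TrainConfig, multistage_train


class SpikeSegNet(BaseEstimator):
    """Two-stage spike segmenter: local-patch network + mask refinement.

    Parameters
    ----------
    patch_size : tile edge in pixels (must be a multiple of 8).
    step : tile stride in pixels; step < patch_size gives overlapping tiles.
    base_widths : encoder channel triple; (16, 64, 128) is the reference
        scale, (4, 8, 16) the CPU-scale variant.
    lpnet_epochs, gmrnet_epochs : training epochs per stage.
    learning_rate, batch_size : Adam settings shared by both stages.
    threshold : probability cut for the refined mask.
    connectivity, min_area : particle-analysis settings used by ``count``.
    end_to_end : run the optional joint fine-tuning stage after stage 2.
    random_state : seed for weight init and batch shuffling.
    """

    def __init__(self, patch_size: int = 256, step: int = 100,
                 base_widths=DEFAULT_WIDTHS, lpnet_epochs: int = 200,
                 gmrnet_epochs: int = 200, learning_rate: float = 5e-4,
                 batch_size: int = 32, threshold: float = 0.5,
                 connectivity: int = 8, min_area: int = 0,
                 end_to_end: bool = False, random_state: int = 0):
        self.patch_size = patch_size
        self.step = step
        self.base_widths = base_widths
        self.lpnet_epochs = lpnet_epochs
        self.gmrnet_epochs = gmrnet_epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.threshold = threshold
        self.connectivity = connectivity
        self.min_area = min_area
        self.end_to_end = end_to_end
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _as_scenes(self, X, y):
        if y is None:
            return list(X)
        return list(zip(X, y))

    def fit(self, X: Sequence, y: Optional[Sequence] = None) -> "SpikeSegNet":
        """Fit on scenes: X is a sequence of scene samples (image+mask), or
        a sequence of RGB images with y the matching binary masks."""
        scenes = self._as_scenes(X, y)
        ss = np.random.SeedSequence(self.random_state)
        seed_lp, seed_gmr = (int(s.generate_state(1)[0] % (2 ** 31))
                             for s in ss.spawn(2))
        lp_cfg = TrainConfig(learning_rate=self.learning_rate,
                             epochs=self.lpnet_epochs,
                             batch_size=self.batch_size, seed=seed_lp,
                             threshold=self.threshold)
        gmr_cfg = TrainConfig(learning_rate=self.learning_rate,
                              epochs=self.gmrnet_epochs,
                              batch_size=self.batch_size, seed=seed_gmr,
                              threshold=self.threshold)
        self.lpnet_, self.gmrnet_, self.lpnet_history_, self.gmrnet_history_ = \
            multistage_train(scenes, lp_cfg, gmr_cfg,
                             patch_size=self.patch_size, step=self.step,
                             base_widths=tuple(self.base_widths),
                             end_to_end=self.end_to_end)
        return self

    def _check_fitted(self):
        if not hasattr(self, "lpnet_"):
            raise NotFittedError("SpikeSegNet is not fitted; call fit first")

    # -- prediction --------------------------------------------------------

    def segment(self, image: np.ndarray) -> SegmentationResult:
        self._check_fitted()
        return segment_image(np.asarray(image), self.lpnet_, self.gmrnet_,
                             patch_size=self.patch_size, step=self.step,
                             threshold=self.threshold,
                             batch_size=self.batch_size)

    def predict(self, X: Sequence) -> np.ndarray:
        """Refined binary masks, shape (n, S, S) with S the patch size."""
        return np.stack([self.segment(img).refined_mask for img in X])

    def predict_proba(self, X: Sequence) -> np.ndarray:
        """Refined probability maps, shape (n, S, S)."""
        return np.stack([self.segment(img).refined_map for img in X])

    def count(self, view_images: Sequence[np.ndarray],
              angles=(0, 120, 240)) -> PlantCountResult:
        """Three-view spike count: segment each view, count particles,
        report the per-view counts and their maximum."""
        masks = [self.segment(img).refined_mask for img in view_images]
        return count_spikes_plant(masks, self.connectivity, self.min_area,
                                  angles=angles)

    def score(self, X: Sequence, y: Sequence) -> float:
        """Mean pixel F1 of refined masks against masks resized (nearest)
        to the refinement resolution."""
        self._check_fitted()
        size = self.patch_size
        f1s = []
        for img, mask in zip(X, y):
            pred = self.segment(img).refined_mask
            truth = resize_map(np.asarray(mask, dtype=float), size, size,
                               mode="nearest").astype(np.uint8)
            f1s.append(segmentation_metrics(pixel_confusion(pred, truth)).f1)
        return float(np.mean(f1s))
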