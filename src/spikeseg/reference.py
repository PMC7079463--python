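"""Published reference values used as worked-example inputs.

These are the printed headline numbers of the wheat-spike segmentation and
counting study this package re-implements, kept here so worked examples and
consistency checks can re-derive one metric from another (F1 and JI from
precision/recall, implied wrong-pixel counts from error rates, per-plant
counting metrics from raw object confusions) without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

#: Pixel-level segmentation performance on the study's validation set
#: (means over 90 side-view images of 30 plants).
SEGMENTATION_REFERENCE = {
    "e1": 0.0016,
    "e2": 0.0487,
    "ji": 0.9982,
    "accuracy": 0.9991,
    "precision": 0.9993,
    "recall": 0.9989,
    "f1": 0.9991,
}

#: Refined masks are evaluated at this fixed resolution.
EVAL_PIXELS = 256 * 256

#: Misclassification rate E1 under gamma re-illumination of the validation
#: set (gamma 1.0 is the unmodified image).
ILLUMINATION_E1 = {
    0.1: 0.005349223,
    0.3: 0.003051249,
    0.5: 0.002396139,
    1.0: 0.001693726,
    1.5: 0.00177917,
    2.0: 0.0020579,
    2.5: 0.002359009,
}


@dataclass(frozen=True)
class CountingRow:
    """One validation plant: ground-truth/predicted spike counts, the object
    confusion, and the metrics printed for it (2 dp)."""

    plant: int
    ground_truth: int
    predicted: int
    tp: int
    fp: int
    fn: int
    precision: float
    accuracy: float
    f1: float


#: Spike-counting outcomes for the 30 validation plants.
COUNTING_ROWS: Tuple[CountingRow, ...] = (
    CountingRow(1, 10, 9, 9, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(2, 8, 7, 7, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(3, 10, 9, 8, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(4, 11, 10, 10, 0, 1, 1.00, 0.91, 0.95),
    CountingRow(5, 10, 10, 10, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(6, 9, 9, 8, 1, 0, 0.89, 0.89, 0.94),
    CountingRow(7, 10, 9, 9, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(8, 6, 6, 6, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(9, 12, 11, 10, 0, 1, 1.00, 0.91, 0.95),
    CountingRow(10, 12, 12, 11, 0, 1, 1.00, 0.92, 0.96),
    CountingRow(11, 13, 12, 10, 0, 1, 1.00, 0.91, 0.95),
    CountingRow(12, 11, 10, 9, 0, 1, 1.00, 0.90, 0.95),
    CountingRow(13, 6, 6, 6, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(14, 8, 8, 8, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(15, 16, 15, 13, 2, 1, 0.87, 0.81, 0.90),
    CountingRow(16, 2, 2, 2, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(17, 10, 10, 10, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(18, 1, 1, 1, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(19, 11, 10, 10, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(20, 7, 7, 7, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(21, 8, 7, 7, 0, 1, 1.00, 0.88, 0.93),
    CountingRow(22, 8, 7, 7, 0, 1, 1.00, 0.88, 0.93),
    CountingRow(23, 10, 10, 10, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(24, 11, 10, 10, 0, 1, 1.00, 0.91, 0.95),
    CountingRow(25, 2, 2, 2, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(26, 8, 8, 7, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(27, 9, 8, 7, 0, 1, 1.00, 0.88, 0.93),
    CountingRow(28, 12, 10, 10, 0, 2, 1.00, 0.83, 0.91),
    CountingRow(29, 7, 7, 7, 0, 0, 1.00, 1.00, 1.00),
    CountingRow(30, 8, 8, 7, 1, 0, 0.88, 0.88, 0.93),
)

#: Averages of the per-plant counting metrics as published (2 dp).
COUNTING_AVERAGES = {"precision": 0.99, "accuracy": 0.95, "f1": 0.97}
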