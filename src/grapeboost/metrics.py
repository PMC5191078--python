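"""Detection and classification metrics.

Caution on naming: the rates follow the defining formulas of the
method's evaluation protocol, which are *nonstandard*.  Its "FNR" is a
false-discovery-style rate over detections (spurious detections /
(spurious + correct)); its "FPR" is the miss rate over true clusters
(missed / total); its "TPR" is the correct-detection rate (correct /
total).  Docstrings state the formula actually computed; do not expect
ROC-style semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class DetectionCounts:
    """Tallies of a detection experiment.

    total : number of true clusters present
    correctly_done : clusters detected correctly
    false_negative : background regions misreported as clusters
        (spurious detections, in this protocol's idiosyncratic naming)
    missed_done : true clusters not detected
    """

    total: int
    correctly_done: int
    false_negative: int
    missed_done: int

    def __post_init__(self):
        if min(self.total, self.correctly_done, self.false_negative, self.missed_done) < 0:
            raise ValueError("counts must be nonnegative")
        if self.correctly_done + self.missed_done != self.total:
            raise ValueError("correctly_done + missed_done must equal total")


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class sample-classification tallies."""

    grape_as_grape: int
    grape_as_background: int
    background_as_grape: int
    background_as_background: int

    def __post_init__(self):
        if min(
            self.grape_as_grape,
            self.grape_as_background,
            self.background_as_grape,
            self.background_as_background,
        ) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return (
            self.grape_as_grape
            + self.grape_as_background
            + self.background_as_grape
            + self.background_as_background
        )


def fnr(counts: DetectionCounts) -> float:
    """Spurious-detection rate: 100 * FN / (FN + correctly done)."""
    denom = counts.false_negative + counts.correctly_done
    if denom == 0:
        raise ZeroDivisionError("FNR undefined: no detections at all")
    return 100.0 * counts.false_negative / denom


def fpr(counts: DetectionCounts) -> float:
    """Miss rate: 100 * missed / total true clusters."""
    if counts.total == 0:
        raise ZeroDivisionError("FPR undefined: no true clusters")
    return 100.0 * counts.missed_done / counts.total


def tpr(counts: DetectionCounts) -> float:
    """Correct-detection rate: 100 * correctly done / total."""
    if counts.total == 0:
        raise ZeroDivisionError("TPR undefined: no true clusters")
    return 100.0 * counts.correctly_done / counts.total


def accuracy(conf: ConfusionCounts) -> float:
    """Overall sample accuracy: 100 * correct / all samples."""
    if conf.n_samples == 0:
        raise ZeroDivisionError("accuracy undefined for an empty confusion table")
    correct = conf.grape_as_grape + conf.background_as_background
    return 100.0 * correct / conf.n_samples


def pra(manual_region: np.ndarray, algorithm_region: np.ndarray) -> float:
    """Pixel recognition accuracy: 100 * |manual & algorithm| / |manual|.

    Regions are boolean masks of identical shape (or pixel index sets
    cast to masks by the caller).  75% is the usability bar below which
    a detection no longer serves a harvesting robot.
    """
    manual = np.asarray(manual_region, dtype=bool)
    algorithm = np.asarray(algorithm_region, dtype=bool)
    n_manual = int(manual.sum())
    if n_manual == 0:
        raise ValueError("manual region is empty; PRA undefined")
    return 100.0 * int((manual & algorithm).sum()) / n_manual


def mean_pra(values: Sequence[float]) -> float:
    """Arithmetic mean of per-cluster PRA percentages."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mean of an empty PRA list is undefined")
    return float(values.mean())


def round_percent(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for display (93.735 -> 93.74); full precision
    is carried everywhere else."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def detection_report(counts: DetectionCounts) -> dict:
    """All three rates of one detection experiment, full precision."""
    return {
        "total": counts.total,
        "correctly_done": counts.correctly_done,
        "false_negative": counts.false_negative,
        "missed_done": counts.missed_done,
        "TPR": tpr(counts),
        "FNR": fnr(counts),
        "FPR": fpr(counts),
    }
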