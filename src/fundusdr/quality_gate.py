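"""Three-way fundus image quality triage: good / usable / reject.

Grading should only ever see images a clinician could read. This gate is a
transparent heuristic over three cheap metrics — how much of the frame is
retina (foreground fraction), how sharp it is (variance of the Laplacian),
and how bright it is (mean HSV value) — with the same label vocabulary as
learned quality networks, so one can be plugged in behind the same
interface later. Datasets keep only ``good`` and ``usable`` images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .preprocess import build_clip_mask, rgb_to_gray

QUALITY_LABELS = ("good", "usable", "reject")


@dataclass
class QualityMetrics:
    """Audit record for one image."""

    foreground_fraction: float  # fraction of pixels above the clip tolerance
    sharpness: float  # variance of the Laplacian-filtered gray image
    mean_value: float  # mean HSV value channel, 0-255


@dataclass
class QualityThresholds:
    """Lower bounds per label; every ``good`` bound >= its ``usable`` bound.

    Defaults were calibrated once on the synthetic generator's clean,
    blurred, and darkened fixtures and are deliberately loose for clean
    images.
    """

    min_foreground_good: float = 0.35
    min_foreground_usable: float = 0.10
    min_sharpness_good: float = 60.0
    min_sharpness_usable: float = 2.0
    min_mean_value_usable: float = 20.0

    def __post_init__(self):
        if self.min_foreground_good < self.min_foreground_usable:
            raise ValueError("good foreground bound below usable bound")
        if self.min_sharpness_good < self.min_sharpness_usable:
            raise ValueError("good sharpness bound below usable bound")


def compute_metrics(img: np.ndarray, tolerance: int = 7) -> QualityMetrics:
    gray = rgb_to_gray(img)
    fg = float(build_clip_mask(gray, tolerance).mean())
    lap = ndimage.laplace(gray.astype(np.float64))
    sharp = float(lap.var())
    mean_value = float(np.asarray(img).max(axis=2).mean())
    return QualityMetrics(fg, sharp, mean_value)


def assess_quality(
    img: np.ndarray,
    thresholds: QualityThresholds = QualityThresholds(),
    tolerance: int = 7,
) -> tuple[str, QualityMetrics]:
    """Label one image good, usable, or reject and return the metrics."""
    m = compute_metrics(img, tolerance)
    th = thresholds
    if (
        m.foreground_fraction >= th.min_foreground_good
        and m.sharpness >= th.min_sharpness_good
        and m.mean_value >= th.min_mean_value_usable
    ):
        return "good", m
    if (
        m.foreground_fraction >= th.min_foreground_usable
        and m.sharpness >= th.min_sharpness_usable
        and m.mean_value >= th.min_mean_value_usable
    ):
        return "usable", m
    return "reject", m


def filter_usable(
    records: Sequence,
    thresholds: QualityThresholds = QualityThresholds(),
    image_of: Callable = lambda r: r,
) -> list:
    """Keep exactly the records whose image grades good or usable, in order."""
    kept = []
    for rec in records:
        label, _ = assess_quality(image_of(rec), thresholds)
        if label in ("good", "usable"):
            kept.append(rec)
    return kept
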