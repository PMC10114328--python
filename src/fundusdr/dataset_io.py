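"""Label reading, severity binarization, and balanced split selection.

The label file follows the Kaggle dialect: a CSV with header ``image,level``
where ``level`` is the 0-4 severity grade (0 healthy; 1-4 the four
retinopathy stages). Grading here is binary, so every non-zero level
collapses to label 1. Splits are drawn without replacement, class-balanced,
and pairwise disjoint by image id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError


@dataclass
class LabelRecord:
    image_id: str
    level: int
    binary_label: int


@dataclass
class SplitSpec:
    """Balanced-selection sizes; the full-scale values are 1500 per class for
    training and 300 each (150 per class) for validation and test."""

    n_train_per_class: int = 1500
    n_val: int = 300
    n_test: int = 300
    seed: int = 0

    def __post_init__(self):
        if min(self.n_train_per_class, self.n_val, self.n_test) < 1:
            raise ConfigError("split sizes must be >= 1")
        if self.n_val % 2 or self.n_test % 2:
            raise ConfigError("n_val and n_test must be even (balanced per class)")


def binarize(level: int) -> int:
    """0 iff level is 0; any of the four disease stages maps to 1."""
    if not 0 <= level <= 4:
        raise InvalidInputError(f"severity level out of range 0-4: {level}")
    return 0 if level == 0 else 1


def read_labels(path: str | Path) -> list[LabelRecord]:
    """Parse a Kaggle-dialect label CSV into records with binary labels."""
    df = pd.read_csv(path, dtype={"image": str})
    missing = {"image", "level"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"label file missing column(s): {sorted(missing)}")
    if df["image"].duplicated().any():
        dup = df["image"][df["image"].duplicated()].iloc[0]
        raise InvalidInputError(f"duplicate image id: {dup!r}")
    records = []
    for row_idx, (image_id, level) in enumerate(zip(df["image"], df["level"])):
        try:
            level = int(level)
        except (TypeError, ValueError):
            raise InvalidInputError(f"row {row_idx}: non-integer level {level!r}")
        if not 0 <= level <= 4:
            raise InvalidInputError(f"row {row_idx}: level out of range 0-4: {level}")
        records.append(LabelRecord(str(image_id), level, binarize(level)))
    return records


def make_splits(
    records: list[LabelRecord], spec: SplitSpec
) -> dict[str, list[str]]:
    """Seeded balanced sampling into disjoint train/val/test id lists.

    Train takes n_train_per_class of each binary class; validation and test
    take n_val/2 and n_test/2 per class from what remains.
    """
    by_class = {0: [], 1: []}
    for rec in records:
        by_class[rec.binary_label].append(rec.image_id)
    need = {
        c: spec.n_train_per_class + spec.n_val // 2 + spec.n_test // 2 for c in (0, 1)
    }
    for c in (0, 1):
        if len(by_class[c]) < need[c]:
            raise ConfigError(
                f"class {c}: need {need[c]} images, have {len(by_class[c])} "
                f"(short {need[c] - len(by_class[c])})"
            )
    rng = np.random.default_rng(spec.seed)
    splits = {"train": [], "val": [], "test": []}
    for c in (0, 1):
        chosen = rng.choice(len(by_class[c]), size=need[c], replace=False)
        ids = [by_class[c][i] for i in chosen]
        a = spec.n_train_per_class
        b = a + spec.n_val // 2
        splits["train"] += ids[:a]
        splits["val"] += ids[a:b]
        splits["test"] += ids[b:]
    return splits
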