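"""Object- and image-level measurements."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imgio import BinaryMask
from .segmentation import LabelMap, build_object_table

__all__ = [
    "AreaOccupiedResult",
    "count_objects",
    "measure_object_areas",
    "area_occupied",
    "subtract_counts",
    "two_sample_ttest",
]


@dataclass
class AreaOccupiedResult:
    """Fraction of the full image frame covered by foreground.

    The denominator is the total pixel count of the frame, not a
    tissue-restricted area.
    """

    foreground_pixels: int
    total_pixels: int

    @property
    def fraction(self) -> float:
        return self.foreground_pixels / self.total_pixels

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def count_objects(labels: LabelMap) -> int:
    return labels.n_objects


def measure_object_areas(labels: LabelMap) -> pd.DataFrame:
    """Per-object pixel areas and equivalent diameters (label, area, ...)."""
    return build_object_table(labels)


def area_occupied(mask: BinaryMask) -> AreaOccupiedResult:
    return AreaOccupiedResult(
        foreground_pixels=int(mask.pixels.sum()),
        total_pixels=int(mask.pixels.size),
    )


def subtract_counts(total: int, excluded: int) -> tuple[int, Optional[str]]:
    """total - excluded, floored at zero.

    The two counts come from independent segmentation passes and can
    disagree; when excluded > total, the result is clamped to 0 and a
    discrepancy warning is returned so the inconsistency stays auditable.
    """
    if total < 0 or excluded < 0:
        raise ValueError("counts must be non-negative")
    if excluded > total:
        return 0, (
            f"excluded count ({excluded}) exceeds total count ({total}); "
            "difference clamped to 0"
        )
    return total - excluded, None


def two_sample_ttest(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided unpaired Student's t-test (equal-variance form).

    Convenience for comparing per-animal summary values between groups.
    Degenerate zero-pooled-variance input returns t = 0, p = 1 for equal
    means and t = ±inf, p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if pooled_ss == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
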