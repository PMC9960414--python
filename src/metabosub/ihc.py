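"""Immunoreactive score (IRS) computation and group comparison.

IRS = proportion score (0-4) x staining intensity (0-3), binned into
negative (0-1), mild (2-3), moderate (4-8) and strong (9-12). The published
proportion bins leave (50, 51) and (80, 81) undefined for continuous
percentages; they are closed as 2: (10, 50], 3: (50, 80], 4: (80, 100],
preserving the printed integer anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from metabosub.errors import ValidationError

MARKERS = ("ENO1", "PFKFB3", "NSDHL", "SQLE", "other")

IRS_BINS = (
    ("negative", 0, 1),
    ("mild", 2, 3),
    ("moderate", 4, 8),
    ("strong", 9, 12),
)


@dataclass(frozen=True)
class IhcSpecimen:
    specimen_id: str
    positive_cell_pct: float
    intensity: int
    marker: str = "other"
    group: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.positive_cell_pct <= 100:
            raise ValidationError("positive_cell_pct must lie in [0, 100]")
        if self.intensity not in (0, 1, 2, 3):
            raise ValidationError("intensity must be an integer in 0-3")


@dataclass(frozen=True)
class IrsResult:
    specimen_id: str
    proportion_score: int
    intensity_score: int
    irs: int
    category: str


def proportion_score(pct: float) -> int:
    """Positive-cell percentage -> 0-4 proportion score."""
    if not 0 <= pct <= 100:
        raise ValidationError(f"percentage {pct} outside [0, 100]")
    if pct == 0:
        return 0
    if pct < 10:
        return 1
    if pct <= 50:
        return 2
    if pct <= 80:
        return 3
    return 4


def categorize(irs_value: int) -> str:
    for name, lo, hi in IRS_BINS:
        if lo <= irs_value <= hi:
            return name
    raise ValidationError(f"IRS value {irs_value} outside 0-12")


def irs(specimen: IhcSpecimen) -> IrsResult:
    p = proportion_score(specimen.positive_cell_pct)
    value = p * specimen.intensity
    return IrsResult(specimen.specimen_id, p, specimen.intensity, value,
                     categorize(value))


def compare_groups(group_a, group_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t-test on IRS values (Welch by default).

    Returns (t statistic, p value).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
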