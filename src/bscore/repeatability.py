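"""Bland-Altman repeatability of the B-score.

A repeat-scan pair gives two B-scores for the same knee.  The smallest
detectable difference (SDD) is the 95% limit-of-agreement half-width,
1.96 times the sample SD of the paired differences; dividing the working
range of the score by the SDD gives the number of distinguishable grades
the measurement supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ScanPair",
    "RepeatabilityResult",
    "bland_altman_sdd",
    "distinguishable_grades",
    "sdd_as_fraction_of_range",
]


@dataclass(frozen=True)
class ScanPair:
    """Two same-knee B-score measurements (same-day or one-week interval)."""

    shape_id: str
    bscore_1: float
    bscore_2: float
    interval: str = "same_day"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.bscore_1) and math.isfinite(self.bscore_2)):
            raise ValueError(f"non-finite B-score in pair {self.shape_id!r}")
        if self.interval not in ("same_day", "one_week"):
            raise ValueError(f"unknown interval {self.interval!r}")


@dataclass(frozen=True)
class RepeatabilityResult:
    n_pairs: int
    bias: float          # mean of (bscore_1 - bscore_2)
    sd_diff: float       # sample SD of differences (n-1)
    sdd: float           # z * sd_diff, the limit-of-agreement half-width
    limits: tuple[float, float]  # bias -/+ z * sd_diff


def bland_altman_sdd(pairs: Sequence[ScanPair], z: float = 1.96) -> RepeatabilityResult:
    """Bland-Altman limits of agreement for repeat B-score measurements.

    ``z`` is the limit multiplier, 1.96 for 95% limits (the convention; a
    t-quantile is deliberately not substituted).
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(pairs)}")
    diffs = np.array([p.bscore_1 - p.bscore_2 for p in pairs])
    bias = float(diffs.mean())
    sd_diff = float(np.std(diffs, ddof=1))
    sdd = z * sd_diff
    return RepeatabilityResult(
        n_pairs=len(pairs), bias=bias, sd_diff=sd_diff, sdd=sdd,
        limits=(bias - sdd, bias + sdd),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def distinguishable_grades(range_lo: float, range_hi: float, sdd: float) -> int:
    """Number of measurement-distinguishable grades over a score range.

    Rounds (range_hi - range_lo) / sdd to the nearest integer (ties away
    from zero): a range of 10 B-score units at SDD 0.251 supports 40 grades.
    """
    if sdd <= 0:
        raise ValueError(f"sdd must be positive, got {sdd}")
    if range_hi <= range_lo:
        raise ValueError(f"empty range ({range_lo}, {range_hi})")
    return _round_half_away((range_hi - range_lo) / sdd)


def sdd_as_fraction_of_range(sdd: float, range_lo: float, range_hi: float) -> float:
    """SDD as a percentage of the score range (e.g. 0.254 over (-3, 7) -> 2.54%)."""
    if sdd <= 0:
        raise ValueError(f"sdd must be positive, got {sdd}")
    if range_hi <= range_lo:
        raise ValueError(f"empty range ({range_lo}, {range_hi})")
    return 100.0 * sdd / (range_hi - range_lo)
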