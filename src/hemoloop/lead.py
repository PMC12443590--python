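"""Population statistics behind the paddle-lead geometry.

The paddle must span the last three thoracic spinal segments (the
hemodynamic hotspot) in most of the population.  Segment lengths are modeled
as independent normals, so the combined length is normal with summed means
and variances; the lead length that covers a population fraction ``c`` is
the ``c``-quantile of that sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = ["SegmentStats", "coverage_length", "normalized_position"]


@dataclass(frozen=True)
class SegmentStats:
    """Per-segment length statistics: (label, mean mm, s.d. mm) tuples."""

    segments: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((str(l), float(m), float(s)) for l, m, s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("need at least one segment")
        for label, mean, sd in segs:
            if mean <= 0:
                raise ValueError(f"segment {label}: mean length must be > 0 mm")
            if sd < 0:
                raise ValueError(f"segment {label}: s.d. must be >= 0 mm")

    @property
    def total_mean(self) -> float:
        return float(sum(m for _, m, _ in self.segments))

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(sum(s**2 for _, _, s in self.segments)))

    @classmethod
    def from_rows(cls, rows: Sequence[tuple[str, float, float]]) -> "SegmentStats":
        return cls(tuple(rows))


def coverage_length(stats: SegmentStats, coverage: float = 0.95) -> float:
    """Lead length (mm) spanning the combined segments for a fraction
    ``coverage`` of the population.

    With independent normal segment lengths the total is
    N(sum(mu), sum(sigma^2)); the answer is its one-sided ``coverage``
    quantile: sum(mu) + z(coverage) * sqrt(sum(sigma^2)).
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    z = float(_stats.norm.ppf(coverage))
    return stats.total_mean + z * stats.total_sd


def normalized_position(distance_from_hotspot_center: float, spinal_length: float) -> float:
    """Rostrocaudal electrode position normalized by spinal length.

    ``distance_from_hotspot_center`` is the signed distance (mm) to the
    hotspot center (T11), rostral positive; ``spinal_length`` is the
    participant's T9-to-conus length (mm).  Returns the dimensionless ratio.
    """
    if spinal_length <= 0:
        raise ValueError("spinal length must be > 0")
    return distance_from_hotspot_center / spinal_length
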