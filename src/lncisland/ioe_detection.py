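"""Island-of-expression (I.o.E) detection.

An island is a maximal run of positions with depth strictly above the depth
threshold, retained only if at least one read length long (defaults: depth
> 2, length >= 100 bp, matching a 100-bp read-mate length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CoverageTrack
from .intervals import GenomeInterval

DEPTH_THRESHOLD = 2  # strict: qualifying positions have depth > 2
MIN_ISLAND_LENGTH = 100  # one read-mate length


@dataclass(frozen=True)
class IslandOfExpression:
    interval: GenomeInterval
    strand: str
    mean_depth: float
    max_depth: int
    sample_id: str = ""


def find_islands(
    track: CoverageTrack,
    depth_threshold: int = DEPTH_THRESHOLD,
    min_length: int = MIN_ISLAND_LENGTH,
    sample_id: str = "",
) -> list[IslandOfExpression]:
    """Maximal above-threshold runs of length >= ``min_length``, sorted."""
    if depth_threshold <= 0 or min_length <= 0:
        raise ValueError("thresholds must be positive")
    above = track.depth > depth_threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    run_starts = np.flatnonzero(d == 1) + 1
    run_ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        run_starts = np.concatenate([[0], run_starts])
    if above[-1]:
        run_ends = np.concatenate([run_ends, [len(above)]])
    out = []
    for s, e in zip(run_starts, run_ends):
        if e - s < min_length:
            continue
        seg = track.depth[s:e]
        out.append(
            IslandOfExpression(
                GenomeInterval(track.chrom, int(s), int(e), track.strand),
                track.strand,
                float(seg.mean()),
                int(seg.max()),
                sample_id,
            )
        )
    return out


def island_mean_depth(track: CoverageTrack, interval: GenomeInterval) -> float:
    """Arithmetic mean depth of the track over ``interval``."""
    if interval.start >= interval.end:
        raise ValueError("empty interval")
    if interval.end > len(track.depth):
        raise ValueError("interval outside track")
    return float(track.depth[interval.start : interval.end].mean())
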