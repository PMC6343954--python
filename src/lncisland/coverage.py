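"""Per-base coverage tracks for one chromosome strand.

Depth is held as a dense integer numpy vector (chromosomes here are tens of
megabases at most; a run-length representation is used only on disk, as
bedGraph).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import read_bedgraph, write_bedgraph


@dataclass
class CoverageTrack:
    chrom: str
    strand: str
    depth: np.ndarray  # int vector indexed by 0-based position

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(self.chrom, self.strand, self.depth.copy())


def track_from_bedgraph(
    path: str | Path, chrom: str, strand: str, chrom_length: int | None = None
) -> CoverageTrack:
    """Materialise the dense depth vector of one chromosome from a bedGraph."""
    df = read_bedgraph(path)
    df = df[df["chrom"] == chrom]
    n = chrom_length if chrom_length is not None else (int(df["end"].max()) if len(df) else 0)
    depth = np.zeros(n, dtype=np.int64)
    for s, e, d in zip(df["start"], df["end"], df["depth"]):
        depth[s:e] += int(d)
    return CoverageTrack(chrom, strand, depth)


def track_to_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write non-zero runs of the track as 4-column bedGraph."""
    d = track.depth
    if len(d) == 0:
        Path(path).write_text("")
        return
    change = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(d)]])
    vals = d[starts]
    keep = vals != 0
    df = pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": starts[keep],
            "end": ends[keep],
            "depth": vals[keep],
        }
    )
    write_bedgraph(df, path)
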