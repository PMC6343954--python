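"""Strand-aware exclusion mask built from annotated gene models.

Coverage inside the mask is zeroed so that only unannotated transcription can
seed islands of expression. Two modes:

* ``span`` — mask each gene's full span (min exon start .. max exon end),
  extended by a flank (default 1000 bp) on both sides, on the gene's strand.
  Used for the intergenic / antisense / monoexonic branch; it also masks
  annotated-intron interiors so that incomplete pre-mRNA signal is not called
  novel.
* ``exon_union`` — mask only exons (plus flank at the gene ends), leaving
  intron interiors open; used for the second pass that discovers intronic
  candidates.

The mask is strand-specific: a dUTP stranded library distinguishes the two
strands, and antisense lncRNAs (on the strand opposite an annotated gene) must
survive masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .coverage import CoverageTrack
from .intervals import GeneModel, GenomeInterval, merge_pairs

MASK_MODES = ("span", "exon_union")


@dataclass
class StrandMask:
    """Per (chrom, strand) sorted disjoint interval lists."""

    intervals: dict[tuple[str, str], list[tuple[int, int]]] = field(
        default_factory=dict
    )

    def get(self, chrom: str, strand: str) -> list[tuple[int, int]]:
        return self.intervals.get((chrom, strand), [])

    def covers(self, iv: GenomeInterval) -> bool:
        """True iff iv lies entirely inside the same-strand mask."""
        return any(
            s <= iv.start and iv.end <= e
            for s, e in self.get(iv.chrom, iv.strand)
        )

    def overlaps(self, iv: GenomeInterval) -> bool:
        return any(
            s < iv.end and iv.start < e for s, e in self.get(iv.chrom, iv.strand)
        )


def build_mask(
    genes: Iterable[GeneModel], flank: int = 1000, mode: str = "span"
) -> StrandMask:
    """Build the exclusion mask from gene models extended by ``flank`` bp."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if mode not in MASK_MODES:
        raise ValueError(f"mask mode must be one of {MASK_MODES}")
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in genes:
        key = (g.gene_span.chrom, g.strand)
        pieces = raw.setdefault(key, [])
        if mode == "span":
            pieces.append(
                (max(0, g.gene_span.start - flank), g.gene_span.end + flank)
            )
        else:
            exons = g.exons or [g.gene_span]
            for i, e in enumerate(exons):
                s = e.start - flank if i == 0 else e.start
                t = e.end + flank if i == len(exons) - 1 else e.end
                pieces.append((max(0, s), t))
    return StrandMask({k: merge_pairs(v) for k, v in raw.items()})


def mask_coverage(track: CoverageTrack, mask: StrandMask) -> CoverageTrack:
    """Zero the track at every masked position (same chrom/strand)."""
    out = track.copy()
    n = len(out.depth)
    for s, e in mask.get(track.chrom, track.strand):
        if s >= n:
            break
        out.depth[s : min(e, n)] = 0
    return out
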