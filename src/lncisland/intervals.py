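"""Genomic interval primitives.

All coordinates are 0-based half-open internally; display / GTF / SJ.out.tab
coordinates are 1-based inclusive and converted at the I/O boundary.

Interval-set algebra (merge, intersection, difference, atomic segmentation)
operates on sorted lists of ``(start, end)`` tuples and underpins the
exclusion mask, consensus-intron computation and exon reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")

# some typeset sources render minus strands with a unicode minus sign
_UNICODE_MINUS = "−"


def normalize_strand(s: str) -> str:
    s = s.replace(_UNICODE_MINUS, "-")
    if s not in STRANDS:
        raise ValueError(f"unknown strand symbol: {s!r}")
    return s


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval [start, end) on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        object.__setattr__(self, "strand", normalize_strand(self.strand))

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_display(self) -> tuple[int, int]:
        """Internal half-open -> 1-based inclusive (start, end)."""
        return self.start + 1, self.end

    @classmethod
    def from_display(
        cls, chrom: str, start1: int, end1: int, strand: str = "."
    ) -> "GenomeInterval":
        """1-based inclusive coordinates -> internal interval."""
        return cls(chrom, start1 - 1, end1, strand)


@dataclass
class GeneModel:
    """An annotated gene: strand-tagged exon set plus overall gene span."""

    gene_id: str
    biotype: str
    strand: str
    gene_span: GenomeInterval
    exons: list[GenomeInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.strand = normalize_strand(self.strand)
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        prev_end = None
        for e in self.exons:
            if e.chrom != self.gene_span.chrom or e.strand != self.strand:
                raise ValueError(f"{self.gene_id}: exon off gene chrom/strand")
            if not self.gene_span.contains(e):
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e.end

    @property
    def introns(self) -> list[GenomeInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomeInterval(a.chrom, a.end, b.start, self.strand))
        return out


@dataclass(frozen=True)
class SpliceJunction:
    """An intron inferred from spliced alignments, with unique-read support."""

    intron: GenomeInterval
    strand: str
    unique_reads: int
    annotated_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", normalize_strand(self.strand))
        if self.unique_reads < 0:
            raise ValueError("negative unique read support")


@dataclass
class TranscriptCandidate:
    """A reconstructed putative lncRNA gene model."""

    id: str
    chrom: str
    strand: str
    exons: list[GenomeInterval]
    klass: str = "unclassified"  # antisense | intergenic | intronic | unclassified
    closest_gene_id: str = ""
    distance_to_closest: int = -1
    filter_flags: set[str] = field(default_factory=set)
    coding_probability: float = float("nan")
    condition_fpkm: dict[str, float] = field(default_factory=dict)
    source_samples: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.strand = normalize_strand(self.strand)
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        prev = None
        for e in self.exons:
            if prev is not None and e.start < prev:
                raise ValueError(f"{self.id}: overlapping exons")
            prev = e.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomeInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomeInterval(self.chrom, a.end, b.start, self.strand))
        return out


# ---------------------------------------------------------------------------
# interval-set algebra on (start, end) tuples


Pairs = list[tuple[int, int]]


def merge_pairs(pairs: Iterable[tuple[int, int]]) -> Pairs:
    """Union of half-open intervals; adjacent intervals are coalesced."""
    out: Pairs = []
    for s, e in sorted(pairs):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_pairs(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> Pairs:
    a, b = merge_pairs(a), merge_pairs(b)
    out: Pairs = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_pairs(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> Pairs:
    """Set difference a \\ b of half-open interval unions."""
    a, b = merge_pairs(a), merge_pairs(b)
    out: Pairs = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_bp(pairs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_pairs(pairs))


def atomic_segments(pairs: Sequence[tuple[int, int]]) -> Pairs:
    """Break the union of intervals at every interval boundary.

    Returns the maximal sub-intervals within which the set of covering input
    intervals is constant ("discrete segments" of a set of junctions).
    """
    bounds = sorted({p for s, e in pairs for p in (s, e)})
    covered = merge_pairs(pairs)
    out: Pairs = []
    for s, e in zip(bounds, bounds[1:]):
        if any(cs <= s and e <= ce for cs, ce in covered):
            out.append((s, e))
    return out
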