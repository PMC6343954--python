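"""Transcript assembly from islands of expression and splice junctions.

Stages:

1. junction filtering (unique support > 2, 20 < intron length < 100,000,
   outside the same-strand mask, optionally unannotated only);
2. clustering islands connected by junctions (connected components of the
   island/junction graph, with co-overlapping islands across samples also
   joined);
3. consensus introns per cluster via relative frequency of the atomic
   segments of the cluster's junction set;
4. exon reconstruction by subtracting consensus introns from the island hull;
5. smoothed z-score refinement on residual exon coverage (extra introns and
   transcript-end trimming);
6. monoexonic path (cross-sample intersection + Pr(>) < 0.1 rank filter);
7. merging per-sample candidates into a non-redundant gene-level set with
   per-condition replicate-presence flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_mask import StrandMask
from .coverage import CoverageTrack
from .intervals import (
    GenomeInterval,
    SpliceJunction,
    TranscriptCandidate,
    atomic_segments,
    intersect_pairs,
    merge_pairs,
    subtract_pairs,
)
from .ioe_detection import IslandOfExpression


@dataclass
class AssemblyParams:
    """Tunable thresholds of the reconstruction.

    Comparison senses follow the printed rules: junction support strictly
    greater than ``sj_min_unique_reads``; intron length strictly between the
    two bounds; island depth strictly above ``depth_threshold``; island
    length at least ``min_island_length``.
    """

    sj_min_unique_reads: int = 2  # kept iff unique_reads > 2
    sj_min_length: int = 20  # kept iff length > 20
    sj_max_length: int = 100_000  # kept iff length < 100,000
    z_window: int = 31
    z_drop_threshold: float = 5.0
    z_min_intron: int = 20
    z_s_floor: float = 1.0
    consensus_fraction: float = 0.5
    min_island_length: int = 100
    depth_threshold: int = 2
    junction_tolerance: int = 10  # bp slack attaching junction ends to islands
    monoexonic_pr_cutoff: float = 0.1
    min_transcript_length: int = 200
    novel_only: bool = False

    def __post_init__(self) -> None:
        if self.z_window % 2 == 0:
            raise ValueError("z_window must be odd")
        for name in (
            "sj_min_length",
            "sj_max_length",
            "z_window",
            "z_min_intron",
            "min_island_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def filter_junctions(
    raw: Iterable[SpliceJunction],
    params: AssemblyParams | None = None,
    mask: StrandMask | None = None,
) -> list[SpliceJunction]:
    """Keep junctions with support > 2 and 20 < intron length < 100,000.

    Junctions lying inside the same-strand mask are annotation signal, not
    novel connectivity, and are removed; with ``novel_only`` set, junctions
    already flagged annotated by the aligner are removed too.
    """
    p = params or AssemblyParams()
    out = []
    for j in raw:
        if j.unique_reads <= p.sj_min_unique_reads:
            continue
        if not (p.sj_min_length < j.intron.length < p.sj_max_length):
            continue
        if p.novel_only and j.annotated_flag:
            continue
        if mask is not None and mask.covers(j.intron):
            continue
        out.append(j)
    return out


@dataclass
class IslandCluster:
    islands: list[IslandOfExpression]
    junctions: list[SpliceJunction]
    strand: str
    chrom: str

    @property
    def span(self) -> GenomeInterval:
        s = min(i.interval.start for i in self.islands)
        e = max(i.interval.end for i in self.islands)
        return GenomeInterval(self.chrom, s, e, self.strand)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _touches(iv: GenomeInterval, pos: int, tol: int) -> bool:
    return iv.start - tol <= pos <= iv.end + tol


def cluster_islands(
    islands: Sequence[IslandOfExpression],
    junctions: Sequence[SpliceJunction],
    tolerance: int = 10,
) -> list[IslandCluster]:
    """Connected components of the island graph.

    Two islands are joined when a junction's donor end falls in (or abuts,
    within ``tolerance`` bp) one island and its acceptor end the other, or
    when the islands themselves overlap (co-overlapping islands from
    different samples). Unconnected islands form singleton clusters.
    """
    isl = sorted(islands, key=lambda i: (i.interval.start, i.interval.end, i.sample_id))
    n = len(isl)
    uf = _UnionFind(n)

    # co-overlap edges (sorted sweep)
    for i in range(n):
        for j in range(i + 1, n):
            if isl[j].interval.start >= isl[i].interval.end:
                break
            uf.union(i, j)

    # junction edges; record which junctions connect members
    used: dict[int, list[SpliceJunction]] = {}
    for sj in junctions:
        donors = [
            k for k in range(n) if _touches(isl[k].interval, sj.intron.start, tolerance)
        ]
        acceptors = [
            k for k in range(n) if _touches(isl[k].interval, sj.intron.end, tolerance)
        ]
        linked = False
        for a in donors:
            for b in acceptors:
                if a != b:
                    uf.union(a, b)
                    linked = True
        if linked:
            for a in set(donors + acceptors):
                used.setdefault(a, []).append(sj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    clusters = []
    for root in sorted(groups):
        members = [isl[i] for i in groups[root]]
        sjs: list[SpliceJunction] = []
        seen = set()
        for i in groups[root]:
            for sj in used.get(i, []):
                key = (sj.intron.start, sj.intron.end, sj.unique_reads)
                if key not in seen:
                    seen.add(key)
                    sjs.append(sj)
        clusters.append(
            IslandCluster(
                islands=members,
                junctions=sorted(sjs, key=lambda s: (s.intron.start, s.intron.end)),
                strand=members[0].strand,
                chrom=members[0].interval.chrom,
            )
        )
    return clusters


def consensus_introns(
    cluster_junctions: Sequence[SpliceJunction],
    consensus_fraction: float = 0.5,
    min_intron: int = 20,
) -> list[tuple[int, int]]:
    """Consensus introns from the relative frequency of junction segments.

    The union of junction intervals is broken at every junction boundary into
    atomic segments. A segment is accepted when the number of junctions
    containing it, divided by the number of junctions overlapping the
    segment's connected union block, exceeds ``consensus_fraction``. Adjacent
    accepted segments merge; merged introns shorter than ``min_intron`` are
    discarded.
    """
    if not cluster_junctions:
        return []
    pairs = [(j.intron.start, j.intron.end) for j in cluster_junctions]
    blocks = merge_pairs(pairs)
    segments = atomic_segments(pairs)
    accepted = []
    for s, e in segments:
        block = next(b for b in blocks if b[0] <= s and e <= b[1])
        denom = sum(1 for ps, pe in pairs if ps < block[1] and block[0] < pe)
        num = sum(1 for ps, pe in pairs if ps <= s and e <= pe)
        if denom and num / denom > consensus_fraction:
            accepted.append((s, e))
    merged = merge_pairs(accepted)
    return [(s, e) for s, e in merged if e - s >= min_intron]


def subtract_introns(
    cluster: IslandCluster,
    introns: Sequence[tuple[int, int]],
    candidate_id: str = "",
) -> TranscriptCandidate:
    """Reconstruct the exon chain: island hull minus introns, trimmed to
    island-supported bp at the outer ends of each exon piece."""
    span = cluster.span
    hull = [(span.start, span.end)]
    pieces = subtract_pairs(hull, list(introns))
    support = merge_pairs(
        [(i.interval.start, i.interval.end) for i in cluster.islands]
    )
    exons: list[tuple[int, int]] = []
    for s, e in pieces:
        covered = intersect_pairs([(s, e)], support)
        if not covered:
            continue
        # trim the piece's ends to supported bp, keep interior gaps bridged
        exons.append((covered[0][0], covered[-1][1]))
    if not exons:
        raise ValueError("intron subtraction left no exonic bp")
    return TranscriptCandidate(
        id=candidate_id or f"cand:{cluster.chrom}:{span.start}-{span.end}",
        chrom=cluster.chrom,
        strand=cluster.strand,
        exons=[GenomeInterval(cluster.chrom, s, e, cluster.strand) for s, e in exons],
    )


# ---------------------------------------------------------------------------
# smoothed z-score breakpoint detector


def zscore_breakpoints(
    depth: np.ndarray, params: AssemblyParams | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Smoothed z-score thresholding over one coverage segment.

    A trailing window of ``z_window`` positions maintains a rolling mean m
    and standard deviation s of the *filtered* signal (flagged positions do
    not update the statistics: influence 0). Position i is flagged DROP when
    m - depth[i] > threshold * max(s, s_floor), PEAK for the symmetric
    excess. Maximal DROP runs of length >= ``z_min_intron`` are candidate
    introns; shorter runs are ignored. Returns {"drops": runs,
    "peaks": runs} as half-open offsets into the segment.
    """
    p = params or AssemblyParams()
    x = np.asarray(depth, dtype=float)
    n = len(x)
    if n <= p.z_window:
        return {"drops": [], "peaks": []}
    w = p.z_window
    filt = x.copy()
    flags = np.zeros(n, dtype=np.int8)  # 0 none, -1 drop, +1 peak
    for i in range(w, n):
        window = filt[i - w : i]
        m = window.mean()
        s = max(window.std(), p.z_s_floor)
        dev = x[i] - m
        if dev > p.z_drop_threshold * s:
            flags[i] = 1
            filt[i] = filt[i - 1]
        elif -dev > p.z_drop_threshold * s:
            flags[i] = -1
            filt[i] = filt[i - 1]

    def runs(mask: np.ndarray) -> list[tuple[int, int]]:
        out = []
        i = 0
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                out.append((i, j))
                i = j
            else:
                i += 1
        return out

    drops = [r for r in runs(flags == -1) if r[1] - r[0] >= p.z_min_intron]
    peaks = runs(flags == 1)
    return {"drops": drops, "peaks": peaks}


def refine_candidate(
    candidate: TranscriptCandidate,
    track: CoverageTrack,
    params: AssemblyParams | None = None,
) -> TranscriptCandidate | None:
    """Apply z-score refinement to each exon of a candidate.

    DROP runs inside an exon become additional introns; DROP runs touching
    the first/last exon's outer end trim the transcript. Returns None when
    refinement leaves no exon of usable length.
    """
    p = params or AssemblyParams()
    cut: list[tuple[int, int]] = []
    first_start = candidate.exons[0].start
    last_end = candidate.exons[-1].end
    for e in candidate.exons:
        seg = track.depth[e.start : e.end]
        bp = zscore_breakpoints(seg, p)
        for s, t in bp["drops"]:
            gs, ge = e.start + s, e.start + t
            interior = gs > first_start and ge < last_end
            boundary = ge >= e.end or gs <= e.start  # touches a segment end
            if interior or boundary:
                cut.append((gs, ge))
    if not cut:
        return candidate
    exon_pairs = [(e.start, e.end) for e in candidate.exons]
    new_pairs = [
        (s, e)
        for s, e in subtract_pairs(exon_pairs, cut)
        if e - s > 0
    ]
    if not new_pairs:
        return None
    return replace(
        candidate,
        exons=[
            GenomeInterval(candidate.chrom, s, e, candidate.strand)
            for s, e in new_pairs
        ],
    )


# ---------------------------------------------------------------------------
# monoexonic path


@dataclass
class MonoexonicCandidate:
    region: GenomeInterval
    strand: str
    mean_depth: float
    survival: float = float("nan")  # Pr(>) within the monoexonic population


def monoexonic_regions(
    islands_by_sample: Mapping[str, Sequence[IslandOfExpression]],
    tracks_by_sample: Mapping[str, CoverageTrack],
) -> list[MonoexonicCandidate]:
    """Cross-sample intersection of junction-free islands (no ranking yet).

    Overlapping junction-free islands are grouped across samples; a group
    present in every sample yields the intersection of its per-sample
    regions, with length-normalised coverage c = pooled depth over the
    region / region length (averaged over samples).
    """
    samples = sorted(islands_by_sample)
    if len(samples) < 2:
        raise ValueError("monoexonic path requires >= 2 samples")
    tagged = [
        (isl, s) for s in samples for isl in islands_by_sample[s]
    ]
    if not tagged:
        return []
    tagged.sort(key=lambda t: (t[0].interval.start, t[0].interval.end))
    # group overlapping islands (transitively)
    groups: list[list[tuple[IslandOfExpression, str]]] = []
    cur: list[tuple[IslandOfExpression, str]] = []
    cur_end = -1
    for isl, s in tagged:
        if cur and isl.interval.start < cur_end:
            cur.append((isl, s))
            cur_end = max(cur_end, isl.interval.end)
        else:
            if cur:
                groups.append(cur)
            cur = [(isl, s)]
            cur_end = isl.interval.end
    if cur:
        groups.append(cur)

    candidates: list[MonoexonicCandidate] = []
    for grp in groups:
        per_sample: dict[str, list[tuple[int, int]]] = {}
        for isl, s in grp:
            per_sample.setdefault(s, []).append(
                (isl.interval.start, isl.interval.end)
            )
        if set(per_sample) != set(samples):
            continue  # not present in all samples
        region = per_sample[samples[0]]
        for s in samples[1:]:
            region = intersect_pairs(region, per_sample[s])
            if not region:
                break
        if not region:
            continue
        # the intersection of overlapping intervals is a single interval
        rs, re = region[0][0], region[-1][1]
        chrom = grp[0][0].interval.chrom
        strand = grp[0][0].strand
        pooled = sum(
            float(tracks_by_sample[s].depth[rs:re].sum()) for s in samples
        )
        c = pooled / (re - rs) / len(samples)
        candidates.append(
            MonoexonicCandidate(
                GenomeInterval(chrom, rs, re, strand), strand, c
            )
        )
    return candidates


def rank_monoexonic(
    candidates: Sequence[MonoexonicCandidate], pr_cutoff: float = 0.1
) -> list[MonoexonicCandidate]:
    """Keep candidates whose coverage sits in the population's upper tail.

    The empirical upper-tail probability Pr(>) = #{c' > c}/N is computed over
    the *whole* monoexonic candidate population; a candidate survives iff
    Pr(>) < ``pr_cutoff`` (the top decile at the default 0.1). Equal coverage
    values share the same survival value.
    """
    if not candidates:
        return []
    values = np.array([c.mean_depth for c in candidates])
    n = len(values)
    kept = []
    for cand in candidates:
        surv = float((values > cand.mean_depth).sum()) / n
        cand.survival = surv
        if surv < pr_cutoff:
            kept.append(cand)
    return kept


def monoexonic_pipeline(
    islands_by_sample: Mapping[str, Sequence[IslandOfExpression]],
    tracks_by_sample: Mapping[str, CoverageTrack],
    pr_cutoff: float = 0.1,
) -> list[MonoexonicCandidate]:
    """Cross-sample monoexonic path: region intersection then Pr(>) filter."""
    return rank_monoexonic(
        monoexonic_regions(islands_by_sample, tracks_by_sample), pr_cutoff
    )


# ---------------------------------------------------------------------------
# sample merging


@dataclass
class MergedGene:
    candidate: TranscriptCandidate
    presence: dict[str, bool]  # condition -> present in all replicates
    junctions: list[SpliceJunction] = field(default_factory=list)


def merge_samples(
    per_sample: Mapping[str, Sequence[TranscriptCandidate]],
    sample_condition: Mapping[str, str],
    junctions_by_sample: Mapping[str, Sequence[SpliceJunction]] | None = None,
    params: AssemblyParams | None = None,
) -> list[MergedGene]:
    """Union overlapping same-strand per-sample candidates into gene models.

    Same-strand candidates sharing >= 1 exonic bp merge; the merged exon set
    is reconstructed by subtracting consensus introns (recomputed on the
    pooled junctions of the contributing samples) from the hull of the
    pooled exons, falling back to the plain exon union when no junctions
    are available. Each merged gene records, per condition, whether some
    contributing candidate came from every replicate of that condition;
    genes present in no complete condition are dropped.
    """
    p = params or AssemblyParams()
    items: list[tuple[str, TranscriptCandidate]] = []
    for s in sorted(per_sample):
        for c in per_sample[s]:
            items.append((s, c))
    if not items:
        return []
    # group by (chrom, strand), then exonic-overlap connected components
    by_key: dict[tuple[str, str], list[tuple[str, TranscriptCandidate]]] = {}
    for s, c in items:
        by_key.setdefault((c.chrom, c.strand), []).append((s, c))

    conditions = sorted(set(sample_condition.values()))
    replicates = {
        cond: sorted(s for s, cc in sample_condition.items() if cc == cond)
        for cond in conditions
    }

    merged: list[MergedGene] = []
    for key in sorted(by_key):
        group = sorted(
            by_key[key], key=lambda t: (t[1].span.start, t[1].span.end, t[0])
        )
        n = len(group)
        uf = _UnionFind(n)
        for i in range(n):
            for j in range(i + 1, n):
                if group[j][1].span.start >= group[i][1].span.end:
                    break
                a = [(e.start, e.end) for e in group[i][1].exons]
                b = [(e.start, e.end) for e in group[j][1].exons]
                if intersect_pairs(a, b):
                    uf.union(i, j)
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(uf.find(i), []).append(i)
        for root in sorted(comps):
            members = [group[i] for i in comps[root]]
            chrom, strand = key
            exon_union = merge_pairs(
                [(e.start, e.end) for _, c in members for e in c.exons]
            )
            member_samples = {s for s, _ in members}
            pooled_sjs: list[SpliceJunction] = []
            if junctions_by_sample:
                span_s = exon_union[0][0]
                span_e = exon_union[-1][1]
                seen = set()
                for s in sorted(member_samples):
                    for sj in junctions_by_sample.get(s, []):
                        if (
                            sj.strand == strand
                            and sj.intron.chrom == chrom
                            and span_s <= sj.intron.start
                            and sj.intron.end <= span_e
                        ):
                            k = (sj.intron.start, sj.intron.end, sj.unique_reads)
                            if k not in seen:
                                seen.add(k)
                                pooled_sjs.append(sj)
            if pooled_sjs:
                introns = consensus_introns(
                    pooled_sjs, p.consensus_fraction, p.z_min_intron
                )
                hull = [(exon_union[0][0], exon_union[-1][1])]
                pieces = subtract_pairs(hull, introns)
                exons = []
                for s0, e0 in pieces:
                    covered = intersect_pairs([(s0, e0)], exon_union)
                    if covered:
                        exons.append((covered[0][0], covered[-1][1]))
            else:
                exons = exon_union
            if not exons:
                continue
            presence = {}
            for cond in conditions:
                reps = replicates[cond]
                presence[cond] = bool(reps) and all(
                    s in member_samples for s in reps
                )
            if not any(presence.values()):
                continue
            cand = TranscriptCandidate(
                id=f"merged:{chrom}:{exons[0][0]}-{exons[-1][1]}({strand})",
                chrom=chrom,
                strand=strand,
                exons=[GenomeInterval(chrom, s0, e0, strand) for s0, e0 in exons],
            )
            cand.source_samples = member_samples
            merged.append(MergedGene(cand, presence, pooled_sjs))
    merged.sort(
        key=lambda m: (m.candidate.chrom, m.candidate.span.start, m.candidate.strand)
    )
    return merged
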