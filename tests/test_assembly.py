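"""Assembly stages: junction filtering, clustering, consensus introns,
exon reconstruction, z-score refinement, monoexonic path and merging."""

import numpy as np
import pytest

from lncisland.annotation_mask import build_mask
from lncisland.assembly import (
    AssemblyParams,
    cluster_islands,
    consensus_introns,
    filter_junctions,
    merge_samples,
    monoexonic_pipeline,
    rank_monoexonic,
    subtract_introns,
    zscore_breakpoints,
    MonoexonicCandidate,
    IslandCluster,
)
from lncisland.coverage import CoverageTrack
from lncisland.intervals import (
    GeneModel,
    GenomeInterval,
    SpliceJunction,
    TranscriptCandidate,
)
from lncisland.ioe_detection import IslandOfExpression


def sj(start, end, reads=5, strand="+", annotated=False, chrom="c"):
    return SpliceJunction(
        GenomeInterval(chrom, start, end, strand), strand, reads, annotated
    )


def island(start, end, strand="+", sample="s1", chrom="c", mean=10.0):
    return IslandOfExpression(
        GenomeInterval(chrom, start, end, strand), strand, mean, int(mean), sample
    )


# ---------------------------------------------------------------------------
# junction filter


@pytest.mark.parametrize(
    "reads,kept", [(1, False), (2, False), (3, True), (4, True)]
)
def test_junction_support_strictly_greater_than_two(reads, kept):
    out = filter_junctions([sj(1000, 2000, reads)])
    assert bool(out) == kept


@pytest.mark.parametrize(
    "length,kept",
    [(19, False), (20, False), (21, True), (99_999, True), (100_000, False), (100_001, False)],
)
def test_junction_length_bounds_exclusive(length, kept):
    out = filter_junctions([sj(1000, 1000 + length)])
    assert bool(out) == kept


def test_masked_and_annotated_junctions_removed():
    g = GeneModel(
        "g", "pc", "+", GenomeInterval("c", 5000, 9000, "+"),
        [GenomeInterval("c", 5000, 9000, "+")],
    )
    mask = build_mask([g], flank=0)
    inside = sj(6000, 7000)
    outside = sj(20_000, 21_000)
    assert filter_junctions([inside, outside], mask=mask) == [outside]
    annotated = sj(1000, 2000, annotated=True)
    p = AssemblyParams(novel_only=True)
    assert filter_junctions([annotated], p) == []
    assert filter_junctions([annotated]) == [annotated]


# ---------------------------------------------------------------------------
# clustering


def test_junction_links_two_islands():
    a, b = island(0, 150), island(300, 450)
    clusters = cluster_islands([a, b], [sj(150, 300)])
    assert len(clusters) == 1
    assert len(clusters[0].islands) == 2
    assert clusters[0].junctions


def test_chain_clusters_transitively():
    a, b, c = island(0, 150), island(300, 450), island(600, 750)
    clusters = cluster_islands([a, b, c], [sj(150, 300), sj(450, 600)])
    assert len(clusters) == 1 and len(clusters[0].islands) == 3


def test_unconnected_islands_stay_singletons():
    clusters = cluster_islands([island(0, 150), island(5000, 5200)], [])
    assert len(clusters) == 2
    assert all(not c.junctions for c in clusters)


def _warshall_components(n, edges):
    reach = [[i == j for j in range(n)] for i in range(n)]
    for a, b in edges:
        reach[a][b] = reach[b][a] = True
    for k in range(n):
        for i in range(n):
            for j in range(n):
                reach[i][j] = reach[i][j] or (reach[i][k] and reach[k][j])
    comps = {}
    for i in range(n):
        root = min(j for j in range(n) if reach[i][j])
        comps.setdefault(root, set()).add(i)
    return sorted(frozenset(v) for v in comps.values())


def test_components_match_transitive_closure_oracle():
    rng = np.random.default_rng(2024)
    tol = 10
    for _ in range(500):
        n = int(rng.integers(2, 13))
        # islands on a grid; occasionally overlapping (multi-sample)
        starts = np.cumsum(rng.integers(50, 400, size=n)) + 1000
        isl = []
        for i, s in enumerate(starts):
            ln = int(rng.integers(60, 200))
            shift = int(rng.integers(-20, 20)) if rng.random() < 0.3 else 0
            isl.append(island(int(s) + shift, int(s) + shift + ln, sample=f"s{i%3}"))
        junctions = []
        for _ in range(int(rng.integers(0, n))):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            a, b = sorted((int(i), int(j)))
            d = isl[a].interval.end + int(rng.integers(-tol, tol))
            acc = isl[b].interval.start - int(rng.integers(-tol, tol))
            if acc - d >= 21:
                junctions.append(sj(d, acc))
        clusters = cluster_islands(isl, junctions, tol)
        got = sorted(
            frozenset(
                next(k for k, x in enumerate(isl) if x is m) for m in c.islands
            )
            for c in clusters
        )
        # independent edge derivation + Warshall closure
        edges = []
        for a in range(len(isl)):
            for b in range(a + 1, len(isl)):
                ia, ib = isl[a].interval, isl[b].interval
                if ia.start < ib.end and ib.start < ia.end:
                    edges.append((a, b))
        for j in junctions:
            donors = [
                k for k, x in enumerate(isl)
                if x.interval.start - tol <= j.intron.start <= x.interval.end + tol
            ]
            acceptors = [
                k for k, x in enumerate(isl)
                if x.interval.start - tol <= j.intron.end <= x.interval.end + tol
            ]
            edges.extend(
                (min(a, b), max(a, b)) for a in donors for b in acceptors if a != b
            )
        assert got == _warshall_components(len(isl), edges)


# ---------------------------------------------------------------------------
# consensus introns


def test_single_junction_is_its_own_consensus():
    assert consensus_introns([sj(150, 300)]) == [(150, 300)]
    assert consensus_introns([sj(150, 300), sj(150, 300)]) == [(150, 300)]


def test_majority_segment_rule():
    # segment [100,200) covered by 3/3 junctions; [200,300) by 1/3 -> dropped
    js = [sj(100, 200), sj(100, 200), sj(100, 300)]
    assert consensus_introns(js) == [(100, 200)]


def test_disjoint_junction_blocks_are_independent():
    js = [sj(100, 200), sj(100, 200), sj(500, 700)]
    assert consensus_introns(js) == [(100, 200), (500, 700)]


def test_consensus_respects_min_intron_length():
    js = [sj(100, 119), sj(100, 119)]  # 19 bp segment
    assert consensus_introns(js, min_intron=20) == []


def test_empty_junction_set_gives_no_introns():
    assert consensus_introns([]) == []


# ---------------------------------------------------------------------------
# intron subtraction


def _cluster(island_pairs, junctions=(), strand="+"):
    return IslandCluster(
        islands=[island(s, e, strand) for s, e in island_pairs],
        junctions=list(junctions),
        strand=strand,
        chrom="c",
    )


def test_subtraction_between_islands():
    c = _cluster([(0, 150), (300, 450)])
    cand = subtract_introns(c, [(150, 300)])
    assert [(e.start, e.end) for e in cand.exons] == [(0, 150), (300, 450)]


def test_subtraction_splits_single_island():
    c = _cluster([(0, 450)])
    cand = subtract_introns(c, [(150, 300)])
    assert [(e.start, e.end) for e in cand.exons] == [(0, 150), (300, 450)]


def test_subtraction_matches_position_set_oracle():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n_isl = int(rng.integers(1, 4))
        pairs = []
        pos = 0
        for _ in range(n_isl):
            pos += int(rng.integers(0, 50))
            ln = int(rng.integers(30, 150))
            pairs.append((pos, pos + ln))
            pos += ln
        span = (pairs[0][0], pairs[-1][1])
        introns = []
        for _ in range(int(rng.integers(0, 3))):
            s = int(rng.integers(span[0], span[1] - 25))
            introns.append((s, s + int(rng.integers(20, 60))))
        introns = sorted(set(introns))
        merged_introns = []
        for s, e in introns:
            if merged_introns and s <= merged_introns[-1][1]:
                merged_introns[-1] = (merged_introns[-1][0], max(e, merged_introns[-1][1]))
            else:
                merged_introns.append((s, e))
        c = _cluster(pairs)
        try:
            cand = subtract_introns(c, merged_introns)
        except ValueError:
            # oracle: hull minus introns has no island-supported bp
            hull = set(range(*span))
            cut = {p for s, e in merged_introns for p in range(s, e)}
            support = {p for s, e in pairs for p in range(s, e)}
            assert not ((hull - cut) & support)
            continue
        got = {p for e in cand.exons for p in range(e.start, e.end)}
        # oracle: each hull-minus-intron piece trimmed to supported ends
        hull_pieces = []
        cur = span[0]
        for s, e in merged_introns:
            s, e = max(s, span[0]), min(e, span[1])
            if s > cur:
                hull_pieces.append((cur, s))
            cur = max(cur, e)
        if cur < span[1]:
            hull_pieces.append((cur, span[1]))
        support = {p for s, e in pairs for p in range(s, e)}
        want = set()
        for s, e in hull_pieces:
            inside = [p for p in range(s, e) if p in support]
            if inside:
                want |= set(range(min(inside), max(inside) + 1))
        assert got == want


# ---------------------------------------------------------------------------
# z-score breakpoints


def test_constant_depth_has_no_breakpoints():
    bp = zscore_breakpoints(np.full(500, 30.0))
    assert bp == {"drops": [], "peaks": []}


def test_step_drop_becomes_one_intron():
    d = np.full(500, 50.0)
    d[200:240] = 0.0  # 40-bp gap
    bp = zscore_breakpoints(d)
    assert len(bp["drops"]) == 1
    s, e = bp["drops"][0]
    assert s <= 210 and e >= 230  # contains the gap interior


def test_short_dip_below_min_intron_ignored():
    d = np.full(500, 50.0)
    d[200:210] = 0.0  # 10 bp < min intron 20
    assert zscore_breakpoints(d)["drops"] == []


@pytest.mark.parametrize("dip,flagged", [(5.0, False), (6.0, True)])
def test_drop_threshold_boundary_on_flat_signal(dip, flagged):
    # flat signal: s = 0 -> floor 1; deviation must exceed threshold * 1
    d = np.full(300, 100.0)
    d[150:180] = 100.0 - dip
    drops = zscore_breakpoints(d)["drops"]
    assert bool(drops) == flagged


@pytest.mark.parametrize("gap,expect", [(19, False), (20, True), (21, True)])
def test_min_intron_boundary(gap, expect):
    d = np.full(400, 60.0)
    d[200 : 200 + gap] = 0.0
    assert bool(zscore_breakpoints(d)["drops"]) == expect


def test_window_must_be_odd():
    AssemblyParams(z_window=31)
    with pytest.raises(ValueError):
        AssemblyParams(z_window=30)
    with pytest.raises(ValueError):
        AssemblyParams(z_window=32)


def test_segment_shorter_than_window_passes_through():
    assert zscore_breakpoints(np.zeros(10)) == {"drops": [], "peaks": []}


def test_peak_detection_flags_spikes():
    d = np.full(300, 10.0)
    d[200:205] = 200.0
    assert zscore_breakpoints(d)["peaks"]


# ---------------------------------------------------------------------------
# monoexonic path


def _tracks(n=2, length=1000, depth=20, chrom="c", strand="+"):
    return {
        f"s{i+1}": CoverageTrack(chrom, strand, np.full(length, depth))
        for i in range(n)
    }


def test_monoexonic_region_is_cross_sample_intersection():
    islands = {
        "s1": [island(0, 200, sample="s1")],
        "s2": [island(50, 250, sample="s2")],
    }
    out = monoexonic_pipeline(islands, _tracks(), pr_cutoff=1.1)
    assert len(out) == 1
    assert (out[0].region.start, out[0].region.end) == (50, 200)


def test_monoexonic_requires_presence_in_every_sample():
    islands = {"s1": [island(0, 200, sample="s1")], "s2": []}
    assert monoexonic_pipeline(islands, _tracks(), pr_cutoff=1.1) == []


def test_non_overlapping_islands_across_samples_discarded():
    islands = {
        "s1": [island(0, 200, sample="s1")],
        "s2": [island(5000, 5200, sample="s2")],
    }
    assert monoexonic_pipeline(islands, _tracks(length=6000), pr_cutoff=1.1) == []


def test_pr_rank_filter_keeps_top_decile():
    cands = [
        MonoexonicCandidate(GenomeInterval("c", i * 100, i * 100 + 50), "+", float(i))
        for i in range(100)
    ]
    kept = rank_monoexonic(cands, 0.1)
    # rank k from the top (k=0 highest) has Pr(>) = k/100; k <= 9 survives
    assert sorted(c.mean_depth for c in kept) == [float(v) for v in range(90, 100)]
    assert len(kept) == 10


@pytest.mark.parametrize("n,kept_expected", [(10, 1)])
def test_pr_boundary_exactly_point_one_excluded(n, kept_expected):
    cands = [
        MonoexonicCandidate(GenomeInterval("c", i * 100, i * 100 + 50), "+", float(i))
        for i in range(n)
    ]
    kept = rank_monoexonic(cands, 0.1)
    # rank-1 candidate has Pr(>) = 1/10 = 0.1, not < 0.1
    assert len(kept) == kept_expected
    assert kept[0].mean_depth == float(n - 1)


# ---------------------------------------------------------------------------
# merging


def _cand(cid, exon_pairs, strand="+", chrom="c"):
    return TranscriptCandidate(
        id=cid,
        chrom=chrom,
        strand=strand,
        exons=[GenomeInterval(chrom, s, e, strand) for s, e in exon_pairs],
    )


COND = {"a1": "A", "a2": "A", "a3": "A", "a4": "A", "b1": "B", "b2": "B", "b3": "B", "b4": "B"}


def test_candidate_in_all_replicates_is_present():
    per_sample = {s: [_cand(f"x_{s}", [(0, 300)])] for s in ("a1", "a2", "a3", "a4")}
    per_sample.update({s: [] for s in ("b1", "b2", "b3", "b4")})
    merged = merge_samples(per_sample, COND)
    assert len(merged) == 1
    assert merged[0].presence == {"A": True, "B": False}


def test_candidate_in_three_of_four_replicates_dropped():
    per_sample = {s: [_cand(f"x_{s}", [(0, 300)])] for s in ("a1", "a2", "a3")}
    per_sample.update({s: [] for s in ("a4", "b1", "b2", "b3", "b4")})
    assert merge_samples(per_sample, COND) == []


def test_overlapping_candidates_union_exons():
    per_sample = {
        "a1": [_cand("p", [(0, 200), (400, 600)])],
        "a2": [_cand("q", [(100, 250), (400, 650)])],
    }
    cond = {"a1": "A", "a2": "A"}
    merged = merge_samples(per_sample, cond)
    assert len(merged) == 1
    got = {
        p
        for e in merged[0].candidate.exons
        for p in range(e.start, e.end)
    }
    want = (
        set(range(0, 200)) | set(range(400, 600))
        | set(range(100, 250)) | set(range(400, 650))
    )
    assert got == want


def test_merge_is_sample_order_independent():
    per_sample = {
        "a1": [_cand("p", [(0, 200)])],
        "a2": [_cand("q", [(100, 300)])],
    }
    cond = {"a1": "A", "a2": "A"}
    m1 = merge_samples(dict(sorted(per_sample.items())), cond)
    m2 = merge_samples(dict(sorted(per_sample.items(), reverse=True)), cond)
    assert [
        [(e.start, e.end) for e in m.candidate.exons] for m in m1
    ] == [[(e.start, e.end) for e in m.candidate.exons] for m in m2]


def test_same_strand_only_merging():
    per_sample = {
        "a1": [_cand("p", [(0, 200)], strand="+"), _cand("q", [(0, 200)], strand="-")],
        "a2": [_cand("r", [(0, 200)], strand="+"), _cand("s", [(0, 200)], strand="-")],
    }
    cond = {"a1": "A", "a2": "A"}
    merged = merge_samples(per_sample, cond)
    assert len(merged) == 2
    assert {m.candidate.strand for m in merged} == {"+", "-"}
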