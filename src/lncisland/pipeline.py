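"""End-to-end orchestration: evidence in, filtered novel-lncRNA GTF out.

Stage order: read annotation -> build strand masks -> per-sample island
detection on masked coverage -> junction filtering -> island clustering and
consensus-intron subtraction -> smoothed z-score refinement -> second pass
with an exon-union mask for intronic candidates -> cross-sample merge ->
monoexonic path -> context classification -> length / coding / consistency /
expression filters -> naming and GTF export. A run manifest records
parameters, input digests and per-stage feature counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_mask import StrandMask, build_mask, mask_coverage
from .assembly import (
    AssemblyParams,
    MergedGene,
    cluster_islands,
    consensus_introns,
    filter_junctions,
    merge_samples,
    monoexonic_regions,
    rank_monoexonic,
    refine_candidate,
    subtract_introns,
)
from .coverage import CoverageTrack, track_from_bedgraph
from .filtering import (
    AnnotationIndex,
    FilterParams,
    apply_filters,
    classify_context,
    coding_features,
    coding_probability,
    compute_fpkm,
    is_retained_intron,
    train_hexamer_table,
    train_logistic,
    transcript_sequence,
)
from .intervals import GenomeInterval, TranscriptCandidate, intersect_pairs, total_bp
from .io_formats import make_name, read_counts, read_gtf, read_sample_table, read_sj_tab, write_gtf
from .ioe_detection import find_islands
from .simulate import make_training_sets

log = logging.getLogger("lncisland")


@dataclass
class PipelineConfig:
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    filters: FilterParams = field(default_factory=FilterParams)
    flank: int = 1000
    fragment_span: int = 200  # read-pair footprint used to estimate fragments
    intronic_pass: bool = True
    seed: int = 0  # seeds the coding-model training only
    gtf_dialect: str = "ensembl"


@dataclass
class PipelineResult:
    candidates: list[TranscriptCandidate]
    discarded: dict[str, str]  # id -> first failing filter flag
    stage_counts: dict[str, int]
    manifest: dict


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_genome(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _assemble_sample(
    tracks: Mapping[tuple[str, str], CoverageTrack],
    junctions,
    mask: StrandMask,
    params: AssemblyParams,
    sample: str,
):
    """One sample, one mask mode: returns (multiexonic candidates,
    junction-free islands) across all (chrom, strand) units."""
    cands: list[TranscriptCandidate] = []
    lone_islands = []
    fj = filter_junctions(junctions, params, mask)
    for (chrom, strand) in sorted(tracks):
        track = tracks[(chrom, strand)]
        masked = mask_coverage(track, mask)
        islands = find_islands(
            masked, params.depth_threshold, params.min_island_length, sample
        )
        if not islands:
            continue
        sjs = [j for j in fj if j.intron.chrom == chrom and j.strand == strand]
        clusters = cluster_islands(islands, sjs, params.junction_tolerance)
        for ci, cluster in enumerate(clusters):
            if not cluster.junctions:
                for isl in cluster.islands:
                    lone_islands.append(isl)
                continue
            introns = consensus_introns(
                cluster.junctions, params.consensus_fraction, params.z_min_intron
            )
            try:
                cand = subtract_introns(
                    cluster, introns, f"{sample}:{chrom}:{strand}:{ci}"
                )
            except ValueError:
                continue
            refined = refine_candidate(cand, masked, params)
            if refined is not None and refined.exons:
                cands.append(refined)
    return cands, lone_islands, fj


def run_pipeline(
    annotation_gtf: str | Path,
    genome_fasta: str | Path,
    bedgraphs: Mapping[str, Mapping[str, str | Path]],  # sample -> {"+": f, "-": f}
    sj_tabs: Mapping[str, str | Path],
    counts_tsv: str | Path,
    samples_tsv: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    p = cfg.assembly
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for path in [annotation_gtf, genome_fasta, counts_tsv, samples_tsv, *sj_tabs.values()]:
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input: {path}")
    for files in bedgraphs.values():
        for f in files.values():
            if not Path(f).exists():
                raise FileNotFoundError(f"missing input: {f}")

    genes = read_gtf(annotation_gtf, cfg.gtf_dialect)
    genome = _load_genome(genome_fasta)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    index = AnnotationIndex(genes)
    span_mask = build_mask(genes, cfg.flank, "span")
    exon_mask = build_mask(genes, cfg.flank, "exon_union")
    log.info("annotation: %d gene models", len(genes))

    sample_table = read_sample_table(samples_tsv)
    counts = read_counts(counts_tsv)
    samples = sorted(bedgraphs)
    sample_condition = {s: str(sample_table.loc[s, "condition"]) for s in samples}
    library_sizes = {s: float(counts[s].sum()) for s in samples}

    stage_counts: dict[str, int] = {"annotated_genes": len(genes)}

    raw_tracks: dict[str, dict[tuple[str, str], CoverageTrack]] = {}
    per_sample_cands: dict[str, list[TranscriptCandidate]] = {}
    per_sample_junctions: dict[str, list] = {}
    lone_by_sample: dict[str, dict[tuple[str, str], list]] = {}
    n_islands = n_pass1 = n_pass2 = 0

    for sample in samples:
        tracks = {}
        for strand in "+-":
            path = bedgraphs[sample][strand]
            for chrom in sorted(chrom_lengths):
                tracks[(chrom, strand)] = track_from_bedgraph(
                    path, chrom, strand, chrom_lengths[chrom]
                )
        raw_tracks[sample] = tracks
        junctions = read_sj_tab(sj_tabs[sample])

        cands, lone, fj = _assemble_sample(tracks, junctions, span_mask, p, sample)
        n_pass1 += len(cands)
        n_islands += len(lone) + len(cands)
        per_sample_junctions[sample] = filter_junctions(junctions, p, exon_mask)
        lone_by_sample[sample] = {}
        for isl in lone:
            lone_by_sample[sample].setdefault(
                (isl.interval.chrom, isl.strand), []
            ).append(isl)

        if cfg.intronic_pass:
            cands2, _lone2, _ = _assemble_sample(tracks, junctions, exon_mask, p, sample)
            intronic = []
            for c in cands2:
                c = classify_context(c, index)
                if c.klass != "intronic":
                    continue
                if is_retained_intron(c, index, p.junction_tolerance):
                    continue
                intronic.append(c)
            n_pass2 += len(intronic)
            cands = cands + intronic
        per_sample_cands[sample] = cands
        log.info("%s: %d multiexonic candidates", sample, len(cands))

    stage_counts["per_sample_candidates"] = sum(map(len, per_sample_cands.values()))
    stage_counts["pass1_candidates"] = n_pass1
    stage_counts["pass2_intronic_candidates"] = n_pass2

    merged = merge_samples(
        per_sample_cands, sample_condition, per_sample_junctions, p
    )
    stage_counts["merged_genes"] = len(merged)

    # monoexonic path: regions per (chrom, strand), Pr(>) ranked over the
    # pooled monoexonic candidate population
    mono_merged: list[MergedGene] = []
    keys = sorted({k for d in lone_by_sample.values() for k in d})
    conditions = sorted(set(sample_condition.values()))
    mono_regions = []
    if len(samples) >= 2:
        for key in keys:
            islands_by_sample = {s: lone_by_sample[s].get(key, []) for s in samples}
            tracks_by_sample = {s: raw_tracks[s][key] for s in samples}
            mono_regions.extend(
                monoexonic_regions(islands_by_sample, tracks_by_sample)
            )
    for m in rank_monoexonic(mono_regions, p.monoexonic_pr_cutoff):
        cand = TranscriptCandidate(
            id=f"mono:{m.region.chrom}:{m.region.start}-{m.region.end}({m.strand})",
            chrom=m.region.chrom,
            strand=m.strand,
            exons=[m.region],
        )
        cand.source_samples = set(samples)
        mono_merged.append(MergedGene(cand, {c: True for c in conditions}, []))
    # drop monoexonic candidates subsumed by multiexonic merged genes
    def _overlaps_merged(c: TranscriptCandidate) -> bool:
        ce = [(e.start, e.end) for e in c.exons]
        for m in merged:
            if m.candidate.chrom == c.chrom and m.candidate.strand == c.strand:
                me = [(e.start, e.end) for e in m.candidate.exons]
                if intersect_pairs(ce, me):
                    return True
        return False

    mono_merged = [m for m in mono_merged if not _overlaps_merged(m.candidate)]
    stage_counts["monoexonic_kept"] = len(mono_merged)

    all_merged = merged + mono_merged
    all_merged.sort(
        key=lambda m: (m.candidate.chrom, m.candidate.span.start, m.candidate.strand)
    )

    # classification, expression, coding potential
    presence: dict[str, dict[str, bool]] = {}
    condition_fpkm: dict[str, dict[str, float]] = {}
    for i, m in enumerate(all_merged):
        c = m.candidate
        c.id = f"NOVEL{i + 1:05d}"
        classify_context(c, index)
        presence[c.id] = m.presence
        fpkm_by_cond: dict[str, list[float]] = {cond: [] for cond in conditions}
        for s in samples:
            track = raw_tracks[s][(c.chrom, c.strand)]
            frag = sum(
                float(track.depth[e.start : e.end].sum()) for e in c.exons
            ) / cfg.fragment_span
            fpkm_by_cond[sample_condition[s]].append(
                compute_fpkm(frag, c.length, library_sizes[s])
            )
        condition_fpkm[c.id] = {
            cond: float(np.mean(v)) for cond, v in fpkm_by_cond.items() if v
        }

    rng = np.random.default_rng(cfg.seed)
    coding_train, noncoding_train = make_training_sets(rng)
    hex_table = train_hexamer_table(coding_train, noncoding_train)
    model = train_logistic(
        [coding_features(s, hex_table) for s in coding_train],
        [coding_features(s, hex_table) for s in noncoding_train],
        cfg.filters.coding_cutoff,
    )
    coding_prob = {}
    for m in all_merged:
        seq = transcript_sequence(m.candidate, genome)
        coding_prob[m.candidate.id] = coding_probability(
            coding_features(seq, hex_table), model
        )

    kept, discarded = apply_filters(
        [m.candidate for m in all_merged],
        presence,
        condition_fpkm,
        coding_prob,
        cfg.filters,
    )
    stage_counts["final_candidates"] = len(kept)
    log.info("final: %d novel lncRNA gene models", len(kept))

    for c in kept:
        c.id = make_name(c)
    kept.sort(key=lambda c: (c.chrom, c.span.start, c.span.end, c.strand))

    final_gtf = out / "novel_lncRNAs.gtf"
    write_gtf(kept, final_gtf)
    report = pd.DataFrame(
        [
            {
                "id": c.id,
                "chrom": c.chrom,
                "start": c.span.start + 1,
                "end": c.span.end,
                "strand": c.strand,
                "class": c.klass,
                "closest_gene": c.closest_gene_id,
                "distance": c.distance_to_closest,
                "n_exons": c.n_exons,
                "length": c.length,
                "coding_probability": round(c.coding_probability, 6),
                "max_condition_fpkm": round(max(c.condition_fpkm.values()), 4),
            }
            for c in kept
        ]
    )
    report.to_csv(out / "novel_lncRNAs.tsv", sep="\t", index=False)

    manifest = {
        "parameters": {
            "assembly": asdict(cfg.assembly),
            "filters": asdict(cfg.filters),
            "flank": cfg.flank,
            "fragment_span": cfg.fragment_span,
            "seed": cfg.seed,
        },
        "inputs": {
            "annotation": _sha256(annotation_gtf),
            "genome": _sha256(genome_fasta),
            "counts": _sha256(counts_tsv),
            "sj": {s: _sha256(f) for s, f in sorted(sj_tabs.items())},
        },
        "stage_counts": stage_counts,
        "outputs": {"gtf": str(final_gtf)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(kept, discarded, stage_counts, manifest)


def run_on_simulated(sim_dir: str | Path, out_dir: str | Path,
                     config: PipelineConfig | None = None) -> PipelineResult:
    """Run the pipeline on a directory produced by :func:`simulate_all`."""
    sim = Path(sim_dir)
    samples = sorted(p.name.split(".")[0] for p in sim.glob("*.SJ.out.tab"))
    bedgraphs = {
        s: {"+": sim / f"{s}.plus.bedgraph", "-": sim / f"{s}.minus.bedgraph"}
        for s in samples
    }
    sj_tabs = {s: sim / f"{s}.SJ.out.tab" for s in samples}
    return run_pipeline(
        sim / "annotation.gtf",
        sim / "genome.fa",
        bedgraphs,
        sj_tabs,
        sim / "counts.tsv",
        sim / "samples.tsv",
        out_dir,
        config,
    )


# ---------------------------------------------------------------------------
# truth evaluation


def _reciprocal_match(a: TranscriptCandidate, b: TranscriptCandidate, frac: float) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    ov = total_bp(
        intersect_pairs(
            [(e.start, e.end) for e in a.exons], [(e.start, e.end) for e in b.exons]
        )
    )
    return ov >= frac * a.length and ov >= frac * b.length


def evaluate_against_truth(
    candidates: list[TranscriptCandidate],
    truth: list[TranscriptCandidate],
    decoys: list[TranscriptCandidate] | None = None,
    min_reciprocal_overlap: float = 0.5,
) -> dict:
    """Gene-level recall/precision at reciprocal exonic overlap, class-label
    agreement on matches, and decoy-removal rate."""
    decoys = decoys or []
    matched_truth: dict[str, TranscriptCandidate] = {}
    decoy_hit: set[str] = set()
    cand_state: dict[str, str] = {}
    for c in candidates:
        hit = next(
            (t for t in truth if _reciprocal_match(c, t, min_reciprocal_overlap)),
            None,
        )
        if hit is not None:
            matched_truth[hit.id] = c
            cand_state[c.id] = "true_positive"
            continue
        if any(_reciprocal_match(c, d, min_reciprocal_overlap) for d in decoys):
            decoy_hit.add(c.id)
            cand_state[c.id] = "decoy"
        else:
            cand_state[c.id] = "false_positive"

    non_decoy = [c for c in candidates if cand_state[c.id] != "decoy"]
    tp = sum(1 for c in non_decoy if cand_state[c.id] == "true_positive")
    recall = len(matched_truth) / len(truth) if truth else float("nan")
    precision = tp / len(non_decoy) if non_decoy else float("nan")
    agree = sum(
        1 for tid, c in matched_truth.items()
        if c.klass == next(t for t in truth if t.id == tid).klass
    )
    class_agreement = agree / len(matched_truth) if matched_truth else float("nan")
    decoy_removal = (
        1.0 - len(decoy_hit) / len(decoys) if decoys else float("nan")
    )
    return {
        "recall": recall,
        "precision": precision,
        "class_agreement": class_agreement,
        "decoy_removal": decoy_removal,
        "n_truth": len(truth),
        "n_candidates": len(candidates),
        "n_true_positives": tp,
        "n_decoys_retained": len(decoy_hit),
    }
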