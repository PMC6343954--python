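"""Synthetic fixtures with planted ground truth.

Generates a toy genome, a protein-coding annotation, stranded per-sample
coverage (bedGraph), STAR-style splice-junction files, a count matrix with
condition labels and a DE table, plus truth GTFs for the planted novel
lncRNAs and coding-like decoys. Everything is a deterministic function of
the seed.

What is emulated: novel lncRNAs expressed ~10x below protein-coding genes,
an exon-number distribution skewed to biexonic transcripts, strand-specific
plateau coverage over exons, junction support proportional to expression,
short sub-island background noise, and a population of weak monoexonic
transcriptional-noise islands against which the strong planted monoexonic
lncRNAs form the upper tail (the situation the Pr(>) rank filter is
designed for). What is not emulated: mappability/GC structure, soft-clip
junction jitter, isoform mixtures, sequencing errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomeInterval, TranscriptCandidate
from .io_formats import write_bedgraph, write_gtf

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# codon pool biased toward GC-rich mammalian-style usage, no stop codons
_CODING_CODONS = [
    "GCC", "GAG", "CTG", "AAG", "GAC", "ATC", "GTG", "ACC", "TTC", "GGC",
    "CAG", "AAC", "CCC", "AGC", "TAC", "CGC", "CAC", "ATG", "TGC", "GAT",
]
_STOP = "TGA"


@dataclass
class SimulationConfig:
    seed: int = 7
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_coding_genes: int = 40
    n_antisense: int = 6
    n_intergenic: int = 12
    n_intronic: int = 6
    n_monoexonic: int = 6
    n_noise_monoexonic: int = 54  # weak monoexonic background population
    n_decoys: int = 3  # coding-like planted transcripts
    depth_range: tuple[int, int] = (20, 50)
    junction_support_range: tuple[int, int] = (5, 15)
    n_samples_per_condition: int = 3
    n_conditions: int = 2
    noise_runs_per_mb: int = 20  # sub-island-length background runs
    read_length: int = 100
    coding_base_mean: float = 500.0  # NB mean counts for coding genes
    lnc_expression_ratio: float = 0.1  # lncRNA mean = ratio * coding mean
    nb_dispersion: float = 0.1
    fraction_antisense_flipped: float = 0.5
    n_condition_specific: int = 2  # intergenic lncRNAs expressed in cond 1 only

    @property
    def n_planted(self) -> int:
        return self.n_antisense + self.n_intergenic + self.n_intronic + self.n_monoexonic

    @property
    def samples(self) -> list[str]:
        return [
            f"cond{c + 1}_rep{r + 1}"
            for c in range(self.n_conditions)
            for r in range(self.n_samples_per_condition)
        ]

    @property
    def sample_condition(self) -> dict[str, str]:
        return {s: s.split("_")[0] for s in self.samples}


@dataclass
class _Feature:
    """A planted expressed unit (gene, lncRNA, decoy or noise island)."""

    fid: str
    kind: str  # coding | antisense | intergenic | intronic | monoexonic | noise | decoy
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    depth_target: float
    sj_support: int = 0
    annotated_sj: bool = False
    conditions: tuple[str, ...] = ()  # empty = expressed in all
    log2fc: float = 0.0
    padj: float = 1.0

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]) if b[0] > a[1]
        ]

    def as_candidate(self, klass: str | None = None) -> TranscriptCandidate:
        return TranscriptCandidate(
            id=self.fid,
            chrom=self.chrom,
            strand=self.strand,
            exons=[GenomeInterval(self.chrom, s, e, self.strand) for s, e in self.exons],
            klass=klass or self.kind,
        )


@dataclass
class Reference:
    config: SimulationConfig
    chrom_lengths: dict[str, int]
    genome: dict[str, str]
    genes: list[GeneModel]
    features: list[_Feature] = field(default_factory=list)

    @property
    def planted(self) -> list[_Feature]:
        return [
            f
            for f in self.features
            if f.kind in ("antisense", "intergenic", "intronic", "monoexonic")
        ]

    @property
    def decoys(self) -> list[_Feature]:
        return [f for f in self.features if f.kind == "decoy"]


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _orf_sequence(rng: np.random.Generator, total: int, orf_codons: int) -> str:
    """ATG + biased codons + stop, padded to ``total`` with random flanks."""
    orf = "ATG" + "".join(
        rng.choice(_CODING_CODONS) for _ in range(orf_codons)
    ) + _STOP
    pad = total - len(orf)
    if pad < 0:
        raise ValueError("ORF longer than transcript")
    left = pad // 3  # short 5' UTR, longer 3' UTR
    right = pad - left
    flank = lambda n: "".join(chr(b[0]) for b in _rand_seq(rng, n)) if n else ""
    return flank(left) + orf + flank(right)


_COMP = str.maketrans("ACGT", "TGCA")


def _write_transcript_seq(
    genome: dict[str, bytearray], feat: _Feature, seq: str
) -> None:
    """Write a transcript sequence into the genome across the feature's exons
    (reverse-complemented for minus-strand features)."""
    if feat.strand == "-":
        seq = seq.translate(_COMP)[::-1]
    pos = 0
    g = genome[feat.chrom]
    for s, e in feat.exons:
        g[s:e] = seq[pos : pos + (e - s)].encode()
        pos += e - s


def simulate_reference(config: SimulationConfig | None = None) -> Reference:
    """Build genome, annotation and planted features (deterministic in seed)."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome = {c: bytearray(_rand_seq(rng, cfg.chrom_length).tobytes()) for c in chroms}

    slot = 13_000
    margin = 2_000
    slots_per_chrom = (cfg.chrom_length - 2 * margin) // slot
    all_slots = [
        (c, margin + i * slot) for c in chroms for i in range(slots_per_chrom)
    ]
    need = (
        cfg.n_coding_genes
        + cfg.n_intergenic
        + cfg.n_monoexonic
        + cfg.n_noise_monoexonic
        + cfg.n_decoys
    )
    if need > len(all_slots):
        raise ValueError(
            f"cannot place {need} features in {len(all_slots)} slots; "
            "increase chrom_length or n_chromosomes"
        )
    order = rng.permutation(len(all_slots))
    slot_iter = iter([all_slots[i] for i in order])

    features: list[_Feature] = []
    genes: list[GeneModel] = []

    def depth() -> float:
        return float(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))

    def support() -> int:
        lo, hi = cfg.junction_support_range
        return int(rng.integers(lo, hi + 1))

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    def make_exons(
        start: int, n_exons: int, exon_len: tuple[int, int], intron_len: tuple[int, int]
    ) -> list[tuple[int, int]]:
        exons = []
        pos = start
        for i in range(n_exons):
            ln = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exons.append((pos, pos + ln))
            pos += ln
            if i < n_exons - 1:
                pos += int(rng.integers(intron_len[0], intron_len[1] + 1))
        return exons

    # --- coding genes; the first n_antisense host antisense lncRNAs and the
    # next n_intronic carry a wide intron hosting an intronic lncRNA
    for gi in range(cfg.n_coding_genes):
        chrom, start = next(slot_iter)
        st = strand()
        if gi < cfg.n_antisense:
            exons = make_exons(start, 3, (250, 400), (600, 1500))
            role = "antisense_host"
        elif gi < cfg.n_antisense + cfg.n_intronic:
            pos = start
            e1 = (pos, pos + int(rng.integers(250, 400)))
            gap = int(rng.integers(2400, 3200))
            e2s = e1[1] + gap
            e2 = (e2s, e2s + int(rng.integers(250, 400)))
            exons = [e1, e2]
            role = "intronic_host"
        else:
            n_ex = int(rng.integers(3, 6))
            exons = make_exons(start, n_ex, (150, 400), (300, 1200))
            role = "plain"
        total = sum(e - s for s, e in exons)
        total -= total % 3
        # trim last exon so the exon chain length is a codon multiple
        exons[-1] = (exons[-1][0], exons[-1][0] + (total - sum(e - s for s, e in exons[:-1])))
        gid = f"GENE{gi + 1:04d}"
        feat = _Feature(
            fid=gid,
            kind="coding",
            chrom=chrom,
            strand=st,
            exons=exons,
            depth_target=depth(),
            sj_support=support() * 3,
            annotated_sj=True,
        )
        feat.role = role  # type: ignore[attr-defined]
        features.append(feat)
        orf_codons = (total - 6) // 3
        _write_transcript_seq(genome, feat, _orf_sequence(rng, total, orf_codons))
        genes.append(
            GeneModel(
                gid,
                "protein_coding",
                st,
                GenomeInterval(chrom, exons[0][0], exons[-1][1], st),
                [GenomeInterval(chrom, s, e, st) for s, e in exons],
            )
        )

    hosts_as = [f for f in features if getattr(f, "role", "") == "antisense_host"]
    hosts_in = [f for f in features if getattr(f, "role", "") == "intronic_host"]

    # --- antisense lncRNAs: opposite strand, first exon overlapping a host exon
    for i in range(cfg.n_antisense):
        host = hosts_as[i]
        opp = "-" if host.strand == "+" else "+"
        he = host.exons[1]
        e1 = (he[0] - 60, he[1] + 40)
        intron = int(rng.integers(250, 500))
        e2s = e1[1] + intron
        e2 = (e2s, e2s + int(rng.integers(200, 350)))
        features.append(
            _Feature(
                fid=f"lnc_antisense_{i + 1}",
                kind="antisense",
                chrom=host.chrom,
                strand=opp,
                exons=[e1, e2],
                depth_target=depth(),
                sj_support=support(),
            )
        )

    # --- intronic lncRNAs: inside the host's wide intron, same strand,
    # ends well clear of the intron boundaries (not a retained intron)
    for i in range(cfg.n_intronic):
        host = hosts_in[i]
        intron_s, intron_e = host.exons[0][1], host.exons[1][0]
        s = intron_s + 150
        e1 = (s, s + int(rng.integers(200, 300)))
        gap = int(rng.integers(250, 400))
        e2s = e1[1] + gap
        e2 = (e2s, e2s + int(rng.integers(200, 300)))
        if e2[1] > intron_e - 150:
            raise RuntimeError("intronic lncRNA does not fit host intron")
        features.append(
            _Feature(
                fid=f"lnc_intronic_{i + 1}",
                kind="intronic",
                chrom=host.chrom,
                strand=host.strand,
                exons=[e1, e2],
                depth_target=depth(),
                sj_support=support(),
            )
        )

    # --- intergenic lncRNAs (biexonic-skewed exon counts)
    exon_counts = [2] * 7 + [3] * 4 + [4] * 1
    for i in range(cfg.n_intergenic):
        chrom, start = next(slot_iter)
        n_ex = exon_counts[i % len(exon_counts)]
        exons = make_exons(start, n_ex, (200, 500), (300, 900))
        conds = ()
        if i < cfg.n_condition_specific:
            conds = ("cond1",)
        features.append(
            _Feature(
                fid=f"lnc_intergenic_{i + 1}",
                kind="intergenic",
                chrom=chrom,
                strand=strand(),
                exons=exons,
                depth_target=depth(),
                sj_support=support(),
                conditions=conds,
            )
        )

    # --- monoexonic lncRNAs (strong) and the weak monoexonic noise population
    for i in range(cfg.n_monoexonic):
        chrom, start = next(slot_iter)
        ln = int(rng.integers(300, 800))
        features.append(
            _Feature(
                fid=f"lnc_monoexonic_{i + 1}",
                kind="monoexonic",
                chrom=chrom,
                strand=strand(),
                exons=[(start, start + ln)],
                depth_target=depth(),
            )
        )
    for i in range(cfg.n_noise_monoexonic):
        chrom, start = next(slot_iter)
        ln = int(rng.integers(150, 300))
        features.append(
            _Feature(
                fid=f"noise_mono_{i + 1}",
                kind="noise",
                chrom=chrom,
                strand=strand(),
                exons=[(start, start + ln)],
                depth_target=4.0,
            )
        )

    # --- coding-like decoys: discoverable transcripts with a real ORF
    for i in range(cfg.n_decoys):
        chrom, start = next(slot_iter)
        exons = make_exons(start, 2, (450, 650), (300, 700))
        feat = _Feature(
            fid=f"decoy_{i + 1}",
            kind="decoy",
            chrom=chrom,
            strand=strand(),
            exons=exons,
            depth_target=depth(),
            sj_support=support(),
        )
        features.append(feat)
        total = sum(e - s for s, e in exons)
        orf_codons = int(total * 0.6) // 3 - 2
        _write_transcript_seq(genome, feat, _orf_sequence(rng, total, orf_codons))

    # --- condition effects for the DE table
    for i, f in enumerate(f for f in features if f.kind == "intergenic"):
        if i % 2 == 0:
            f.log2fc = float(rng.choice([-1.5, 1.5]))
            f.padj = 0.01
    n_flip = int(round(cfg.fraction_antisense_flipped * cfg.n_antisense))
    antisense = [f for f in features if f.kind == "antisense"]
    for i, f in enumerate(antisense):
        host = hosts_as[i]
        host.log2fc = float(rng.choice([-1.0, 1.0]))
        host.padj = 0.01
        f.padj = 0.01
        f.log2fc = -host.log2fc if i < n_flip else host.log2fc

    return Reference(
        config=cfg,
        chrom_lengths={c: cfg.chrom_length for c in chroms},
        genome={c: bytes(genome[c]).decode() for c in chroms},
        genes=genes,
        features=features,
    )


# ---------------------------------------------------------------------------
# evidence


def _expressed_in(feat: _Feature, sample: str, cfg: SimulationConfig) -> bool:
    if not feat.conditions:
        return True
    return cfg.sample_condition[sample] in feat.conditions


def simulate_evidence(
    ref: Reference, out_dir: str | Path, rng: np.random.Generator | None = None
) -> dict:
    """Write per-sample bedGraphs and SJ tabs, the count matrix, sample table
    and DE table into ``out_dir``; returns a manifest of file paths."""
    cfg = ref.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)

    manifest: dict = {"samples": {}, "config": asdict(cfg)}

    chroms = sorted(ref.chrom_lengths)
    for sample in cfg.samples:
        depth = {
            (c, st): np.zeros(ref.chrom_lengths[c], dtype=np.int64)
            for c in chroms
            for st in "+-"
        }
        sj_rows = []
        for f in ref.features:
            if not _expressed_in(f, sample, cfg):
                continue
            if f.kind == "noise":
                plateau = 3 + int(rng.poisson(1.0))
            else:
                plateau = max(4, int(rng.poisson(f.depth_target)))
            for s, e in f.exons:
                depth[(f.chrom, f.strand)][s:e] += plateau
            for s, e in f.introns:
                reads = max(3, int(rng.poisson(f.sj_support)))
                sj_rows.append(
                    (f.chrom, s + 1, e, 1 if f.strand == "+" else 2,
                     1, int(f.annotated_sj), reads, 0, cfg.read_length // 2)
                )
        # sparse background noise: runs shorter than an island
        n_noise = int(
            cfg.noise_runs_per_mb * cfg.n_chromosomes * cfg.chrom_length / 1e6
        )
        for _ in range(n_noise):
            c = chroms[int(rng.integers(len(chroms)))]
            st = "+" if rng.random() < 0.5 else "-"
            ln = int(rng.integers(20, 80))
            pos = int(rng.integers(0, ref.chrom_lengths[c] - ln))
            depth[(c, st)][pos : pos + ln] += int(rng.integers(3, 6))
        # a few unsupported junctions that the support filter must drop
        for _ in range(5):
            c = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1000, ref.chrom_lengths[c] - 2000))
            sj_rows.append((c, pos + 1, pos + 500, 1, 1, 0, int(rng.integers(1, 3)), 0, 50))

        files = {}
        for st, tag in (("+", "plus"), ("-", "minus")):
            rows = []
            for c in chroms:
                d = depth[(c, st)]
                change = np.flatnonzero(np.diff(d)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(d)]])
                vals = d[starts]
                keep = vals != 0
                rows.append(
                    pd.DataFrame(
                        {"chrom": c, "start": starts[keep], "end": ends[keep], "depth": vals[keep]}
                    )
                )
            bg = pd.concat(rows, ignore_index=True)
            path = out / f"{sample}.{tag}.bedgraph"
            write_bedgraph(bg, path)
            files[tag] = str(path)
        sj_rows.sort()
        sj_path = out / f"{sample}.SJ.out.tab"
        sj_path.write_text(
            "\n".join("\t".join(map(str, r)) for r in sj_rows) + "\n"
        )
        files["sj"] = str(sj_path)
        manifest["samples"][sample] = files

    # --- counts (negative binomial), features = genes + planted lncRNAs
    counted = [f for f in ref.features if f.kind != "noise"]
    counts = {}
    for sample in cfg.samples:
        col = []
        for f in counted:
            if f.kind == "coding":
                mean = cfg.coding_base_mean
            else:
                mean = cfg.coding_base_mean * cfg.lnc_expression_ratio
            if cfg.sample_condition[sample] != "cond1":
                mean *= 2.0 ** f.log2fc
            if not _expressed_in(f, sample, cfg):
                mean = 0.05
            r = 1.0 / cfg.nb_dispersion
            p = r / (r + mean)
            col.append(int(rng.negative_binomial(r, p)))
        counts[sample] = col
    counts_df = pd.DataFrame(counts, index=[f.fid for f in counted])
    counts_df.index.name = "feature"
    counts_path = out / "counts.tsv"
    counts_df.to_csv(counts_path, sep="\t")

    samples_df = pd.DataFrame(
        {"condition": [cfg.sample_condition[s] for s in cfg.samples]},
        index=pd.Index(cfg.samples, name="sample"),
    )
    samples_path = out / "samples.tsv"
    samples_df.to_csv(samples_path, sep="\t")

    de_df = pd.DataFrame(
        {
            "log2fc": [f.log2fc for f in counted],
            "padj": [f.padj for f in counted],
        },
        index=pd.Index([f.fid for f in counted], name="feature"),
    )
    de_path = out / "de.tsv"
    de_df.to_csv(de_path, sep="\t")

    manifest.update(
        counts=str(counts_path), samples=str(samples_path), de=str(de_path)
    )
    return manifest


def write_reference(ref: Reference, out_dir: str | Path) -> dict:
    """Write genome FASTA, annotation GTF and truth/decoy GTFs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for c in sorted(ref.genome):
            fh.write(f">{c}\n")
            seq = ref.genome[c]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    ann = out / "annotation.gtf"
    lines = []
    for g in ref.genes:
        s1, e1 = g.gene_span.to_display()
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        lines.append(
            "\t".join(
                [g.gene_span.chrom, "sim", "gene", str(s1), str(e1), ".", g.strand, ".", attrs]
            )
        )
        for i, e in enumerate(g.exons, start=1):
            es, ee = e.to_display()
            lines.append(
                "\t".join(
                    [
                        e.chrom, "sim", "exon", str(es), str(ee), ".", g.strand, ".",
                        attrs + f' transcript_id "{g.gene_id}.1"; exon_number "{i}";',
                    ]
                )
            )
    ann.write_text("\n".join(lines) + "\n")

    truth = out / "truth.gtf"
    # genomic-context class labels: planted monoexonic features live in
    # intergenic space, so their context class is intergenic
    write_gtf(
        [
            f.as_candidate(
                klass="intergenic" if f.kind == "monoexonic" else f.kind
            )
            for f in ref.planted
        ],
        truth,
        source="truth",
    )
    decoys = out / "decoys.gtf"
    write_gtf(
        [f.as_candidate(klass="intergenic") for f in ref.decoys],
        decoys,
        source="truth",
    )
    return {
        "genome": str(fasta),
        "annotation": str(ann),
        "truth": str(truth),
        "decoys": str(decoys),
    }


def simulate_all(config: SimulationConfig | None = None, out_dir: str | Path = ".") -> dict:
    """Reference + evidence in one call; returns the combined manifest."""
    cfg = config or SimulationConfig()
    ref = simulate_reference(cfg)
    manifest = write_reference(ref, out_dir)
    manifest.update(simulate_evidence(ref, out_dir))
    Path(out_dir, "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# training sequences for the coding-potential model


def make_training_sets(
    rng: np.random.Generator, n_per_class: int = 150, length: int = 900
) -> tuple[list[str], list[str]]:
    """ORF-rich coding-like sequences and their shuffled noncoding controls."""
    coding = []
    noncoding = []
    for _ in range(n_per_class):
        orf_codons = int(rng.integers(120, (length - 120) // 3 - 2))
        seq = _orf_sequence(rng, length, orf_codons)
        coding.append(seq)
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        rng.shuffle(arr)
        noncoding.append(arr.tobytes().decode())
    return coding, noncoding
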