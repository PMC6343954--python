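"""Readers and writers for the pipeline's file formats.

GTF (ENSEMBL / RefSeq attribute dialects), STAR ``SJ.out.tab``, 4-column
bedGraph, BED6 TSS tracks, plain TSV count matrices, and the lncRNA naming
scheme ``{closest_gene}_LNCRNA[_IG|_INTRONIC]:{chrom}:{start}-{end}({strand})``
with 1-based inclusive display coordinates.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .intervals import (
    GeneModel,
    GenomeInterval,
    SpliceJunction,
    TranscriptCandidate,
    normalize_strand,
)


class GtfParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

# attribute keys accepted for the gene identifier, in priority order
_GENE_KEYS = {"ensembl": ("gene_id",), "refseq": ("gene_id", "gene")}


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path, dialect: str = "ensembl") -> list[GeneModel]:
    """Parse a 9-column GTF into one :class:`GeneModel` per gene_id.

    Exon records are merged per gene; gene span is the hull of its exons
    (or the explicit ``gene`` record when present). GTF 1-based inclusive
    coordinates are converted to internal 0-based half-open.
    """
    if dialect not in _GENE_KEYS:
        raise ValueError(f"unknown GTF dialect: {dialect}")
    gene_keys = _GENE_KEYS[dialect]

    exons: dict[str, list[GenomeInterval]] = defaultdict(list)
    spans: dict[str, GenomeInterval] = {}
    biotypes: dict[str, str] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            try:
                iv = GenomeInterval.from_display(
                    chrom, int(start), int(end), strand
                )
            except ValueError as exc:
                raise GtfParseError(f"{path}: line {lineno}: {exc}") from exc
            attr = _parse_attributes(attrs)
            gene_id = next((attr[k] for k in gene_keys if k in attr), None)
            if gene_id is None:
                raise GtfParseError(
                    f"{path}: line {lineno}: no gene identifier attribute "
                    f"(tried {gene_keys})"
                )
            if gene_id not in biotypes:
                order.append(gene_id)
                biotypes[gene_id] = attr.get(
                    "gene_biotype", attr.get("gene_type", "unknown")
                )
            if feature == "exon":
                exons[gene_id].append(iv)
            elif feature == "gene":
                spans[gene_id] = iv

    genes = []
    for gid in order:
        ex = sorted(set(exons[gid]), key=lambda e: (e.start, e.end))
        if not ex and gid not in spans:
            continue
        if ex:
            strand = ex[0].strand
            chrom = ex[0].chrom
            span = spans.get(
                gid,
                GenomeInterval(chrom, ex[0].start, ex[-1].end, strand),
            )
        else:
            span = spans[gid]
            strand = span.strand
        genes.append(GeneModel(gid, biotypes[gid], strand, span, ex))
    return genes


def _gtf_row(chrom, source, feature, iv: GenomeInterval, strand, attrs: str) -> str:
    s1, e1 = iv.to_display()
    return "\t".join(
        [chrom, source, feature, str(s1), str(e1), ".", strand, ".", attrs]
    )


def write_gtf(
    candidates: Iterable[TranscriptCandidate],
    path: str | Path,
    source: str = "lncisland",
) -> None:
    """Export candidates as GTF with gene, transcript and exon rows.

    Rows are emitted in coordinate-sorted order so that identical candidate
    sets produce byte-identical files.
    """
    cands = sorted(candidates, key=lambda c: (c.chrom, c.span.start, c.span.end, c.strand, c.id))
    lines = []
    for c in cands:
        span = c.span
        base = f'gene_id "{c.id}"'
        gene_attrs = base + f'; gene_biotype "lncRNA"; lnc_class "{c.klass}";'
        tx_attrs = base + f'; transcript_id "{c.id}.1";'
        lines.append(_gtf_row(c.chrom, source, "gene", span, c.strand, gene_attrs))
        lines.append(_gtf_row(c.chrom, source, "transcript", span, c.strand, tx_attrs))
        for i, e in enumerate(c.exons, start=1):
            attrs = tx_attrs + f' exon_number "{i}";'
            lines.append(_gtf_row(c.chrom, source, "exon", e, c.strand, attrs))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_candidate_gtf(path: str | Path) -> list[TranscriptCandidate]:
    """Read a candidate GTF written by :func:`write_gtf` back into objects."""
    exons: dict[str, list[GenomeInterval]] = defaultdict(list)
    meta: dict[str, dict[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            chrom, _s, feature, start, end, _sc, strand, _f, attrs = fields
            attr = _parse_attributes(attrs)
            gid = attr["gene_id"]
            if gid not in meta:
                meta[gid] = {"chrom": chrom, "strand": normalize_strand(strand)}
                order.append(gid)
            if "lnc_class" in attr:
                meta[gid]["class"] = attr["lnc_class"]
            if feature == "exon":
                exons[gid].append(
                    GenomeInterval.from_display(chrom, int(start), int(end), strand)
                )
    return [
        TranscriptCandidate(
            id=gid,
            chrom=meta[gid]["chrom"],
            strand=meta[gid]["strand"],
            exons=sorted(exons[gid], key=lambda e: (e.start, e.end)),
            klass=meta[gid].get("class", "unclassified"),
        )
        for gid in order
    ]


# ---------------------------------------------------------------------------
# STAR SJ.out.tab

_SJ_STRAND = {0: ".", 1: "+", 2: "-"}
_SJ_CODE = {".": 0, "+": 1, "-": 2}


def read_sj_tab(path: str | Path) -> list[SpliceJunction]:
    """Read STAR's 9-column SJ.out.tab.

    Columns: chrom, 1-based intron start, 1-based intron end, strand code
    (0 undefined / 1 plus / 2 minus), motif, annotated flag, unique reads,
    multi reads, max overhang.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            chrom = fields[0]
            start1, end1 = int(fields[1]), int(fields[2])
            strand = _SJ_STRAND[int(fields[3])]
            annotated = int(fields[5]) != 0
            unique = int(fields[6])
            intron = GenomeInterval.from_display(chrom, start1, end1, strand)
            out.append(SpliceJunction(intron, strand, unique, annotated))
    return out


def write_sj_tab(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    rows = []
    for j in sorted(junctions, key=lambda j: (j.intron.chrom, j.intron.start, j.intron.end)):
        s1, e1 = j.intron.to_display()
        rows.append(
            "\t".join(
                map(
                    str,
                    [
                        j.intron.chrom,
                        s1,
                        e1,
                        _SJ_CODE[j.strand],
                        1,
                        int(j.annotated_flag),
                        j.unique_reads,
                        0,
                        50,
                    ],
                )
            )
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# bedGraph and BED

def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph (0-based half-open) into a DataFrame."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="t",  # skips optional "track" header lines
        header=None,
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": int, "end": int, "depth": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 of transcription start sites (single-base features)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    df["strand"] = df["strand"].map(normalize_strand)
    return df


# ---------------------------------------------------------------------------
# count matrices

def read_counts(path: str | Path) -> pd.DataFrame:
    """Features x samples TSV with a header row and feature-id index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative entries in count matrix")
    return df


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample id index, at least a 'condition' column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "condition" not in df.columns:
        raise ValueError(f"{path}: sample table needs a 'condition' column")
    return df


# ---------------------------------------------------------------------------
# naming scheme

_CLASS_TAG = {"intergenic": "_IG", "antisense": "", "intronic": "_INTRONIC"}
_TAG_CLASS = {"IG": "intergenic", "": "antisense", "INTRONIC": "intronic"}

_NAME_RE = re.compile(
    r"^(?P<gene>.+?)_LNCRNA(?:_(?P<tag>IG|INTRONIC))?"
    r":(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)"
    r"\((?P<strand>[+\-.−])\)$"
)


def make_name(
    candidate: TranscriptCandidate,
    closest_gene_id: str | None = None,
    klass: str | None = None,
) -> str:
    """Build the display name ``gene_LNCRNA[_IG]:chrom:start-end(strand)``.

    Intergenic candidates carry the ``IG`` tag; antisense candidates name
    their sense gene with no tag; intronic candidates are tagged
    ``INTRONIC``. Coordinates are 1-based inclusive.
    """
    gene = closest_gene_id if closest_gene_id is not None else candidate.closest_gene_id
    kls = klass if klass is not None else candidate.klass
    if kls not in _CLASS_TAG:
        raise ValueError(f"cannot name candidate of class {kls!r}")
    span = candidate.span
    s1, e1 = span.to_display()
    tag = _CLASS_TAG[kls]
    return f"{gene}_LNCRNA{tag}:{candidate.chrom}:{s1}-{e1}({candidate.strand})"


def parse_name(name: str) -> tuple[str, str, GenomeInterval]:
    """Invert :func:`make_name` -> (closest gene, class, interval)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable lncRNA name: {name!r}")
    strand = normalize_strand(m["strand"])
    iv = GenomeInterval.from_display(
        m["chrom"], int(m["start"]), int(m["end"]), strand
    )
    return m["gene"], _TAG_CLASS[m["tag"] or ""], iv
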