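"""Candidate filtering: coding potential, expression, consistency, context.

Coding potential is scored in the CPAT style: longest-ORF length and
coverage, the Fickett TESTCODE statistic, and an in-frame hexamer
log-likelihood bias feed a logistic regression trained on labelled coding /
noncoding sequence sets. The default probability cutoff (0.44) is the
published mouse value for that scheme; it is configurable per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import (
    GeneModel,
    GenomeInterval,
    TranscriptCandidate,
    intersect_pairs,
    total_bp,
)

DEFAULT_CODING_CUTOFF = 0.44
MIN_TRANSCRIPT_LENGTH = 200
FPKM_CUTOFF = 0.5

_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def transcript_sequence(candidate: TranscriptCandidate, genome: Mapping[str, str]) -> str:
    """Concatenated exon sequence on the candidate strand (revcomp for -)."""
    chrom_seq = genome[candidate.chrom]
    s = "".join(chrom_seq[e.start : e.end] for e in candidate.exons).upper()
    return reverse_complement(s) if candidate.strand == "-" else s


# ---------------------------------------------------------------------------
# ORF


def longest_orf(seq: str) -> tuple[int, float]:
    """Longest ATG..stop ORF over the three forward frames.

    Returns (orf_length_nt, orf_coverage); the stop codon counts toward the
    length. (0, 0.0) when no complete ORF exists.
    """
    seq = seq.upper()
    n = len(seq)
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    if best == 0 or n == 0:
        return 0, 0.0
    return best, best / n


# ---------------------------------------------------------------------------
# Fickett TESTCODE

# published TESTCODE lookup tables: probability that a sequence with the
# given position/composition parameter is coding, and per-base weights
_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.49, 0.54, 0.75, 0.59, 0.57, 0.42],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.73, 0.64, 0.64, 0.37],
    "T": [0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.51, 0.63, 0.33],
}
_POSITION_WEIGHT = {"A": 0.22, "C": 0.23, "G": 0.24, "T": 0.18}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.31, 0.33, 0.29, 0.25, 0.18],
    "G": [0.21, 0.40, 0.47, 0.50, 0.52, 0.60, 0.50, 0.46, 0.45, 0.02],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.09, 0.05],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, paras: Sequence[float], probs: Sequence[float]) -> float:
    for p, pr in zip(paras, probs):
        if value >= p:
            return pr
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic (positional asymmetry + composition)."""
    seq = seq.upper()
    score = 0.0
    for base in "ACGT":
        counts = [
            sum(1 for i in range(f, len(seq), 3) if seq[i] == base)
            for f in range(3)
        ]
        pos_value = max(counts) / (min(counts) + 1)
        score += (
            _lookup(pos_value, _POSITION_PARA, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        content = seq.count(base) / len(seq) if seq else 0.0
        score += (
            _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


# ---------------------------------------------------------------------------
# hexamer bias


def hexamer_bias(seq: str, table: Mapping[str, float]) -> float:
    """Mean log-likelihood ratio over in-frame (step 3) hexamers.

    Hexamers containing letters outside ACGT (e.g. N) are skipped.
    """
    seq = seq.upper()
    vals = []
    for i in range(0, len(seq) - 5, 3):
        h = seq[i : i + 6]
        if h in table:
            vals.append(table[h])
    return float(np.mean(vals)) if vals else 0.0


def train_hexamer_table(
    coding: Sequence[str], noncoding: Sequence[str], pseudocount: float = 1.0
) -> dict[str, float]:
    """log((f_coding + p) / (f_noncoding + p)) over all 4096 hexamers.

    Hexamers are counted in-frame (step 3) in both classes so that identical
    training sets yield the all-zero table.
    """
    if not coding or not noncoding:
        raise ValueError("empty training class")

    def freqs(seqs: Sequence[str]) -> np.ndarray:
        counts = {}
        for s in seqs:
            s = s.upper()
            for i in range(0, len(s) - 5, 3):
                h = s[i : i + 6]
                if all(c in "ACGT" for c in h):
                    counts[h] = counts.get(h, 0) + 1
        total = sum(counts.values()) or 1
        return counts, total

    c_counts, c_total = freqs(coding)
    n_counts, n_total = freqs(noncoding)
    from itertools import product

    table = {}
    for h in map("".join, product("ACGT", repeat=6)):
        fc = c_counts.get(h, 0) / c_total
        fn = n_counts.get(h, 0) / n_total
        table[h] = float(np.log((fc + pseudocount / c_total) / (fn + pseudocount / n_total)))
    return table


# ---------------------------------------------------------------------------
# logistic model


@dataclass
class LogisticModel:
    intercept: float
    coef: tuple[float, float, float, float]  # orf_length, orf_coverage, fickett, hexamer
    cutoff: float = DEFAULT_CODING_CUTOFF

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")


@dataclass
class CodingFeatures:
    orf_length: int
    orf_coverage: float
    fickett: float
    hexamer: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.orf_length, self.orf_coverage, self.fickett, self.hexamer]
        )


def coding_features(seq: str, hexamer_table: Mapping[str, float]) -> CodingFeatures:
    ol, oc = longest_orf(seq)
    return CodingFeatures(ol, oc, fickett_score(seq), hexamer_bias(seq, hexamer_table))


def coding_probability(features: CodingFeatures, model: LogisticModel) -> float:
    z = model.intercept + float(np.dot(model.coef, features.as_array()))
    return float(1.0 / (1.0 + np.exp(-z)))


def train_logistic(
    coding_features_list: Sequence[CodingFeatures],
    noncoding_features_list: Sequence[CodingFeatures],
    cutoff: float = DEFAULT_CODING_CUTOFF,
) -> LogisticModel:
    """Maximum-likelihood logistic fit on the four coding-potential features."""
    from sklearn.linear_model import LogisticRegression

    if not coding_features_list or not noncoding_features_list:
        raise ValueError("empty training class")
    X = np.array(
        [f.as_array() for f in coding_features_list]
        + [f.as_array() for f in noncoding_features_list]
    )
    y = np.array([1] * len(coding_features_list) + [0] * len(noncoding_features_list))
    # scale ORF length to keep the unpenalised fit well conditioned
    scale = np.array([1e-3, 1.0, 1.0, 1.0])
    clf = LogisticRegression(C=1e12, max_iter=2000, solver="lbfgs")
    clf.fit(X * scale, y)
    coef = clf.coef_[0] * scale
    return LogisticModel(float(clf.intercept_[0]), tuple(float(c) for c in coef), cutoff)


# ---------------------------------------------------------------------------
# FPKM


def compute_fpkm(count: float, transcript_length: int, library_size: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if transcript_length <= 0 or library_size <= 0:
        raise ValueError("transcript length and library size must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count * 1e9 / (transcript_length * library_size)


# ---------------------------------------------------------------------------
# context classification


@dataclass
class AnnotationIndex:
    """Per-(chrom,strand) exon and span interval lists for classification."""

    genes: list[GeneModel]
    exons: dict[tuple[str, str], list[tuple[int, int, str]]] = field(init=False)
    spans: dict[str, list[tuple[int, int, str, str]]] = field(init=False)
    introns: dict[str, list[tuple[int, int, str, str]]] = field(init=False)

    def __post_init__(self) -> None:
        self.exons = {}
        self.spans = {}
        self.introns = {}
        for g in self.genes:
            for e in g.exons or [g.gene_span]:
                self.exons.setdefault((e.chrom, g.strand), []).append(
                    (e.start, e.end, g.gene_id)
                )
            self.spans.setdefault(g.gene_span.chrom, []).append(
                (g.gene_span.start, g.gene_span.end, g.strand, g.gene_id)
            )
            for intr in g.introns:
                self.introns.setdefault(intr.chrom, []).append(
                    (intr.start, intr.end, g.strand, g.gene_id)
                )
        for d in (self.exons, self.spans, self.introns):
            for k in d:
                d[k].sort()


_OPPOSITE = {"+": "-", "-": "+"}


def classify_context(
    candidate: TranscriptCandidate,
    index: AnnotationIndex,
    intronic_same_strand_only: bool = False,
) -> TranscriptCandidate:
    """Assign genomic-context class, closest gene and distance.

    Priority antisense > intronic > intergenic: antisense when any candidate
    exon bp overlaps an annotated exon on the opposite strand; intronic when
    the candidate lies inside one annotated intron (either strand by
    default) without such overlap; intergenic otherwise. Distance is gap bp
    to the closest gene span (0 for antisense/intronic); ties on distance
    break to the lexicographically smaller gene_id.
    """
    ex_pairs = [(e.start, e.end) for e in candidate.exons]
    opp = _OPPOSITE.get(candidate.strand)

    # antisense: exonic overlap with opposite-strand annotated exons
    if opp is not None:
        hits = []
        for s, e, gid in index.exons.get((candidate.chrom, opp), []):
            ov = total_bp(intersect_pairs(ex_pairs, [(s, e)]))
            if ov > 0:
                hits.append((-ov, gid))
        if hits:
            hits.sort()
            candidate.klass = "antisense"
            candidate.closest_gene_id = hits[0][1]
            candidate.distance_to_closest = 0
            return candidate

    # intronic: contained in an annotated intron
    span = candidate.span
    intron_hits = []
    for s, e, strand, gid in index.introns.get(candidate.chrom, []):
        if intronic_same_strand_only and strand != candidate.strand:
            continue
        if s <= span.start and span.end <= e:
            intron_hits.append(gid)
    if intron_hits:
        candidate.klass = "intronic"
        candidate.closest_gene_id = sorted(intron_hits)[0]
        candidate.distance_to_closest = 0
        return candidate

    # intergenic: closest gene by span gap distance
    best: tuple[int, str] | None = None
    for s, e, strand, gid in index.spans.get(candidate.chrom, []):
        if e <= span.start:
            d = span.start - e
        elif span.end <= s:
            d = s - span.end
        else:
            d = 0
        if best is None or (d, gid) < best:
            best = (d, gid)
    candidate.klass = "intergenic"
    if best is not None:
        candidate.distance_to_closest = best[0]
        candidate.closest_gene_id = best[1]
    else:
        candidate.distance_to_closest = -1
        candidate.closest_gene_id = ""
    return candidate


def is_retained_intron(
    candidate: TranscriptCandidate, index: AnnotationIndex, tolerance: int = 10
) -> bool:
    """True when both candidate ends sit within ``tolerance`` bp of the
    flanking exon boundaries of the host annotated intron."""
    span = candidate.span
    for s, e, _strand, _gid in index.introns.get(candidate.chrom, []):
        if s <= span.start and span.end <= e:
            if abs(span.start - s) <= tolerance and abs(e - span.end) <= tolerance:
                return True
    return False


# ---------------------------------------------------------------------------
# conjunctive filters


FILTER_ORDER = ("min_length", "coding", "replicate_consistency", "min_fpkm")


@dataclass
class FilterParams:
    min_length: int = MIN_TRANSCRIPT_LENGTH
    fpkm_cutoff: float = FPKM_CUTOFF
    coding_cutoff: float = DEFAULT_CODING_CUTOFF


def apply_filters(
    candidates: Sequence[TranscriptCandidate],
    presence: Mapping[str, Mapping[str, bool]],
    condition_fpkm: Mapping[str, Mapping[str, float]],
    coding_prob: Mapping[str, float],
    params: FilterParams | None = None,
) -> tuple[list[TranscriptCandidate], dict[str, str]]:
    """Keep candidates passing length / noncoding / consistency / FPKM.

    A candidate is kept iff length >= 200 AND coding probability < cutoff
    AND present in all replicates of >= 1 condition AND mean FPKM > 0.5 in
    >= 1 condition. Returns (kept, {candidate id -> first failing flag}).
    Filters are conjunctive so their order only affects which flag a
    discarded candidate carries.
    """
    p = params or FilterParams()
    kept = []
    flags: dict[str, str] = {}
    for c in candidates:
        fail = None
        if c.length < p.min_length:
            fail = "min_length"
        elif not (coding_prob[c.id] < p.coding_cutoff):
            fail = "coding"
        elif not any(presence.get(c.id, {}).values()):
            fail = "replicate_consistency"
        elif not any(
            v > p.fpkm_cutoff for v in condition_fpkm.get(c.id, {}).values()
        ):
            fail = "min_fpkm"
        if fail is None:
            c.filter_flags = set()
            c.coding_probability = coding_prob[c.id]
            c.condition_fpkm = dict(condition_fpkm.get(c.id, {}))
            kept.append(c)
        else:
            c.filter_flags = {fail}
            flags[c.id] = fail
    return kept, flags
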