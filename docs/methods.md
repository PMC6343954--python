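# Methods

## Model of the data

The pipeline assumes stranded (dUTP-style) paired-end RNA-seq summarised to
per-base, per-strand coverage of properly paired, uniquely mapped reads,
plus aligner-reported splice junctions with unique-read support. Transcribed
loci outside annotated gene models then appear as contiguous coverage runs
("islands of expression") on the strand of origin, connected by junctions
when the locus is spliced. The method reconstructs gene-level models only —
no isoform deconvolution — because its purpose is a non-redundant novel
annotation suitable for count-based differential expression.

## Stages and parameters

All internal coordinates are 0-based half-open; GTF, SJ and display
coordinates are 1-based inclusive and converted at the I/O boundary.

| parameter | default | units | rationale |
|---|---|---|---|
| `mask.flank` | 1000 | bp | gene models are extended both ways so unannotated UTR extensions are not called novel genes |
| `mask.mode` | span / exon_union | — | span for the intergenic/antisense branch (annotated introns masked); exon_union for the intronic second pass |
| `depth_threshold` | 2 (strict >) | read pairs | minimum evidence for transcription; qualifying positions have depth ≥ 3 |
| `min_island_length` | 100 | bp | one read-mate length, so overlapping mates cannot fake an island |
| `sj_min_unique_reads` | 2 (strict >) | reads | discards spurious junctions |
| `sj_min_length`, `sj_max_length` | 20 / 100 000 (both exclusive) | bp | plausible intron size range |
| `junction_tolerance` | 10 | bp | junction ends may overshoot island edges by soft-clip noise; attachment allows this slack |
| `consensus_fraction` | 0.5 | — | a segment becomes intronic on a strict majority of the junctions overlapping its block |
| `z_window` | 31 (odd) | bp | trailing window of the smoothed z-score detector |
| `z_drop_threshold` | 5 | σ | deviation needed to flag a drop/peak |
| `z_min_intron` | 20 | bp | shortest drop run promoted to an intron |
| `z_s_floor` | 1 | depth | flat plateaus have zero variance; the floor prevents division blow-ups and makes the threshold act on absolute depth there |
| `monoexonic_pr_cutoff` | 0.1 | — | keep only the upper tail of the monoexonic population |
| `min_transcript_length` | 200 | nt | definitional lower bound for lncRNAs |
| `coding_cutoff` | 0.44 | probability | published mouse cutoff for the four-feature logistic coding-potential scheme; configurable per species |
| `fpkm_cutoff` | 0.5 (strict >) | FPKM | removes barely expressed models; mean per condition, best condition must pass |
| `tau_cutoff` / `min_mean_log2` | 0.8 / 3 (both strict >) | — / log2 counts | subtype-specificity calls |

The z-score detector keeps a rolling mean and population SD over the
trailing `z_window` positions of the *filtered* signal: a flagged position
contributes its predecessor's filtered value (influence 0), so a long drop
does not drag the baseline down. Drops are flagged where
`mean − depth > z_drop_threshold · max(sd, z_s_floor)`, peaks symmetrically.
Drop runs shorter than `z_min_intron` are ignored; runs touching a segment
end trim the transcript instead of splitting it. Splice-junction subtraction
runs first and z-score refinement operates on the residual exons, matching
the stage order of the overall design.

Consensus introns: the union of a cluster's junction intervals is broken at
every junction boundary into atomic segments. The acceptance rule divides
the number of junctions containing a segment by the number of junctions
overlapping that segment's connected union block (the denominator the
"relative frequency" rule needs to be scale-free); accepted adjacent
segments merge, and merged introns shorter than `z_min_intron` are dropped.

Monoexonic candidates are the cross-sample intersections of junction-free
islands present in every sample. Their length-normalised coverage c is
ranked in the *whole* monoexonic population and a candidate survives iff
Pr(>) = #{c′ > c}/N < 0.1 — strict comparisons, equal values sharing one
survival value. This is a rank-based, distribution-free reading; it keeps
the strongest ~decile of monoexonic signal and is deliberately conservative
because single-exon calls have no junction corroboration.

Merging: same-strand per-sample candidates sharing ≥ 1 exonic bp union into
one gene model; consensus introns are recomputed on the pooled junctions of
the contributing samples. A merged gene records, per condition, whether
every replicate contributed; genes complete in no condition are dropped.

Intronic discovery is a second pass with the exon-union mask, restricted to
candidates contained in an annotated intron, having ≥ 1 qualifying novel
junction, and not retained-intron-like (both ends within 10 bp of the host
intron's boundaries). Running both passes covers the two defensible
readings of "discard reads overlapping gene models" while still reporting
novel intronic genes.

Context classes partition with priority antisense > intronic > intergenic.
Closest genes use gap distance between feature edges (0 when overlapping);
distance ties break to the lexicographically smaller gene id so output is
deterministic.

## Coding potential

Four features per transcript sequence (exons concatenated on the candidate
strand): longest ATG→stop ORF length (stop included) and its coverage of
the transcript, the Fickett TESTCODE statistic from the published
position/composition lookup tables, and mean in-frame (step 3) hexamer
log-likelihood ratio. The hexamer table is
log((f_coding + p)/(f_noncoding + p)) with pseudocount p = 1 count,
hexamers counted in-frame in both classes so identical classes give a zero
table. A maximum-likelihood logistic regression (no penalty; ORF length
scaled by 10⁻³ for conditioning, coefficients reported on the raw scale)
maps features to a coding probability; training sequences are ORF-rich
synthetics versus their shuffles, generated deterministically from the run
seed. No pretrained model ships with the package; users with a reference
training set can supply their own cutoff and model.

## Expression

FPKM = count · 10⁹ / (length · library size). In the self-contained
pipeline the per-candidate fragment count is estimated from the coverage
tracks as summed exon depth divided by the read-pair footprint (200 bp
default), and library sizes come from the provided count matrix's column
sums. This is the package's own choice for running without an external
read counter; with real data, counts from a dedicated counter can be
substituted through the same interface.

## What the simulator emulates — and what it does not

`simulate` plants, with a fixed seed and byte-reproducible outputs:
coding genes with real ORFs (biased codon usage); antisense lncRNAs
overlapping host exons on the opposite strand; intergenic lncRNAs ≥ 1000 bp
clear of same-strand gene spans (two expressed in only one condition);
intronic lncRNAs inside wide host introns, clear of retained-intron
geometry; strong monoexonic lncRNAs against a ~9× larger population of weak
monoexonic noise islands (the situation the Pr(>) filter addresses);
coding-like decoys with long ORFs that the coding filter must remove; short
sub-island background noise runs; plateau exon coverage (per-sample Poisson
level), junction support proportional to configured ranges, negative
binomial counts (dispersion 0.1) with lncRNAs at 1/10 of coding expression,
and a DE table in which half of the antisense lncRNAs flip sign against
their host. Exon counts are skewed to biexonic transcripts
(7:4:1 for 2:3:4 exons among multiexonic intergenic plants).

Not emulated: mappability/GC structure, soft-clipped junction jitter,
isoform mixtures, ragged coverage edges, sequencing error. Passing the
synthetic-recovery tests therefore demonstrates the pipeline's logic
(masking, clustering, consensus, filtering, classification) is correct
under clean evidence, not its robustness to alignment artefacts on real
libraries.

Default study size: 2 chromosomes × 1 Mb, 40 coding genes, 30 planted
lncRNAs (6 antisense / 12 intergenic / 6 intronic / 6 monoexonic),
54 noise monoexonics, 3 decoys, 2 conditions × 3 samples. These sizes keep
a full simulate-plus-run cycle in seconds while exercising every branch;
tests use a further reduced single-chromosome study.

## Numerical and degenerate-input choices

- Strict inequalities follow the printed rules everywhere (> 2 reads,
  > 2 depth, > 0.5 FPKM, > 0.8 tau, > 3 log2, < 0.1 Pr(>)); boundary tests
  pin each at value and value ± 1.
- Empty island set, junction-free cluster, or a subtraction that leaves no
  exonic bp are handled (skip/flag), never crash the run.
- tau is undefined (error) on all-zero or negative profiles; features with
  all-zero group means get tau = NaN and are never called specific.
- Fisher odds ratios use the Haldane 0.5 correction only when a cell is 0;
  p-values come from the exact hypergeometric two-sided test.
- All iteration orders are sorted; re-running on identical inputs produces
  byte-identical GTF output (manifests differ only in timestamp-free
  content: they contain no timestamps at all, so they are identical too).

## Known limitations

- Gene-level only; overlapping same-strand isoforms collapse into one model.
- Coverage-zeroing is a conservative approximation of read-level filtering;
  a read straddling the mask boundary leaves partial coverage outside.
- The monoexonic Pr(>) filter is population-relative: with few monoexonic
  candidates it is very strict, and singletons depend on cohort composition.
- FPKM estimation from coverage inherits any coverage bias; it is meant for
  thresholding, not quantification.
- The coding-potential model is only as good as its training sequences;
  the built-in synthetic training is a stand-in for species-specific
  reference sets.
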