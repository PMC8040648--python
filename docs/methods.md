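# Methods

## Overview

`nadcap` models the computational half of a tag-based NAD⁺-cap profiling
assay. The wet-lab part of such an assay converts the NAD⁺ cap of a
transcript into a ligation handle (ADPRC transglycosylation with an azido
alcohol, then copper-free click ligation of a synthetic 39-nt RNA tag) so
that cap status becomes a 5′-terminal sequence feature readable by nanopore
direct-RNA sequencing. Everything downstream of basecalling is in scope
here: tag detection, read-to-gene assignment, rRNA removal, counting,
background estimation from enzyme-minus (ADPRC−) controls, per-condition
high-confidence calling, and between-condition statistics. Everything
upstream (chemistry, basecalling) is represented only through the synthetic
read generator's error model.

## Tag detection

### Model

A tagged read is tag + transcript + poly(A), read 5′→3′ in DNA letters.
Two artefacts shape the detector:

* nanopore direct-RNA sequencing misses the first bases of the molecule
  (here modeled as a geometric truncation with mean 12 nt), which eats into
  the tag from its 5′ side;
* the non-nucleotide cap–tag junction miscalls several bases immediately
  downstream of the tag.

The score of tag `t` (m = 39) against the first `search_window` = 80 bases
of a read is the best alignment of any suffix `t[s:]` that (i) is anchored
at the read start — read bases before the tag cost an affine gap — and
(ii) reaches the tag's 3′ end — unmatched 3′ tag bases are penalized,
because the junction side of the tag is always sequenced. Matches score +1,
mismatches −1, gaps open −3 and extend −1, the 5′ overhang `t[:s]` is free,
and the score is floored at 0 (an empty window is defined as −m, the
all-gap alignment). A read is tagged iff score ≥ `min_similarity` = 12, and
is trimmed at the smallest window offset achieving the best score.

### Why affine gaps

The 39-nt tag is periodic (period 6). Under a linear gap penalty of −1 a
random 80-nt window can chain short spurious match runs across cheap gaps
up to the threshold at a rate of several per thousand reads — orders of
magnitude above the enzyme-minus background the assay itself measures,
which upper-bounds the tolerable detector false-positive rate near 10⁻⁴.
Free leading window gaps (an unanchored search) are worse still. Affine
gaps keep tolerance for the isolated indels characteristic of nanopore
reads while making chains expensive. At the defaults the decoy
false-positive rate measured on random 200-nt reads is ~1×10⁻⁵ and the
read-level sensitivity under the full error model (truncation mean 12,
5 %/3 %/4 % sub/ins/del) is ~0.83; the dominant loss is reads whose
truncation leaves fewer than ~13 tag bases, which no scorer could recover
at threshold 12. Both quantities are recomputed by the test suite and the
acceptance script, not assumed.

The implementation is a three-state (match / gap-in-window / gap-in-tag)
banded DP, vectorized across reads (a numba kernel with an equivalent numpy
fallback). A brute-force recursive enumeration over all (suffix, alignment)
pairs serves as the oracle in tests; the two agree exactly on thousands of
random small cases.

## Read-to-gene assignment

Reads (tag-trimmed if tagged, poly(A)-trimmed always) are assigned by
k-mer seeding (k = 15, every 7th k-mer of the first 400 read bases) against
transcript sequences; candidate genes with ≥ 2 seed hits are aligned with
edlib in infix mode, banded at the edit distance that would already push
identity below the acceptance threshold. Identity is 1 − d/max(|read|,
span). The best gene wins if identity ≥ 0.7; an exact tie between distinct
genes leaves the read unassigned (a conservative undercount, preferred over
fractional or double counting); a second distinct gene above threshold sets
a `multi_locus` flag. Reads assigned to rRNA genes are removed and the
removed fraction reported. External long-read aligner output can be
imported from SAM instead (primary alignments only).

## Background estimation and high-confidence calling

ADPRC− controls see the same chemistry except the enzyme, so any tagged
read there is background (spurious ligation or detector error). The
estimator reports the pooled rate Σtagged/Σtotal, per-gene rates, and flags
genes with ≥ 2 tagged reads in any single control sample — in a clean run
scarcely any gene produces more than one background read, so repeat
offenders (extremely abundant transcripts) are excluded from calling.

A gene is called a high-confidence NAD-RNA producer in a condition when in
≥ `min_replicates` = 2 replicates, jointly within the same replicate,
nad/total ≥ `min_ratio` = 0.2 % (≈ 20× background) and nad ≥
`min_nad_reads` = 2. The joint-within-replicate reading is deliberate: the
two criteria describe the same sample. A replicate with zero total reads
fails. These are deliberate thresholds, not hypothesis tests — a gene with
a vanishing capped fraction may produce NAD-RNA incidentally. The calling
set is monotone in all three thresholds (property-tested).

Condition sets are compared by plain set algebra (exclusives, intersection,
union); ratio tables report pooled and per-replicate NAD percentages with
round-half-even formatting and square-root-transformed ratios for plotting.

## Differential statistics

Counts are normalized by median-of-ratios size factors (geometric-mean
rescaled; total-count scaling is the documented fallback when no gene is
positive in all samples, and is also available by name). The two
normalizations are both implemented because "library size" is ambiguous in
this design; median-of-ratios is the default.

Each gene's between-condition test is a Wald test on the log₂ ratio of
normalized group means with a pseudocount of 0.5, under the NB2 variance
μ·E[1/s] + αμ². The dispersion α comes from a method-of-moments estimate
pooled within groups; because that estimate carries only ~4 degrees of
freedom, it is moderated toward the 10 %-trimmed cross-gene common
dispersion with 10 prior degrees of freedom before flooring at 10⁻⁸ —
flooring the raw estimate alone biases the variance upward and makes the
test measurably conservative, while the unfloored estimate is badly
anti-conservative. The Wald statistic is referred to the standard normal:
the denominator is model-based, not a raw sample variance. Calibration is
validated by seeded Poisson-null simulation (type-I error statistically
consistent with the nominal 0.05), not by matching any external tool's
output. Known limitation: under a strongly overdispersed null with three
replicates per group the plug-in Wald test remains mildly anti-conservative
(~0.065 at nominal 0.05); empirical-Bayes shrinkage of the kind used by the
established DE packages is deliberately out of scope.

Multiple testing uses Benjamini–Hochberg (tested against a brute-force
step-up implementation). The NAD-RNA and total-transcript fold changes are
computed with shared (total-count-derived) size factors, since library size
is a property of the sample; significance is defined on the
total-transcript test. Their association is summarized by the Pearson
correlation over called genes, with non-finite fold changes excluded and
counted.

Codon presence: a read "contains" the start (stop) codon iff its aligned
transcript span covers all three codon bases; reads are split into
NAD-mRNA / non-NAD-mRNA classes per condition; genes without a CDS are
excluded from denominators.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the assay it emulates:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 200 | genes per transcriptome (3 rRNA, up to 10 ncRNA, rest mRNA with planted in-frame start/stop codons) |
| `transcript_length_range` | 300–1500 nt | uniform transcript lengths |
| `expression_dispersion` | 1.5 | log-normal σ of per-gene mean expression |
| `capped_gene_fraction` | 0.15 | genes with any NAD capping |
| `capped_low_range` / `capped_high_range` | 0.5–20 % / 30–75 % | capped-fraction mixture; the high component mirrors genes whose transcripts are mostly capped |
| `rrna_read_fraction` | 0.4 | read share from rRNA genes (incomplete depletion; the assay reports 30–50 %) |
| `sub/ins/del rate` | 0.05 / 0.03 / 0.04 | per-base nanopore-like errors (plausible direct-RNA figures; the assay reports none) |
| `junction_error_rate`, `junction_window` | 0.15, 8 nt | elevated miscalls downstream of the cap–tag junction |
| `five_prime_truncation_mean` | 12 nt | geometric 5′ truncation ("a dozen or so bases"); geometric is the simplest memoryless choice, the assay states no distribution |
| `min_read_length` | 98 nt | shortest surviving read |
| `background_tag_rate` | 10⁻⁴ | tag carriage in ADPRC− controls (and on uncapped molecules in ADPRC+ samples), independent of capping |
| `tagging_efficiency` | 1.0 | chemistry efficiency on capped molecules (configurable) |
| `polya_length` | 30 nt | fixed poly(A) tail; irrelevant to detection, trimmed before assignment |
| `reads_per_sample` | 5×10⁴ | desk-scale depth |

Condition structure: two growth conditions; ~30 % of genes get a true
log₂ fold change drawn N(0, 1) in the second condition. Per-sample RNG
streams derive from (master seed, CRC32 of sample id), so adding a sample
never perturbs the others; a fixed (config, seed) pair reproduces reads
byte-identically. Tag orientation follows the ligation topology: the tag's
3′ end joins the cap, so truncation consumes the tag before the transcript.
Sequences use the DNA alphabet throughout (basecalled FASTQ convention);
U→T conversion happens at I/O.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: signal-level (squiggle) artefacts and
sequence-dependent basecaller error; 3′ fragmentation and premature
transcription termination (simulated reads always reach the transcript 3′
end, so stop-codon presence is near 1); operon-spanning and antisense
reads; transcript isoforms; homopolymer-specific indel enrichment; real
rRNA sequence identity (rRNA genes are random sequences with the right
read share). Conclusions about detector sensitivity in particular inherit
the geometric-truncation assumption.

## Numerical and engineering choices

* Alignment scores are integers; the batched DP uses int16 in the numpy
  path (scores are bounded by ±|tag|) and int64 in the numba kernel.
* Ties: tag trimming uses the smallest end offset among equal-best scores;
  assignment ties between distinct genes yield unassigned; ratio-table
  sorting is stable descending with gene-id tie-break.
* Percentages print with round-half-even at the displayed precision; raw
  ratios are kept at full precision internally.
* Coordinates are 0-based half-open internally; GFF3 conversion happens
  only in the I/O layer. CDS codon positions are stored
  transcript-relative and mapped through strand at GFF3 write/read.
* Poly(A) trimming strips the literal 3′ A-run; errors inside the tail
  leave a few bases behind, which the identity threshold absorbs.
* `estimate_background` raises on zero total control reads; a pipeline run
  without ADPRC− samples warns and proceeds without per-gene flagging.
* Acceptance-scale problem sizes (10⁶ control reads; 200 genes × 8 samples
  × 5×10⁴ reads) were chosen so the full suite runs on one CPU in minutes.
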