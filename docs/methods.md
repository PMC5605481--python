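# Methods

## The detection problem

A basidiomycete heterokaryon contains two parental nuclear genotypes. If
meiotic-like homologous recombination occurs during somatic growth, some
DNA molecules in a mycelial sample are single-crossover mosaics of the two
parental haplotypes, and short reads drawn from those molecules carry
*recombinant* allele combinations at nearby heterozygous SNPs.
`recombiscan` detects such reads from alignments of three whole-genome
sequencing samples — the heterokaryon and its two parental homokaryons —
against a shared (possibly diverged) reference assembly.

## Heterozygous SNP calling

Pileups are built with htslib, counting only A/C/G/T base calls from
primary alignments with MAPQ ≥ `mapq_min` (default 10); base qualities are
ignored throughout. A biallelic heterozygous SNP is called at a column
with top-two base counts c₁ ≥ c₂ (c₂ ≥ 1) and depth d when, inclusively,

* d ≥ `min_depth` (default 10),
* (c₁ + c₂)/d ≥ `major_frac` (default 0.90),
* (c₁ − c₂)/d ≤ `max_diff` (default 0.20).

The difference rule is read as a fraction of total depth, matching how the
90% rule is phrased; both are configurable. Ties for the two major
alleles break by base order A<C<G<T. Raising `min_depth` or `major_frac`,
or lowering `max_diff`, can only shrink the call set (tested property).

Because the homokaryons are themselves diverged from the reference,
a heterokaryon "het" SNP whose position is also called in either
homokaryon is treated as a strain-versus-reference difference (or a
duplication artifact) and removed. The default match is by position only
— "also detected" does not require the same alleles; a strict
same-allele-pair mode is available (`snp_filter_match_alleles`).

## Read-backed haplotype windows

Each MAPQ-passing read is reduced to the bases it carries at called het
SNPs (sites under clips/deletions, N calls, and bases matching neither
called allele are dropped; a strict mode discards reads with a
neither-allele base instead). Reads phased by at least k = 5 het SNPs
contribute an allele string to a *window* keyed by the scaffold and the 5
SNP positions. Two policies exist:

* **leading** (default): one string per read, over its first 5 phased
  sites — read counts stay additive across windows;
* **sliding**: every run of 5 consecutive phased sites contributes; a
  read is recombinant if any of its windows says so, and still counts
  once in summaries.

Within a window of 5 biallelic sites the string universe is 2⁵ = 32. The
two most frequent strings are designated parental (ties break
lexicographically; a single observed string is parental with no
recombinants), and the remaining up to 30 strings are recombinant.
Parental designation is per window and per sample; no global phasing
across windows is attempted. Mates of a read pair are treated as
independent reads and never merged.

## Cross-sample recombinant filter

Recombinant-looking haplotypes also arise from duplications and repeats —
the homokaryons themselves show ~19–20% "recombinant" reads. A
heterokaryon recombinant string is therefore excluded when a window with
the identical scaffold and identical 5 SNP positions in either homokaryon
contains the identical string classified recombinant there. Excluded
strings' reads are removed from both the recombinant and the total
counts; parental strings are never removed; heterokaryon windows with no
same-positioned homokaryon window are retained unfiltered (the
conservative reading).

In the full pipeline the "filtered heterokaryon" column is produced by
(1) removing shared SNPs, (2) rebuilding windows on the reduced SNP set,
and (3) applying the shared-recombinant exclusion. For step 3 the
homokaryon reads are phased *at the heterokaryon's filtered SNP
positions*: if homokaryon windows were keyed by their own SNP sets, the
position-level SNP filter would make the two filters operate on disjoint
regions and step 3 could never fire. Each homokaryon's own summary column
still uses its own SNP set. Percentages are rounded half-up to 2 decimals.

## Region fold enrichment

The annotation partitions every genomic bp into genic/intergenic (exon
and intron sub-labels appear only when the annotation has exon features;
overlapping genes are unioned). A recombinant read counts at the label of
its alignment midpoint — the assignment rule is a package choice;
bp-overlap weighting was considered and left out as it changes folds only
at region boundaries. A region's fold enrichment is its share of
recombinant reads divided by its share of genome bp, so the
genome-share-weighted mean fold is exactly 1 when all reads fall inside
the partition.

## Synthetic data generator

The generator emulates the sequencing design the pipeline targets:
250 bp reads at ~30–43× depth, ~1 het SNP per kb, two parental
haplotypes, a fraction of recombinant source molecules, substitution
errors, and a stated fraction of alignments with MAPQ < 10.

* **Reference & annotation.** Uniform-random A/C/G/T scaffolds;
  fixed-size gene blocks tiled so the genic share matches
  `genic_fraction` (default 0.4) up to one block.
* **Haplotypes.** Parental 1 *is* the reference (so simulated alignments
  are exact and no external aligner is involved); parental 2 differs at
  the SNP table's positions. The per-scaffold SNP count is
  Binomial(L, `snp_rate`), but positions are placed in clusters of
  `snp_cluster_size` (default 6) with 2–12 bp gaps: observed fungal
  heterozygosity is locally dense (five het SNPs within ~18 bp in the
  motivating data), and with uniform placement at 10⁻³/bp a 250 bp read
  would essentially never cover 5 SNPs, making read-backed windows
  unobservable.
* **Molecule pool.** `n_molecules` (default 200) scaffold-length
  molecules per scaffold; each is an independent
  Bernoulli(`recomb_fraction`) single-crossover mosaic with its cut drawn
  uniformly over inter-SNP intervals (interval first, then position —
  the data give no breakpoint distribution) and random orientation;
  non-recombinant molecules alternate evenly between the parentals.
  Molecules may be segment-restricted, which concentrates their reads
  locally the way duplicated copies do. Multiple crossovers per molecule
  are out of scope.
* **Reads.** `round(depth·L/250)` reads per scaffold; molecule chosen
  proportionally to its eligible extent, start uniform within it.
  Substitution errors per base at `error_rate`; `mapq_low_fraction`
  (default 0.05) of reads draw MAPQ uniformly from 0–9, the rest get 60.
  Base qualities are constant (never used). Paired-end sequencing is
  modeled as independent single-end reads, consistent with the pipeline's
  never-merge rule.
* **Homokaryon-like samples** (`simulate_trio`) are pure own-parental
  except inside deterministic "duplicated" blocks covering
  `hom_het_fraction` (default 0.3) of each scaffold, where other-parental
  segment molecules add a `hom_minor_fraction` (default 0.5) coverage
  share — emulating the duplication-driven apparent heterozygosity of
  real homokaryons, with the doubled local depth real duplications show.
* **Injected events** (`shared_recombinant_scenario`) are reciprocal
  crossover pairs — both orientation mosaics at the same cut — so the
  injection leaves allele counts balanced at flanking SNPs, exactly as a
  real crossover would.

Everything is a deterministic function of `SimConfig` including `seed`;
a trio derives per-sample streams from one seed sequence.

What the generator does **not** emulate: indels, quality-score error
models, PCR duplicates, insert-size structure, GC bias, mapping ambiguity
(MAPQ is assigned, not computed), multi-crossover molecules, and real
repeat architecture. Passing tests therefore demonstrate the *inference
rules* are implemented correctly and recover planted signal under the
assumed read model — not that the thresholds are optimal on real genomes.

## Recovery experiments and their statistics

`recombiscan.evaluate.recovery_run` simulates one sample, runs SNP
calling and phasing, and compares the estimated recombinant read count
with the truth-derived expectation: a phased read is expected recombinant
iff its source molecule's cut has at least one of the read's window SNPs
on each side. At the default conditions (200 kb, 10⁻³ SNPs/bp, depth 35,
error 10⁻³) only a handful of phased reads straddle a cut, so recovery
checks pool counts over three seeds and compare fractions within three
binomial standard deviations, computed from the larger of the two
fractions so the bound is defined when either is zero. A
recombination-free run bounds the error-driven false-call floor
(≤ 0.5%); sequencing errors can only inflate the estimate (tested at
error 0.01 vs 0).

## Numerical and degenerate-input choices

Coordinates are 1-based in SNP tables and GFF3 (VCF/GFF convention);
alignment internals use pysam's 0-based API. Zero-read summaries report
percentages as not available instead of dividing by zero. A window with
one observed string has one parental and no recombinants. k < 2 windows,
invalid rates, out-of-bounds annotation intervals, unsorted un-indexed
alignments, and coordinate-system mismatches raise explicit errors. An
expected SNP count below 5 per scaffold warns that windows are
impossible. Percentages use decimal half-up rounding, not binary
round-half-even.

## Problem sizes used in the test suite

Unit tests use 20–100 kb single-scaffold genomes; recovery experiments
use 200 kb at depth 35 with three seeds per condition; the
shared-recombinant scenario uses 100 kb at depth 80 so injected window
strings are observed with comfortable margins. These sizes make every
stage's behaviour measurable while keeping the whole suite fast enough to
run routinely.

## Known limitations

* The shared-recombinant filter requires exact 5-position window
  identity; diverged SNP sets between samples reduce its reach (the
  pipeline mitigates this by phasing homokaryons at the heterokaryon's
  SNP positions for the comparison step).
* Frequency-based parental designation can misclassify in windows with
  very few reads; at the default depth windows collect tens of reads and
  this is negligible.
* Breakpoints are not fine-mapped and crossover interference is not
  modeled; the per-read estimate measures window-level recombinant
  fraction, not a recombination rate per bp.
* An external aligner is deliberately out of scope: the pipeline consumes
  already-aligned reads, and the simulator emits exact alignments.
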