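# Methods

## Problem setting

Early-multiplexed 3'-end RNA-seq protocols (BRB-seq style) tag every sample
during reverse transcription with a barcoded oligo-dT primer whose tail also
carries a unique molecular identifier (UMI). All samples are pooled into a
single library; read 1 of each pair sequences only the tag (sample barcode +
UMI), read 2 the cDNA fragment. The informatics problem this package solves
is everything downstream of the sequencer and the aligner: assigning read
pairs back to samples, turning aligned cDNA reads into per-gene read and
molecule counts, quality-controlling the library, depth-matching libraries
for fair comparison, and quantifying how well a protocol or depth detects
differential expression.

## Read-tag model and demultiplexing

The tag layout is expressed as a compact string `B<b>N<n>V<v>`: a barcode of
`b` nt, `n` fully random UMI bases, and `v` random non-T bases that buffer
the UMI from the oligo-dT stretch (non-T because a T-rich UMI tail would
anneal preferentially to the poly-A). The default `B6N10V5` gives a 6 nt
barcode and a 15 nt UMI, i.e. 21 cycles of read 1.

Barcode matching assigns an observed barcode to the unique known barcode at
minimal Hamming distance, provided that distance is at most `max_mismatch`
and strictly smaller than the runner-up; ties are always unassigned
(`ambiguous`), never broken arbitrarily. `N` bases never match. The default
tolerance is 0 mismatches because commonly used barcode sets are not
guaranteed error-correcting; `--max-mismatch 1` is safe for sets with
pairwise distance ≥ 3 and is verified by a property test. Assigned cDNA
reads are written one FASTQ per sample with `_<BARCODE>_<UMI>` appended to
the read name, so counting never needs the tag stream again. Optional
trimming removes the earliest adapter occurrence and a trailing poly-A run
(default minimum run 10, minimum surviving length 20, no adapters unless
given — trimming is conservative and off by default).

## Gene assignment and counting

The gene model is built from a GTF: exons are grouped by `gene_id`,
converted to 0-based half-open coordinates, and overlapping or adjacent
exons of one gene are merged. Assignment is union-mode: a read's aligned
blocks (CIGAR M/=/X; N introns skipped) collect the set of genes they
overlap, filtered for strand compatibility (`forward` by default: the read's
strand must equal the gene's; configurable because protocols differ).
An empty set is `no_feature`, more than one gene `ambiguous`, secondary or
supplementary records and NH > 1 `multimapped`; no MAPQ cutoff is applied.

Counting produces two genes × samples matrices: `reads` counts
feature-assigned records; `umis` counts distinct UMI strings per
(gene, sample), excluding UMIs containing `N` (such reads still count as
reads). UMI collapse is exact string identity — no mismatch merging —
so `umis ≤ reads` holds cell-wise by construction. Matrices round-trip
through dense TSV and sparse MatrixMarket (with gene/sample sidecars).

## QC metrics

* Alignment-category fractions per sample (mapped-to-gene / no-feature /
  ambiguous / multimapped / unmapped); they sum to 1 by construction.
* Mitochondrial rRNA contamination: counts on MT-RNR1 and MT-RNR2 only, the
  two genes that dominate any mitochondrial signal; the gene list is
  configurable.
* Detected genes: genes with count strictly above each threshold
  (0, 1, 5, 10 by default); non-increasing in the threshold.
* UMI-based duplication: 1 − ΣUMIs/Σreads per sample — an unbiased
  duplication estimate that, unlike coordinate-based duplicate marking,
  does not inflate with depth.
* Gene-body coverage: every aligned base of a feature-assigned read is
  projected into the spliced (merged-exon) coordinates of its gene,
  oriented 5'→3' (reversed for minus-strand genes), and accumulated into
  100 bins; the profile is scaled so its maximum bin equals 1, and raw
  per-bin aligned-base totals are also emitted. Spliced rather than genomic
  span coordinates are used so intron-containing genes do not dilute the
  profile.
* Sample correlation: Pearson r on log2(count + 1) over the gene
  intersection; the pseudocount of 1 handles zeros.

## Downsampling

Depth-matched comparisons downsample at the alignment level (after mapping,
before counting) so mapping artifacts are not resampled. The sampling unit
is the distinct query name — all records of a chosen read stay together —
drawn uniformly without replacement with numpy's PCG64 generator; the seed,
input digest and target are recorded in a JSON manifest. Replicate
downsamples (default 10) use seeds `base_seed + i`. Exactness (output
distinct-read count equals the target), byte-level seed determinism, and
hypergeometric consistency of downstream per-gene counts are all tested.

## DE evaluation against a gold standard

A deeply sequenced reference defines a self-assigned gold standard: its DE
genes at |FC| ≥ 2 and BH FDR ≤ 0.05 are the positives; all expressed genes
form the universe, the rest of which are negatives. A method's DE table is
scored by:

* empirical power — |called ∩ positives| / |positives|;
* ROC and precision-recall curves built by sweeping every cutoff of the
  ranked p-value list: at cutoff p*, genes with p ≤ p* are called and FPR,
  TPR and precision recorded. Universe genes missing from a table are
  penalized with p = 1 so that compared methods share a fixed universe.
  AUCs are trapezoidal over the swept points; on dense rankings this is
  numerically equivalent to rolling-mean integration, and the construction
  is tested against exhaustive threshold enumeration including ties.

The minimal depth at which a gene of expression `cpm` is detected (≥ 1
read) with probability `prob` has the closed form
D = ⌈ln(1 − prob) / ln(1 − cpm/10⁶)⌉, verified against Monte-Carlo binomial
detection frequencies.

## Negative-binomial power simulation

`estimate_nb_params` normalizes counts by median-of-ratios size factors and
computes per-gene method-of-moments dispersions max((var − mean)/mean², 0)
(within-group variances when labels are given), then fits a log-linear
mean–dispersion trend. `simulate_de_counts` draws a two-group experiment:
exactly round(frac_de · n_genes) genes get |log2FC| ~ Gamma(shape 2,
scale 0.5) with random sign — a narrow distribution centred near 1 —
applied symmetrically (group means μ·2^(±lfc/2)); counts are NB with the
trend (or supplied) dispersion, Poisson in the zero-dispersion limit.
Defaults are 10,000 genes with 10% DE; baseline means are log-normal
(median ≈ 7 counts) unless empirical parameters are resampled. Dropout
modeling is omitted: the simulation targets bulk libraries where dropout is
secondary.

The built-in two-group caller is a deliberately simple moment-based Wald
test: difference of log size-factor-normalized group means, delta-method
standard error from the NB variance μ + φμ² with pooled MoM dispersion,
referred to a t distribution with n₁+n₂−2 degrees of freedom (the t
reference, rather than the normal, keeps the test at its nominal level for
small per-group n; measured type-I error is 5–6% at α = 5% on null NB
data). It is plumbing, not a DESeq2 reimplementation — externally produced
DE tables are accepted by every evaluation function. `power_curve` averages
the TPR at BH FDR 0.05 over seeded simulations per replicate level
(default levels 5, 20, 50).

## Synthetic library generator

The generator produces the full computational signature of a run: per
molecule a UMI (N segment uniform over ACGT, V segment uniform over ACG), a
PCR duplication factor ~ Geometric(p) (support ≥ 1, mean 1/p; default
p = 0.5, i.e. mean 2 reads per molecule), and a fragment whose 3' end sits
at an Exp(scale = 100 nt) distance from the transcript's 3' terminus —
reproducing the 3'-biased gene-body profile of oligo-dT priming.
Transcripts are synthetic random DNA; SAM positions and CIGARs (with N
operations across introns), not sequence homology, define truth. Reads can
be converted to unmapped, multimapped (NH = 2) or intergenic at
configurable fractions, barcode errors of exactly one mismatch can be
injected, and per-base substitution errors applied to the cDNA read. The
per-read bookkeeping yields exact expected read/UMI matrices, making
end-to-end recovery testable bit for bit.

What the generator does not emulate: base-quality structure (all qualities
are constant), indels and soft-clipping, alignment errors (truth positions
are used directly, standing in for an upstream aligner), barcode-set
cross-talk beyond substitutions, and biological covariance between genes.
Passing tests therefore demonstrate the correctness of the bookkeeping,
matching and counting logic under the protocol's read-structure model, not
robustness to aligner idiosyncrasies on real genomes.

## Problem sizes and numerical choices

Default test and acceptance scales: end-to-end recovery uses 4 samples ×
200 genes × 50,000 molecules (~100,000 reads); calibration uses 2000 null
genes at 10 replicates per group; dispersion recovery 1000 genes × 50
samples; the power curve 1000 genes × 20 simulations per level. These sizes
give stable statistics while keeping the whole suite fast on a single CPU.
Ties in barcode distance and in p-value ranking are handled explicitly
(ambiguous; grouped thresholds). Degenerate inputs are defined rather than
special-cased ad hoc: all-zero genes get p = 1 and log2FC = 0, empty
samples get zero fractions, an all-zero coverage profile stays zero, and
zero-length UMIs (UMI-free mode `B6`) yield an all-zero UMI matrix.

## Known limitations

* UMI collapse ignores sequencing errors inside the UMI (no directional
  network merging); with 15 nt UMIs and per-base error ~0.1% the resulting
  molecule overcount is small but systematic on deep data.
* The built-in DE test's moment dispersion estimates are noisy below ~5
  replicates per group; power estimates at n = 5 are accordingly
  conservative relative to shrinkage-based callers.
* `downsample` holds the distinct-name list in memory (fine up to tens of
  millions of reads; not streaming-constant).
* The GTF reader supports the ubiquitous `key "value";` attribute grammar
  only, and one chromosome/strand per gene id.
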