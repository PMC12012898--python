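# Methods

This note records the models, parameter choices, and numerical conventions
behind `triohap`, and what the synthetic-data experiments do and do not
establish about real data.

## Trio binning and hap-mer algebra

All k-mer work is on canonical k-mers: the lexicographic minimum of a k-mer
and its reverse complement. k must be odd (no self-complementary k-mers) and
defaults to 21. With the A<C<G<T 2-bit encoding, lexicographic order equals
numeric order of the packed codes, so sets are sorted uint64 arrays and all
algebra is vectorized. Windows containing non-ACGT symbols are skipped.

**Solid k-mers** are k-mers whose read-set multiplicity lies in a coverage
window [low, high]. "Solid" is interpreted as *error- and repeat-filtered*
rather than multiplicity exactly 1: in raw reads every true genomic k-mer
appears roughly coverage-many times, so uniqueness can only be meant against
the coverage distribution. When thresholds are not given, `low` is the
multiplicity at the interior minimum between the error peak (multiplicity 1)
and the main coverage peak of the histogram — found by walking down from
multiplicity 1 until counts stop decreasing — and `high` is 4× the main peak
multiplicity. A histogram without an interior minimum (e.g. error-free
simulated reads) has no defensible automatic split, so the code demands
explicit thresholds instead of guessing.

**Hap-mers.** A parent's hap-mers are its solid k-mers shared with the hybrid
*minus the other parent's solid set*. The subtraction is essential: without
it, sequence shared by both parents would sit in both hap-mer sets and the
exclusive-evidence rule below would leave nearly every read ambiguous. This
matches the haplotype-marker concept of Merqury-style evaluation. The two
sets are disjoint by construction and the `HapmerPair` container asserts it.

**Read classification** is exclusive-evidence: a read is maternal iff ≥1 of
its distinct canonical k-mers is a maternal hap-mer and none is paternal
(symmetrically paternal); both-or-neither is ambiguous. Reads shorter than k
are ambiguous with zero evidence, not errors. Binning conserves reads: every
input lands in exactly one of maternal/paternal/ambiguous/skipped.

**Phasing QC.** For an assembly claiming haplotype *own*:

* recovery = 100 × |own hap-mers present| / |own hap-mers|;
* contamination = 100 × |opposite hap-mers present| / |hap-mers of either
  type present in this assembly| — this denominator (not defined in the
  procedures we re-implement) makes the two per-assembly percentages sum
  to 100 and is robust to hap-mer set size imbalance;
* completeness = 100 × |read-solid k-mers present| / |read-solid k-mers|;
* QV: with f the fraction of assembly k-mers found in the read set,
  P = f^(1/k) is the per-base correctness implied by assuming independent
  base errors (an erroneous base corrupts up to k k-mers), E = 1 − P, and
  QV = −10·log10(E), capped at 99 when E = 0. An empty assembly returns
  zeros with a `degenerate` flag.

**Telomeres.** Maximal runs of the plant motif TTTAGGG (forward) and its
reverse complement CCCTAAA (reverse strand) with inter-copy gaps ≤ 100 bp;
runs of ≥ 10 copies are reported (observed real arrays start around 12), with
a terminal flag inside 10 kb of a sequence end. Coordinates are 0-based
half-open; BED6 output uses the repeat count as score.

## Diagnostic-SNP ASE

A position is a diagnostic SNP iff both parental pileups have depth ≥ 10,
each major allele carries ≥ 90% of its depth, and the major alleles differ.
The thresholds are package defaults — the upstream tool this mirrors does not
publish its values — and both are exposed. Assignment is strict consensus by
default: every covered diagnostic site must support the same parent, any
conflict unassigns the read (`conflict`), no covered site unassigns it
(`no_sites`). A majority mode (> 50% of supporting sites, ties unassigned) is
available but not default; strict is conservative and reproduces the presence
of a substantial unassignable fraction on real data. Reads overlapping
several genes count once, toward the largest overlap, ties to the lowest gene
id. Pileup I/O is 1-based; everything internal is 0-based half-open.

## Allele pairs

Homology hits come from a standard 12-column tabular search file or, at
fixture scale, from Biopython's local affine-gap aligner (BLOSUM50, gap −8
for proteins). Hits need score ≥ 50 and aligned fraction ≥ 0.5. Collinear
blocks are chained by O(n²) dynamic programming over hit anchors in gene-rank
space: strictly monotone on both sides (anti-monotone on one side for
inverted blocks), rank gaps ≤ 25 genes, chain score = Σ hit scores − 1.0 per
skipped rank; anchor-disjoint chains of ≥ 5 pairs are reported greedily, best
chain first, which is exact for a single dominant chain and matches exhaustive
enumeration on all tested anchor sets ≤ 12. Block-size and gap defaults
follow the common defaults of the collinearity tool this mirrors, which the
source study did not parameterize. Orthogroups are single-linkage connected
components over hits — a deliberate, documented approximation of full
orthology inference that is adequate for two haplotypes of one genome. An
allele pair must lie in a block *and* in a one-maternal/one-paternal
orthogroup; tandem duplicates therefore drop out, and each gene pairs at most
once.

## Expression statistics

Size factors are median-of-ratios (reference = per-gene geometric mean over
samples; genes with any zero excluded). FPKM(g, s) = 10⁹·c/(L·N).

The NB two-group test approximates the DESeq2 procedure; exact numerical
agreement with that package is a non-goal — calibration and recovery are the
contract, and both are tested. Per gene: normalized counts q = c/sf, group
means μ, and a method-of-moments dispersion from pooled within-group
variances, var(q) ≈ μ·mean(1/sf) + φμ². A trend φ(μ) = a + b/μ is fitted by
least squares with one 10%-trimmed robustness pass, and the working
dispersion is max(φ_gene, φ_trend): with 3 replicates the moment estimator is
noisy and its downward errors inflate the Wald statistic, so the trend acts
as a floor while genuine over-trend outliers keep their own estimate. The
Wald statistic is ln((μ_B+½)/(μ_A+½)) over its delta-method SE,
√(Σ_groups (mean(1/sf)/μ + φ)/n), against the standard normal; BH-adjusted
p-values are reported alongside raw ones. Thresholds are applied to *raw*
p-values (the source analyses write "P < 0.01" without specifying adjustment);
all thresholds are arguments. Under the NB null (2,000 genes, n = 3,
φ = 0.05) the raw p < α frequency sits within 3 binomial SDs of α for
α ∈ {0.05, 0.01}, and power at a planted 8-fold change (means 50 vs 400)
exceeds 0.95 at the species thresholds |log2FC| > 2, p < 0.01.

**Expressed filter**: summed raw counts ≥ 10 in each parent (interpreted as
per-species sums; the source does not say per-replicate vs summed).

**MPV.** Mid-parent pseudo-replicate i is the rounded mean of the two
parents' normalized counts at replicate index i (pairing by index; the MPV
construction is not described in the source and this is the package's
choice). The hybrid is tested against these pseudo-replicates (size factor 1)
at |log2FC| > 1, p < 0.01; non-significant genes are additive. Note that
median-of-ratios normalization absorbs a fold shift shared by *all* genes;
additivity recovery is therefore meaningful when nonadditive genes are a
minority, as in the planted designs (and in real transcriptomes).

**Mode decision table.** Let s12, sh1, sh2 be the significance signs of
parent2-vs-parent1, hybrid-vs-parent1, hybrid-vs-parent2. The table is total
over all 27 combinations: hybrid above (below) both parents is
over(under)dominance regardless of s12; with parents equal and nothing else
significant, conserved; with parents different and the hybrid different from
neither, additive (intermediate); hybrid equal to the higher parent and above
the lower is high-parent dominance (mirrored for low-parent); every remaining
combination is ambiguous. Low-parent dominance and underdominance are
included for totality even though the source study only names the upper
categories. A mid-parent hybrid between 4-fold-spaced parents is
*significantly above the low parent*, so the three-way table files it as
intermediate/dominant patterns — additivity is therefore always judged by the
MPV test, which is also how the source defines it; planted-additive recall is
measured on that route.

**ASE.** The model test treats maternal and paternal columns as two groups
with a shared per-replicate size factor from total assigned allelic counts
(whether the source used allele-specific or combined library sizes is not
stated; combined is the default here). ASEG: raw p < 0.01 and |log2FC| > 1,
labeled by the higher allele. The ratio rule computes
r = maternal/(maternal+paternal) per replicate and calls maternal when
r > 0.7 in ≥ 2 usable replicates (paternal for r < 0.3); zero-total
replicates are excluded and counted, and genes with < 2 usable replicates are
balanced with an `insufficient_data` flag. r is invariant to shared library
scaling, so FPKM and counts give the same calls on equal gene lengths.

Percentages in pathway tables are computed with decimal round-half-up to 2
places, matching the printed style of the tables they reproduce, and always
recompute exactly from the printed counts.

## Synthetic data: what it emulates, and what it does not

Defaults encode the study conditions: divergence 4.6% (the hybrid's reported
heterozygosity), k = 21, 30× coverage, 150 bp reads, 3 replicates per
species, NB dispersion φ = 0.05, 4-fold planted effects, planted allelic
fractions {0.2, 0.5, 0.8}, mode proportions (conserved 0.30, additive 0.30,
high-parent 0.15, low-parent 0.05, over- 0.10, underdominance 0.10), and gene
means log-uniform on [50, 800] — values a small flower-transcriptome
experiment would plausibly show where the study states none. Divergence is
substitution-only by default so both haplotypes share coordinates and the
variant table doubles as diagnostic-SNP truth; gene models are single-exon,
non-overlapping, and identical across haplotypes, matching the one-to-one
allele-pair situation. Reads have uniform starts, both strands, uniform
substitution errors, constant FASTQ qualities. One top-level seed
deterministically derives per-stage generators (SHA-256 of seed:stage), so
identical configs give byte-identical bundles.

Not emulated: indels and structural variation, position- and quality-
dependent error profiles, GC and mappability bias, isoform structure,
paralogy beyond what tests construct explicitly, and real alignment noise
(alignments enter as pileups/tables by design). Passing tests therefore
demonstrate the correctness of the *computations* under their stated models,
not robustness to alignment artifacts or non-SNP divergence.

Linear 100 kb toy genomes also have edge effects real chromosomes dilute:
k-mers within a read length of a sequence end are undersampled, which can
push them out of a read-derived solid window and create spurious hap-mers at
d = 0. The identity property (identical parents ⇒ empty hap-mer sets ⇒ all
reads ambiguous) is exact on genome-derived k-mer sets and is tested that
way; read-derived binning at the study's divergence is unaffected (accuracy
> 99.9% on variant-bearing reads).

## Problem sizes and runtime choices

Simulations are sized for a desk run: 100 kb genomes for binning (~20,000
hybrid reads), 2,000 genes for calibration and mode recovery, 500 genes for
ASE agreement, ≤ 12 anchors where exhaustive enumeration is the oracle.
In-memory k-mer counting is sized for such fixtures, not gigabase genomes
(an explicit non-goal). Stage manifests record SHA-256 checksums and omit
wall-clock timestamps so that reruns are checksum-identical.
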