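# Methods

This note documents the models, estimators and design choices behind
`haplotx`, and what the synthetic-data tests do and do not demonstrate
about real data.

## The measurement problem

An F1 homoploid hybrid carries the two parental subgenomes side by
side. Mapping its RNA-seq reads to the concatenated two-haplotype
transcriptome yields, per 1:1 orthologue pair, two counts that would be
a clean within-plant comparison of the parental alleles — except that
reads from weakly diverged homeologs cross-map. All downstream
inference (haplotype bias, per-haplotype shade response) is only as
good as the set of gene pairs whose reads can be assigned reliably.
The pipeline therefore calibrates assignability empirically from
inbred parental samples, where the true source haplotype of every read
is known, and restricts analysis to pairs passing a median-accuracy
filter.

## Synthetic-data generator

The generator is the package's testbed: it produces inputs with the
statistical structure the analysis assumes plus the ground truth needed
for parameter-recovery tests.

**Misassignment model.** A read of length R from a homeolog with
per-site divergence d overlaps at least one diagnostic site with
probability 1 − e^(−dR); reads without a diagnostic site are split
50/50 between the pair. The per-gene probability of landing on the true
transcript is hence a = 1 − ½e^(−dR) ∈ (0.5, 1]. This is a minimal,
analyzable stand-in for aligner behaviour — it is symmetric between
haplotypes, ignores positional and GC bias, indels and paralogy, and
treats reads as independent. Divergence is Gamma-distributed
(shape 2, mean 0.015 substitutions/site, the Ks scale of a ~1 Ma
species split), read length defaults to 150 bp.

**Counts.** Per gene and haplotype, fragment counts are negative
binomial with variance μ + αμ² (gamma–Poisson mixture), gene-wise
dispersion log-normal (median e^(−3) ≈ 0.05), library-size factors
uniform on a log scale across ±1.5×. Hybrid means are
s·λ·2^(β·shade + h·γ) with h ∈ {0,1} the haplotype indicator; 15% of
genes carry a shade effect |β| = 1.5 log2 units and a disjoint 10% a
haplotype bias |γ| = 1.5 (disjointness keeps truth evaluation
unambiguous). Observed counts arise by binomial thinning at accuracy a
with the complement routed to the partner transcript, which conserves
pair totals exactly. Parental inbreds express a single haplotype,
misassigned by the same a. TPM is counts/effective-length rescaled to
10⁶, with effective length max(1, L − R + 1); fragments, not reads, are
simulated (one transcript per gene, no isoforms).

**Design.** 4 timepoints × 2 tissues × 3 replicates for hybrid and
inbred *Z. marina*, with a flag (default on) dropping three *Z. marina*
replicates as in an unbalanced real campaign, plus 7 wild-collected
*Z. pacifica* samples with no timepoint.

**GO structure.** A random is_a DAG over 60 synthetic terms plus a
root; three target terms are associated with shade-DE genes at
probability 0.6 and with others at 0.04, background terms at ~3 per
gene. This spikes a strong, recoverable enrichment signal.

**Genomes, coverage, codons.** Clones are iid-error copies
(ε = 10⁻⁴/base) of one genotype; distinct genotypes diverge from a
common ancestor at 5 × 10⁻³/base. Coverage is per-base Poisson(λ) for
chromosomes and Poisson(ρλ) for the plastid. Codon pairs evolve by
accepted point substitutions with relative rates 1 : ω for
synonymous : nonsynonymous (the faster class accepted with probability
1), rejecting stop codons.

Every generator is a pure function of (config, seed).

## Calibration

Per (gene pair, parental sample): accuracy = expected/(expected +
unexpected) reads, undefined when the pair drew no reads — such samples
are excluded from the gene's median rather than counted as zero, which
is what makes the median robust to low-coverage samples. Medians pool
both parents' sample sets (a per-parent breakdown is also emitted;
with symmetric accuracy the two views coincide in expectation).
Retention requires median accuracy **strictly** greater than τ = 0.90.
The retained set's share of hybrid transcription is the TPM sum over
retained transcripts (both haplotypes) divided by the total TPM over
all hybrid samples.

One reading correction is baked in: the expected transcript for
*Z. pacifica* samples is Hap2 (the *Z. pacifica*-derived haplotype);
treating Hap1 as expected for both parents would make the statistic
meaningless.

## Differential expression engine

The engine is a deliberate re-implementation of the standard
negative-binomial Wald recipe rather than a wrapper around an existing
DE package; exact numerical parity with any published tool is a
non-goal, while its error control and recovery are tested directly.

* **Size factors** — median-of-ratios against the geometric-mean
  reference over genes positive in all samples; computed separately per
  dataset (each hybrid track × tissue matrix, the *Z. marina* matrix,
  each split matrix), since the datasets are analysed independently.
* **Dispersion** — per-gene method of moments on normalized counts,
  α̂ = Σ(n_g−1)(v_g − x̄·m_g) / Σ(n_g−1)·m_g² pooled over groups
  (x̄ = mean 1/s_s corrects the normalization), clamped at 0. Moments
  are taken **within** group so that real condition effects do not
  masquerade as overdispersion; with marginal moments a true 1.5-log2
  shift would inflate α several-fold and destroy power. A trend
  α(μ) = a₀ + a₁/μ is fitted by non-negative least squares over genes
  with positive moment estimates, and the final dispersion is the
  geometric mean of the per-gene estimate and the trend value, floored
  at 10⁻⁸ (genes with zero moment estimate fall back to the trend).
  For the bias contrasts, dispersion is estimated once on the full
  split matrix with (timepoint × haplotype) cells, then shared by the
  per-timepoint 3 vs 3 contrasts — at that sample size per-contrast
  estimates would be too noisy to control error.
* **Wald test** — per gene, log-link NB GLM (intercept + group
  indicator, log size factors as offset) fitted by IRLS (≤50
  iterations, |Δβ| < 10⁻⁸); SE from the Fisher information at the
  fit; two-sided normal p-value. Genes with no reads in both groups,
  or non-converging fits, carry undefined p and are excluded from the
  BH family. No independent filtering, no LFC shrinkage, no outlier
  replacement — the simplest defensible engine.
* **Significance** — BH-adjusted P ≤ 0.05 and |log2FC| ≥ 0.5.

Shade response is the union over the (t2+t3) vs t1 and (t2+t3) vs t4
contrasts — a gene needs to separate from either the control or the
recovery baseline, not both. *Z. marina* counts sum the two haplotype
mappings per pair (a single-track mode is available), since for the
diploid parent both mappings sample the same locus. Bias contrasts
treat the Hap1/Hap2 subsamples as unpaired groups; they share a plant,
so this is mildly conservative.

Measured behaviour at the simulator's conditions (n = 6 vs 3,
mean ≥ 100): null false-call fraction ≤ 0.002, null p-value KS distance
from uniform ≈ 0.02, recall ≥ 0.9 for |β| = 1.5 spikes with sign
agreement ≈ 1. The plug-in dispersion makes the Wald statistic slightly
heavier-tailed than normal at small n; the significance rule's fold-
change condition absorbs this in practice.

## GO enrichment

Hypergeometric upper tail P(X ≥ k) per term with population count
K ≥ 1 (K = 0 terms are excluded from the BH family), fold enrichment
(k/n)/(K/N), BH across tested terms, significant at padj < 0.05.
Annotation propagation to is_a/part_of ancestors is available but off
by default, and the default population is the retained orthologue set
for hybrid tracks (all tested genes for *Z. marina*) — both choices are
exposed because either convention is defensible.

## Comparative genomics

**K-mers.** Canonical form is the lexicographic minimum of a window
and its reverse complement; k defaults to 21 and must be odd (no
self-complementary k-mers) and within [11, 31]. Windows containing
non-ACGT characters are skipped. Jaccard = |A∩B| / |A∪B|; clustering
is average-linkage (UPGMA) on 1 − J with leaves sorted
lexicographically before linkage so ties resolve deterministically.
No absolute clonality threshold is imposed: with sequencing/consensus
error ε the expected within-clone Jaccard is roughly e^(−2kε) ≈ 0.996
at defaults, far above between-genotype similarity at 5 × 10⁻³
divergence (~0.81), and only this ordering is treated as meaningful.
Windowed conservation tiles a chromosome into non-overlapping windows
(last partial window kept at true width) and reports the fraction of
each window's k-mers found in a pool.

**Ka/Ks.** Nei–Gojobori (1986) counting: per-codon site counts by
mutational fraction (mutations to stop codons count as nonsynonymous),
averaged between the two sequences; differences averaged over all
minimal substitution paths, excluding paths through stop codons
(falling back to all paths if every path is blocked); Jukes–Cantor
correction d = −¾ ln(1 − 4p/3) applied to pS and pN, undefined at
saturation p ≥ 0.75. Codons with gaps or ambiguity in either sequence
are dropped pairwise. NG86 was chosen over likelihood-style estimators
because its counts are exactly checkable against brute-force path
enumeration (the suite sweeps all 61 × 61 sense-codon pairs); on the
purifying/neutral/positive regimes the simulator produces, the ω ≷ 1
classification matches the generating regime.

**Clock.** T = Ks / (2r), r = 6.5 × 10⁻⁹ synonymous
substitutions/site/year (rice-calibrated, standard for monocots). Both
mean and median Ks summaries are reasonable inputs; the scripts report
per-pair values and leave the summary to the caller.

**Plastid ratio.** Median per-base plastid depth divided by the mean
over chromosomes of each chromosome's mean depth. The median on the
plastid side resists local repeats/collapsed regions; the mean of means
weights chromosomes equally regardless of length.

## Numerical choices and degenerate inputs

IRLS linear predictors are clipped to ±30 to avoid overflow before
convergence; p-values are clamped into (0, 1] (smallest positive
float) so BH never sees exact zeros. Undefined accuracies, p-values
and ratios propagate as NaN with explicit flags rather than sentinel
numbers. Medians use standard lower/upper averaging, making them
order-invariant. All tabular I/O is UTF-8 TSV with `#` comments
skipped; coordinates are 0-based half-open throughout.

## Problem sizes in the test suite

The suite and the evaluation script run at reduced but study-shaped
sizes chosen to make the statistical checks sharp: 2,000 gene pairs for
calibration (16 parental samples, mean 50 reads/gene), 5,000 genes for
null error control, 2,000 for spiked recovery, 20 seeded replicates
for enrichment and clonality (100 kb genomes), complete 61 × 61 codon
sweeps for NG86. These are the package's own choices of simulation
scale.

## Limitations

Passing tests demonstrate correct implementation of the stated models
and good behaviour *under the generator's assumptions*. Real data add
aligner-specific cross-mapping asymmetries, positional/GC bias,
isoform complexity, correlated replicates and batch structure, none of
which the generator emulates; the calibration and DE results on real
studies therefore inherit the usual caveats of those tools. The DE
engine does not implement multi-factor designs, shrinkage estimators
or outlier handling, and the bias test ignores within-plant pairing.
NG86 differs from Yang–Nielsen/ML estimators when substitution rates
are strongly codon-position dependent; at the low divergences this
package targets (Ks ≲ 0.1) the difference is small relative to
sampling noise.
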