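# haplotx

Haplotype-resolved transcriptomics and comparative genomics for a
first-generation (F1) homoploid hybrid between two eelgrass species,
*Zostera marina* (haplotype 1) and *Z. pacifica* (haplotype 2).

Because the hybrid carries both parental subgenomes unrecombined, every
RNA-seq sample can be split post-mapping into a Hap1 and a Hap2
subsample, turning one plant into a direct within-individual comparison
of the two parental transcriptomes. The catch is cross-mapping: reads
from homeologs with few diagnostic variants land on the wrong haplotype
transcript. This package implements the full analysis chain around that
idea, together with a synthetic-data generator that reproduces the
statistical structure of such a study, so every step can be validated
against known ground truth.

## What it computes

**Cross-mapping calibration.** For each 1:1 orthologue pair, inbred
parental RNA-seq gives a per-sample mapping accuracy

    accuracy = expected reads / (expected + unexpected reads)

(expected transcript: Hap1 for *Z. marina* samples, Hap2 for
*Z. pacifica*). The per-gene **median** accuracy over the parental
sample set is thresholded strictly at τ = 0.90; only pairs above the
cut-off enter differential expression, and the fraction of hybrid
transcription (TPM) they represent is reported.

**Haplotype-split differential expression.** A negative-binomial Wald
engine (median-of-ratios size factors; within-group method-of-moments
dispersion with a 1/μ trend and geometric-mean shrinkage; log-link NB
GLM fitted by IRLS; Benjamini–Hochberg correction). Significance
requires adjusted P ≤ 0.05 **and** |log2FC| ≥ 0.5. Two designs:

* *shade response*: low-light timepoints (t2+t3) pooled as replicates
  vs full-light t1 (control) and t4 (recovery); a gene responds if
  significant in either contrast, separately per track (hybrid Hap1,
  hybrid Hap2, inbred *Z. marina*) and tissue (leaf, rhizome);
* *haplotype bias*: Hap1 vs Hap2 subsamples within each timepoint ×
  tissue.

**GO enrichment.** One-sided hypergeometric over-representation of the
up/down sets with BH correction (FDR < 0.05), fold enrichment
(k/n)/(K/N), optional is_a/part_of annotation propagation.

**Comparative genomics.** Canonical k-mer (default k = 21) Jaccard
similarity for clonality calls and UPGMA pangenome clustering; windowed
k-mer conservation along chromosomes; Nei–Gojobori (1986) Ka/Ks with
Jukes–Cantor correction; synonymous molecular-clock dating
T = Ks/(2r) at r = 6.5 × 10⁻⁹ substitutions/site/year; and the
plastid:nuclear coverage ratio (median plastid depth over average
chromosome mean depth) as a relative-organelle-copy-number proxy.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (2,000 gene pairs, the 4-timepoint × 2-tissue × 3-replicate design
with three lost *Z. marina* replicates, 7 wild *Z. pacifica* samples):

```bash
python analysis/01_simulate_experiment.py --seed 1
python analysis/02_calibrate_orthologues.py
python analysis/03_shade_differential_expression.py
python analysis/04_haplotype_bias.py
python analysis/05_go_enrichment.py
python analysis/06_comparative_genomics.py
```

Output from seed 1:

```
parental samples used: 28 (21 Z. marina, 7 Z. pacifica)
retained 1163 / 2000 orthologue pairs at median accuracy > 0.90
retained pairs represent 58.7% of hybrid transcription (TPM) across all samples
leaf     hybrid.hap1 :   93 up,  107 down in shade
...
leaf     t1:   55 Hap1-biased,   65 Hap2-biased
...
leaf     hybrid.hap1  up  : 3 enriched terms; top GO:7000000 fold=4.6 padj=2.69e-28
...
k=21 clonality: within-clone Jaccard >= 0.9916, between-genotype <= 0.6686
NG86: Ka=0.0024 Ks=0.0158 Ka/Ks=0.15 -> 1.21 Ma at r=6.5e-9
plastid:nuclear coverage ratio 100.0
```

Reading this: about 58% of gene pairs are separable enough (median
mapping accuracy > 90%) to trust haplotype-split counts; the shade
contrasts recover the simulated shade-responsive genes on both
haplotypes and in the inbred parent; the spiked GO terms surface with
fold enrichments around 4–5; clones are cleanly separated from distinct
genotypes by k-mer Jaccard; and a homeolog pair at Ks ≈ 0.016 dates to
~1.2 Ma under the synonymous clock.

The same stages are exposed as a console script (`haplotx run-all`,
`haplotx calibrate`, `haplotx kaks`, `haplotx jaccard`,
`haplotx plastid`) and as plain library calls (see module docstrings in
`src/haplotx/`).

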