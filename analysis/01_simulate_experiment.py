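#!/usr/bin/env python
"""Generate the synthetic study: mesocosm RNA-seq quants, sample sheet,
orthologue map, GO resources, genomes, coverage tracks and ground truth.

The design mirrors the shade mesocosm: 4 timepoints x 2 tissues x 3
replicates for the hybrid and inbred Z. marina (3 Z. marina replicates
lost), plus 7 wild-collected Z. pacifica samples.  Outputs land under
results/simdata/ in the same dialects the real study's tables would use.
"""

import argparse
from pathlib import Path

from haplotx import io, simulate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=2000)
    ap.add_argument("--outdir", type=Path, default=Path("results/simdata"))
    args = ap.parse_args()

    cfg = simulate.SimConfig(
        n_genes=args.n_genes, mean_depth=300, depth_sdlog=0.5, rng_seed=args.seed
    )
    truth = simulate.make_truth(cfg)
    quants, sheet, sample_truth = simulate.simulate_expression_experiment(truth, cfg)

    out = args.outdir
    (out / "quants").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for sid, q in quants.items():
        io.write_quant_table(q, out / "quants" / f"{sid}.quant.sf")
    io.write_sample_sheet(sheet, out / "samples.tsv")
    io.write_orthologue_map(truth.orthologue_map(), out / "orthologues.tsv")
    truth.table.to_csv(out / "truth" / "gene_truth.tsv", sep="\t")
    sample_truth.to_csv(out / "truth" / "sample_truth.tsv", sep="\t")

    terms, edges = simulate.simulate_go_ontology(cfg)
    io.write_obo(terms, edges, out / "ontology.obo")
    gene2go = {g: set(t.split(";")) - {""} for g, t in truth.table["go_terms"].items()}
    io.write_gene2go(gene2go, out / "gene2go.tsv")

    genomes, labels = simulate.simulate_clone_genomes(cfg)
    io.write_fasta(genomes, out / "genomes.fa")
    with open(out / "truth" / "clone_labels.tsv", "w") as fh:
        for gid, lab in labels.items():
            fh.write(f"{gid}\t{lab}\n")
    profiles = simulate.simulate_coverage_tracks(cfg, chromosome_depth=30, plastid_ratio=100)
    io.write_depth_track(profiles, out / "coverage.bed")
    # divergence scale chosen to match the homeolog Ks the expression
    # simulator assumes (~0.015 synonymous substitutions/site)
    cds_a, cds_b = simulate.simulate_codon_pairs(cfg, n_codons=900, n_substitutions=15)
    io.write_fasta(io.SequenceSet(records={"hap1_cds": cds_a, "hap2_cds": cds_b}),
                   out / "codon_pair.fa")

    t = truth.table
    print(f"simulated {len(t)} gene pairs, {len(sheet)} samples -> {out}")
    print(f"  shade-DE genes: {int(t['is_shade_de'].sum())}; "
          f"haplotype-biased: {int(t['is_biased'].sum())}")
    print(f"  divergence mean {t['divergence'].mean():.4f} subs/site; "
          f"true accuracy median {t['true_accuracy'].median():.3f}")
    print(f"  spiked GO target terms: {', '.join(truth.target_terms)}")


if __name__ == "__main__":
    main()
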