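"""End-to-end orchestration: simulate -> calibrate -> DE -> bias -> enrich -> compgen.

A single structured YAML config drives the run; every output TSV is
recorded in a manifest with a content hash so that identical
(config, seed) pairs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import calibration, compgen, diffexpr, enrichment, io, simulate

logger = logging.getLogger(__name__)

DEFAULTS = {
    "tau": 0.90,
    "alpha": 0.05,
    "lfc": 0.5,
    "fdr": 0.05,
    "k": 21,
    "rng_seed": 0,
    "propagate": False,
}

RANGES = {
    "tau": (0.5, 1.0),
    "alpha": (0.0, 1.0),
    "lfc": (0.0, float("inf")),
    "fdr": (0.0, 1.0),
}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    sim: simulate.SimConfig
    tau: float = 0.90
    alpha: float = 0.05
    lfc: float = 0.5
    fdr: float = 0.05
    k: int = 21
    rng_seed: int = 0
    propagate: bool = False


def validate_config(raw: dict, outdir: str | Path | None = None) -> RunConfig:
    """Validate a parsed config dict, reporting every error at once."""
    errors = []
    merged = {**DEFAULTS, **raw}
    for key, (lo, hi) in RANGES.items():
        v = merged[key]
        if not (lo < v <= hi):
            errors.append(f"{key} out of ({lo}, {hi}]: {v}")
    if merged["k"] % 2 == 0 or not 11 <= merged["k"] <= 31:
        errors.append(f"k must be odd and in [11, 31]: {merged['k']}")
    out = Path(outdir or merged.get("outdir", "results/pipeline"))
    sim_block = merged.get("simulate", {})
    try:
        sim = simulate.SimConfig(rng_seed=int(merged["rng_seed"]), **sim_block)
    except (TypeError, ValueError) as exc:
        errors.append(f"simulate block: {exc}")
        sim = simulate.SimConfig()
    for key in ("quant_dir", "sample_sheet", "orthologue_map"):
        if key in merged and not Path(merged[key]).exists():
            errors.append(f"{key}: path {merged[key]!r} does not exist")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    cfg = RunConfig(
        outdir=out,
        sim=sim,
        tau=float(merged["tau"]),
        alpha=float(merged["alpha"]),
        lfc=float(merged["lfc"]),
        fdr=float(merged["fdr"]),
        k=int(merged["k"]),
        rng_seed=int(merged["rng_seed"]),
        propagate=bool(merged["propagate"]),
    )
    logger.info("validated config: %s", cfg)
    return cfg


def load_config(path: str | Path, **overrides) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return validate_config(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage on synthetic data; return the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}, "counts": {}}

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = "ok"
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)

    # --- simulate ----------------------------------------------------------
    truth = simulate.make_truth(cfg.sim)
    quants, sheet, sample_truth = simulate.simulate_expression_experiment(truth, cfg.sim)
    omap = truth.orthologue_map()
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.table.to_csv(truth_dir / "gene_truth.tsv", sep="\t")
    sample_truth.to_csv(truth_dir / "sample_truth.tsv", sep="\t")
    io.write_sample_sheet(sheet, out / "samples.tsv")
    io.write_orthologue_map(omap, out / "orthologues.tsv")
    record("simulate", [truth_dir / "gene_truth.tsv", truth_dir / "sample_truth.tsv",
                        out / "samples.tsv", out / "orthologues.tsv"])

    # --- calibrate ---------------------------------------------------------
    parent_of = {
        sid: acc
        for sid, acc in zip(sheet.table["sample_id"], sheet.table["accession"])
        if acc in ("zmarina", "zpacifica")
    }
    acc_table = calibration.accuracy_table(quants, omap, parent_of)
    retained = calibration.median_accuracy_filter(acc_table, tau=cfg.tau)
    hybrid_quants = {s: quants[s] for s in sheet.samples(accession="hybrid")}
    retained.tpm_fraction = calibration.tpm_representation(retained, hybrid_quants, omap)
    acc_table.median_accuracy().to_csv(out / "accuracy_median.tsv", sep="\t", index=False)
    pd.Series(retained.hap1_ids, name="hap1_id").to_csv(
        out / "retained_pairs.tsv", sep="\t", index=False
    )
    manifest["counts"]["retained_pairs"] = len(retained)
    manifest["counts"]["tpm_fraction"] = round(retained.tpm_fraction, 4)
    logger.info("retained %d pairs (%.1f%% of hybrid TPM)",
                len(retained), 100 * retained.tpm_fraction)
    record("calibrate", [out / "accuracy_median.tsv", out / "retained_pairs.tsv"])

    # --- shade DE and bias per tissue -------------------------------------
    de_files, shade_sets = [], {}
    bias_rows = []
    for tissue in cfg.sim.tissues:
        matrices = diffexpr.build_track_matrices(
            quants, sheet, omap, retained.hap1_ids, tissue
        )
        for track, cm in matrices.items():
            res = diffexpr.run_shade_contrasts(
                cm, track, tissue, alpha=cfg.alpha, lfc_threshold=cfg.lfc
            )
            shade_sets[(track, tissue)] = res
            for name, table in res.contrasts.items():
                f = out / f"de_{track}_{tissue}_{name}.tsv"
                table.to_csv(f, sep="\t")
                de_files.append(f)
            manifest["counts"][f"de_up_{track}_{tissue}"] = len(res.up)
            manifest["counts"][f"de_down_{track}_{tissue}"] = len(res.down)
            logger.info("%s/%s: %d up, %d down in shade", track, tissue,
                        len(res.up), len(res.down))
        split = diffexpr.build_hybrid_split_matrix(
            quants, sheet, omap, retained.hap1_ids, tissue
        )
        for bias in diffexpr.run_bias_contrasts(
            split, tissue, alpha=cfg.alpha, lfc_threshold=cfg.lfc
        ):
            bias_rows.append(
                {
                    "tissue": tissue,
                    "timepoint": bias.timepoint,
                    "hap1_biased": len(bias.hap1_biased),
                    "hap2_biased": len(bias.hap2_biased),
                }
            )
    bias_df = pd.DataFrame(bias_rows)
    bias_df.to_csv(out / "bias_counts.tsv", sep="\t", index=False)
    record("diffexpr", de_files + [out / "bias_counts.tsv"])

    # --- enrichment --------------------------------------------------------
    terms, edges = simulate.simulate_go_ontology(cfg.sim)
    io.write_obo(terms, edges, out / "ontology.obo")
    gene2go = {
        g: set(t.split(";")) - {""}
        for g, t in truth.table["go_terms"].items()
    }
    io.write_gene2go(gene2go, out / "gene2go.tsv")
    go = io.read_go_resources(out / "ontology.obo", out / "gene2go.tsv")
    enrich_files = [out / "ontology.obo", out / "gene2go.tsv"]
    population = set(retained.hap1_ids)
    for (track, tissue), res in shade_sets.items():
        for direction, genes in (("up", res.up), ("down", res.down)):
            result = enrichment.go_enrichment(
                genes & population, population, go,
                propagate=cfg.propagate, fdr=cfg.fdr, direction=direction,
            )
            f = out / f"enrichment_{track}_{tissue}_{direction}.tsv"
            result.to_csv(f, sep="\t", index=False)
            enrich_files.append(f)
    record("enrichment", enrich_files)

    # --- comparative genomics ----------------------------------------------
    genomes, labels = simulate.simulate_clone_genomes(cfg.sim, genome_length=20_000)
    indices = [
        compgen.build_kmer_set(io.SequenceSet(records={gid: seq}), cfg.k, genome_id=gid)
        for gid, seq in genomes.items()
    ]
    dist, newick = compgen.pairwise_cluster(indices)
    dist.to_csv(out / "jaccard_distance.tsv", sep="\t")
    (out / "pangenome.nwk").write_text(newick + "\n")
    profiles = simulate.simulate_coverage_tracks(cfg.sim)
    io.write_depth_track(profiles, out / "coverage.bed")
    ratio = compgen.plastid_nuclear_ratio(profiles)
    ratio.to_csv(out / "plastid_ratio.tsv", sep="\t", index=False)
    cds_a, cds_b = simulate.simulate_codon_pairs(cfg.sim)
    est = compgen.ng86_kaks(cds_a, cds_b)
    kaks = pd.DataFrame(
        [{
            "Ka": est.Ka, "Ks": est.Ks, "ratio": est.ratio,
            "divergence_time_yr": compgen.divergence_time(est.Ks or 0.0),
        }]
    )
    kaks.to_csv(out / "kaks.tsv", sep="\t", index=False)
    manifest["counts"]["clone_labels"] = labels
    record("compgen", [out / "jaccard_distance.tsv", out / "pangenome.nwk",
                       out / "coverage.bed", out / "plastid_ratio.tsv", out / "kaks.tsv"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
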