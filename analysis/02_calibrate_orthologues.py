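#!/usr/bin/env python
"""Cross-mapping calibration: per-gene mapping accuracy from parental
samples, median aggregation, the tau=0.90 filter, and the fraction of
hybrid transcription (TPM) the retained orthologue pairs represent."""

import argparse
from pathlib import Path

from haplotx import calibration, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdata", type=Path, default=Path("results/simdata"))
    ap.add_argument("--outdir", type=Path, default=Path("results/calibration"))
    ap.add_argument("--tau", type=float, default=0.90)
    args = ap.parse_args()

    sheet = io.read_sample_sheet(args.simdata / "samples.tsv")
    omap = io.read_orthologue_map(args.simdata / "orthologues.tsv")
    quants = {
        sid: io.read_quant_table(args.simdata / "quants" / f"{sid}.quant.sf", sid)
        for sid in sheet.table["sample_id"]
    }
    parent_of = {
        r.sample_id: r.accession
        for r in sheet.table.itertuples()
        if r.accession in ("zmarina", "zpacifica")
    }
    table = calibration.accuracy_table(quants, omap, parent_of)
    retained = calibration.median_accuracy_filter(table, tau=args.tau)
    hybrid = {s: quants[s] for s in sheet.samples(accession="hybrid")}
    retained.tpm_fraction = calibration.tpm_representation(retained, hybrid, omap)

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    table.rows.to_csv(out / "accuracy_per_sample.tsv", sep="\t", index=False)
    table.median_accuracy().to_csv(out / "accuracy_median.tsv", sep="\t", index=False)
    table.median_accuracy(per_parent=True).to_csv(
        out / "accuracy_median_per_parent.tsv", sep="\t", index=False
    )
    with open(out / "retained_pairs.tsv", "w") as fh:
        fh.write("hap1_id\n")
        for gid in retained.hap1_ids:
            fh.write(gid + "\n")

    print(f"parental samples used: {len(parent_of)} "
          f"({sum(v == 'zmarina' for v in parent_of.values())} Z. marina, "
          f"{sum(v == 'zpacifica' for v in parent_of.values())} Z. pacifica)")
    print(f"retained {len(retained)} / {len(omap)} orthologue pairs at "
          f"median accuracy > {args.tau:.2f}")
    print(f"retained pairs represent {100 * retained.tpm_fraction:.1f}% of hybrid "
          f"transcription (TPM) across all samples")


if __name__ == "__main__":
    main()
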