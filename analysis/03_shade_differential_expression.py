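#!/usr/bin/env python
"""Shade-response differential expression per expression track and tissue.

Low-light timepoints (t2+t3) are pooled and contrasted against full light
t1 (control) and t4 (recovery); a gene responds to shade if significant
(BH-adjusted P <= 0.05, |log2FC| >= 0.5) in either contrast.  The hybrid
is analysed as two haplotype tracks; inbred Z. marina as one (haplotype
mappings summed)."""

import argparse
from pathlib import Path

import pandas as pd

from haplotx import diffexpr, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdata", type=Path, default=Path("results/simdata"))
    ap.add_argument("--retained", type=Path,
                    default=Path("results/calibration/retained_pairs.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results/diffexpr"))
    args = ap.parse_args()

    sheet = io.read_sample_sheet(args.simdata / "samples.tsv")
    omap = io.read_orthologue_map(args.simdata / "orthologues.tsv")
    retained = pd.read_csv(args.retained, sep="\t")["hap1_id"].tolist()
    quants = {
        sid: io.read_quant_table(args.simdata / "quants" / f"{sid}.quant.sf", sid)
        for sid in sheet.table["sample_id"]
    }

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    summary = []
    for tissue in ("leaf", "rhizome"):
        matrices = diffexpr.build_track_matrices(quants, sheet, omap, retained, tissue)
        for track, cm in matrices.items():
            res = diffexpr.run_shade_contrasts(cm, track, tissue)
            for name, table in res.contrasts.items():
                table.to_csv(out / f"de_{track}_{tissue}_{name}.tsv", sep="\t")
            summary.append(
                {"track": track, "tissue": tissue,
                 "up_in_shade": len(res.up), "down_in_shade": len(res.down)}
            )
            print(f"{tissue:8s} {track:12s}: {len(res.up):4d} up, "
                  f"{len(res.down):4d} down in shade")
    pd.DataFrame(summary).to_csv(out / "shade_de_counts.tsv", sep="\t", index=False)
    print(f"per-contrast tables written to {out}")


if __name__ == "__main__":
    main()
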