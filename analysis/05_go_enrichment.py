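#!/usr/bin/env python
"""GO over-representation of the shade up/down gene sets per track and
tissue, against the retained-orthologue population, FDR < 0.05."""

import argparse
from pathlib import Path

import pandas as pd

from haplotx import diffexpr, enrichment, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdata", type=Path, default=Path("results/simdata"))
    ap.add_argument("--retained", type=Path,
                    default=Path("results/calibration/retained_pairs.tsv"))
    ap.add_argument("--de-dir", type=Path, default=Path("results/diffexpr"))
    ap.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--propagate", action="store_true")
    args = ap.parse_args()

    go = io.read_go_resources(args.simdata / "ontology.obo", args.simdata / "gene2go.tsv")
    retained = set(pd.read_csv(args.retained, sep="\t")["hap1_id"])
    counts = pd.read_csv(args.de_dir / "shade_de_counts.tsv", sep="\t")

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    for row in counts.itertuples(index=False):
        up, down = set(), set()
        for ref in ("t1", "t4"):
            path = args.de_dir / f"de_{row.track}_{row.tissue}_shade_vs_{ref}.tsv"
            if not path.exists():
                continue
            table = pd.read_csv(path, sep="\t", index_col=0)
            sig = table[table["significant"]]
            up |= set(sig.index[sig["log2fc"] > 0])
            down |= set(sig.index[sig["log2fc"] < 0])
        for direction, genes in (("up", up), ("down", down)):
            res = enrichment.go_enrichment(
                genes & retained, retained, go,
                propagate=args.propagate, direction=direction,
            )
            res.to_csv(out / f"enrichment_{row.track}_{row.tissue}_{direction}.tsv",
                       sep="\t", index=False)
            sig = res[res["significant"]]
            if len(sig):
                top = sig.iloc[0]
                print(f"{row.tissue:8s} {row.track:12s} {direction:4s}: "
                      f"{len(sig)} enriched terms; top {top.term_id} "
                      f"fold={top.fold:.1f} padj={top.padj:.2e}")
            else:
                print(f"{row.tissue:8s} {row.track:12s} {direction:4s}: no enriched terms")


if __name__ == "__main__":
    main()
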