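"""Cross-mapping calibration of 1:1 homeolog pairs from parental samples.

Inbred parental RNA-seq mapped against the concatenated hybrid
transcriptome reveals, per orthologue pair, what fraction of a parent's
reads land on the expected haplotype transcript (Hap1 for Z. marina,
Hap2 for Z. pacifica).  The per-gene median of this mapping accuracy
across the parental sample set, thresholded at tau (default 0.90,
strict), selects the orthologue pairs whose haplotype-split counts can
be trusted for differential expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OrthologueMap, QuantTable

logger = logging.getLogger(__name__)

PARENT_EXPECTED_HAP = {"zmarina": 1, "zpacifica": 2}


@dataclass
class AccuracyTable:
    """Per (gene pair, parental sample) mapping accuracy rows.

    ``rows`` columns: hap1_id, sample_id, parent, expected_reads,
    unexpected_reads, accuracy (NaN when no reads).
    """

    rows: pd.DataFrame

    def median_accuracy(self, per_parent: bool = False) -> pd.DataFrame:
        """Median accuracy per gene over samples with defined accuracy.

        Genes with zero informative samples are dropped.  With
        ``per_parent`` the median is computed within each parent's sample
        set instead of pooling both parents.
        """
        defined = self.rows.dropna(subset=["accuracy"])
        keys = ["hap1_id", "parent"] if per_parent else ["hap1_id"]
        grouped = defined.groupby(keys)["accuracy"]
        out = grouped.median().to_frame("median_accuracy")
        out["n_informative_samples"] = grouped.size()
        return out.reset_index()


@dataclass
class RetainedSet:
    """Gene pairs passing the median-accuracy filter."""

    hap1_ids: list[str]
    tau: float
    tpm_fraction: float | None = None

    def __len__(self) -> int:
        return len(self.hap1_ids)


def per_sample_accuracy(
    quant: QuantTable, omap: OrthologueMap, parent: str
) -> pd.DataFrame:
    """Accuracy rows for one parental sample.

    accuracy = expected / (expected + unexpected) read counts, where the
    expected transcript is Hap1 for ``zmarina`` and Hap2 for
    ``zpacifica``; undefined (NaN) when the pair drew no reads.
    """
    if parent not in PARENT_EXPECTED_HAP:
        raise ValueError(f"parent must be one of {sorted(PARENT_EXPECTED_HAP)}")
    expected_hap = PARENT_EXPECTED_HAP[parent]
    universe = set(quant.table.index)
    missing = [
        h1
        for h1, h2 in omap.pairs
        if h1 not in universe and h2 not in universe
    ]
    if missing:
        logger.warning(
            "%s: %d orthologue pairs absent from quant table",
            quant.sample_id,
            len(missing),
        )
    counts = quant.table["num_reads"]
    records = []
    for h1, h2 in omap.pairs:
        c1 = float(counts.get(h1, 0.0))
        c2 = float(counts.get(h2, 0.0))
        expected, unexpected = (c1, c2) if expected_hap == 1 else (c2, c1)
        total = expected + unexpected
        acc = expected / total if total > 0 else np.nan
        records.append(
            {
                "hap1_id": h1,
                "sample_id": quant.sample_id,
                "parent": parent,
                "expected_reads": expected,
                "unexpected_reads": unexpected,
                "accuracy": acc,
            }
        )
    return pd.DataFrame(records)


def accuracy_table(
    quants: dict[str, QuantTable],
    omap: OrthologueMap,
    parent_of: dict[str, str],
) -> AccuracyTable:
    """Stack per-sample accuracy rows for all parental samples.

    ``parent_of`` maps sample_id -> 'zmarina' | 'zpacifica'.
    """
    frames = [
        per_sample_accuracy(quants[sid], omap, parent)
        for sid, parent in parent_of.items()
    ]
    if not frames:
        raise ValueError("no parental samples supplied")
    return AccuracyTable(rows=pd.concat(frames, ignore_index=True))


def median_accuracy_filter(table: AccuracyTable, tau: float = 0.90) -> RetainedSet:
    """Retain pairs whose pooled median accuracy is strictly above tau."""
    if not 0.5 < tau <= 1.0:
        raise ValueError(f"tau must be in (0.5, 1], got {tau}")
    if table.rows.empty:
        raise ValueError("empty accuracy table")
    med = table.median_accuracy(per_parent=False)
    keep = med.loc[med["median_accuracy"] > tau, "hap1_id"]
    return RetainedSet(hap1_ids=sorted(keep), tau=tau)


def tpm_representation(
    retained: RetainedSet,
    hybrid_quants: dict[str, QuantTable],
    omap: OrthologueMap,
) -> float:
    """Fraction of hybrid TPM carried by retained pairs (both haplotypes)."""
    if not hybrid_quants:
        raise ValueError("no hybrid samples supplied")
    pair_of = dict(omap.pairs)
    kept_ids = set(retained.hap1_ids) | {pair_of[h1] for h1 in retained.hap1_ids}
    total = 0.0
    kept = 0.0
    for quant in hybrid_quants.values():
        tpm = quant.table["tpm"]
        total += float(tpm.sum())
        kept += float(tpm[tpm.index.isin(kept_ids)].sum())
    if total == 0:
        raise ValueError("hybrid samples carry no TPM")
    return kept / total
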