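"""Readers, writers and validation for the pipeline's external formats.

All tabular formats are UTF-8, tab-separated, with ``#``-prefixed comment
lines skipped.  Coordinates are uniformly 0-based half-open.  Each reader
has a matching writer and the pair round-trips exactly on valid data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ACCESSIONS = ("hybrid", "zmarina", "zpacifica")
TISSUES = ("leaf", "rhizome")
TIMEPOINTS = ("t1", "t2", "t3", "t4")

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]

IUPAC = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """A file parses but violates a semantic invariant."""


# ---------------------------------------------------------------------------
# QuantTable


@dataclass
class QuantTable:
    """Per-sample transcript quantification (quant.sf dialect).

    ``table`` is indexed by transcript id with columns ``length``,
    ``effective_length``, ``tpm`` and ``num_reads``.
    """

    sample_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate transcript id {dup!r}")
        for col in ("tpm", "num_reads"):
            bad = np.flatnonzero(self.table[col].to_numpy() < 0)
            if bad.size:
                raise ValidationError(
                    f"negative {col} at row {bad[0] + 1} "
                    f"({self.table.index[bad[0]]!r})"
                )

    def __len__(self) -> int:
        return len(self.table)

    def num_reads(self, transcript_id: str) -> float:
        """Read count for a transcript; absent transcripts count 0."""
        try:
            return float(self.table.at[transcript_id, "num_reads"])
        except KeyError:
            return 0.0

    def tpm(self, transcript_id: str) -> float:
        try:
            return float(self.table.at[transcript_id, "tpm"])
        except KeyError:
            return 0.0


def read_quant_table(path: str | Path, sample_id: str) -> QuantTable:
    """Read a quant.sf-style TSV (Name/Length/EffectiveLength/TPM/NumReads)."""
    df = _read_tsv(path)
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column {missing[0]!r}")
    extra = [c for c in df.columns if c not in QUANT_COLUMNS]
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, extra)
    if df.empty:
        logger.warning("%s: header-only quant table (no transcripts)", path)
    out = pd.DataFrame(
        {
            "length": pd.to_numeric(df["Length"]).astype(int).to_numpy(),
            "effective_length": pd.to_numeric(df["EffectiveLength"]).astype(float).to_numpy(),
            "tpm": pd.to_numeric(df["TPM"]).astype(float).to_numpy(),
            "num_reads": pd.to_numeric(df["NumReads"]).astype(float).to_numpy(),
        },
        index=pd.Index(df["Name"].astype(str).to_numpy(), name="Name"),
    )
    return QuantTable(sample_id=sample_id, table=out)


def write_quant_table(quant: QuantTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "Name": quant.table.index,
            "Length": quant.table["length"].to_numpy(),
            "EffectiveLength": quant.table["effective_length"].to_numpy(),
            "TPM": quant.table["tpm"].to_numpy(),
            "NumReads": quant.table["num_reads"].to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SampleSheet


@dataclass
class SampleSheet:
    """Experimental design: one row per RNA-seq sample.

    Columns: sample_id, accession, tissue, timepoint (may be NA for
    wild-collected samples), replicate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not t["sample_id"].is_unique:
            dup = t["sample_id"][t["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        combo = t[["accession", "tissue", "timepoint", "replicate"]].astype(str)
        if combo.duplicated().any():
            raise ValidationError("duplicate (accession,tissue,timepoint,replicate)")

    def __len__(self) -> int:
        return len(self.table)

    def samples(
        self,
        accession: str | None = None,
        tissue: str | None = None,
        timepoint: str | None = None,
    ) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if accession is not None:
            mask &= t["accession"] == accession
        if tissue is not None:
            mask &= t["tissue"] == tissue
        if timepoint is not None:
            mask &= t["timepoint"] == timepoint
        return list(t.loc[mask, "sample_id"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path)
    required = ["sample_id", "accession", "tissue", "timepoint", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column {missing[0]!r}")
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    df = df[required].astype(object).copy()
    df["sample_id"] = df["sample_id"].astype(str)
    for col, allowed in (("accession", ACCESSIONS), ("tissue", TISSUES)):
        bad = set(df[col]) - set(allowed)
        if bad:
            raise ValidationError(f"{path}: unknown {col} {sorted(bad)[0]!r}")
    df["timepoint"] = df["timepoint"].where(
        ~df["timepoint"].isin(["", "none", "NA", None]) & df["timepoint"].notna(),
        None,
    )
    bad_tp = {t for t in df["timepoint"] if t is not None} - set(TIMEPOINTS)
    if bad_tp:
        raise ValidationError(f"{path}: unknown timepoint {sorted(bad_tp)[0]!r}")
    return SampleSheet(table=df.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = sheet.table.copy()
    df["timepoint"] = [t if t is not None else "none" for t in df["timepoint"]]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# OrthologueMap


@dataclass
class OrthologueMap:
    """Strict 1:1 pairing of Hap1 and Hap2 gene identifiers."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for h1, h2 in self.pairs:
            for g in (h1, h2):
                if g in seen:
                    raise ValidationError(f"gene id {g!r} appears in more than one pair")
                seen.add(g)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def hap1_ids(self) -> list[str]:
        return [h1 for h1, _ in self.pairs]

    @property
    def hap2_ids(self) -> list[str]:
        return [h2 for _, h2 in self.pairs]

    def hap2_of(self, hap1_id: str) -> str:
        return dict(self.pairs)[hap1_id]


def read_orthologue_map(path: str | Path) -> OrthologueMap:
    df = _read_tsv(path, header=None)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 columns")
    pairs = [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    return OrthologueMap(pairs=pairs)


def write_orthologue_map(omap: OrthologueMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h1, h2 in omap.pairs:
            fh.write(f"{h1}\t{h2}\n")


# ---------------------------------------------------------------------------
# GOResources


@dataclass
class GOResources:
    """gene -> GO associations plus the term DAG (is_a/part_of edges).

    ``dag`` edges point child -> parent, so ancestors of a term are its
    descendants in networkx terms are reached by following edges forward.
    """

    gene2go: dict[str, set[str]]
    dag: nx.DiGraph
    n_unknown_terms: int = 0

    def term_name(self, term_id: str) -> str:
        return self.dag.nodes[term_id].get("name", term_id)

    def ancestors(self, term_id: str) -> set[str]:
        """All is_a/part_of ancestors of a term (excluding itself)."""
        if term_id not in self.dag:
            return set()
        return set(nx.descendants(self.dag, term_id))


def read_go_resources(obo_path: str | Path, gene2go_path: str | Path) -> GOResources:
    """Read an OBO subset and a 2-column gene->term association TSV.

    Only ``is_a`` and ``part_of`` relationships enter the DAG; obsolete
    terms are dropped with a warning.  Associations to terms missing from
    the DAG are kept but counted and warned about.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = obonet.read_obo(obo_path, ignore_obsolete=False)
    dag = nx.DiGraph()
    n_obsolete = 0
    for node, data in raw.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            n_obsolete += 1
            continue
        dag.add_node(node, name=data.get("name", node))
    for child, parent, key in raw.edges(keys=True):
        if key not in ("is_a", "part_of"):
            continue
        if child in dag and parent in dag:
            dag.add_edge(child, parent, relation=key)
    if n_obsolete:
        logger.warning("%s: dropped %d obsolete terms", obo_path, n_obsolete)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValidationError(f"{obo_path}: cycle detected in term graph")

    assoc = _read_tsv(gene2go_path, header=None)
    gene2go: dict[str, set[str]] = {}
    n_unknown = 0
    for gene, term in zip(assoc.iloc[:, 0], assoc.iloc[:, 1]):
        gene, term = str(gene), str(term)
        if term not in dag:
            n_unknown += 1
        gene2go.setdefault(gene, set()).add(term)
    if n_unknown:
        logger.warning(
            "%s: %d associations reference terms absent from the DAG",
            gene2go_path,
            n_unknown,
        )
    return GOResources(gene2go=gene2go, dag=dag, n_unknown_terms=n_unknown)


def write_gene2go(gene2go: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene2go):
            for term in sorted(gene2go[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_obo(
    terms: Mapping[str, str],
    is_a_edges: Iterable[tuple[str, str]],
    path: str | Path,
) -> None:
    """Write a minimal OBO file: ``terms`` maps id -> name."""
    edges: dict[str, list[str]] = {}
    for child, parent in is_a_edges:
        edges.setdefault(child, []).append(parent)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n\n")
        for tid in sorted(terms):
            fh.write("[Term]\n")
            fh.write(f"id: {tid}\n")
            fh.write(f"name: {terms[tid]}\n")
            for parent in sorted(edges.get(tid, [])):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# CoverageProfile


@dataclass
class CoverageProfile:
    """Run-length encoded per-base read depth for one sequence."""

    sequence_id: str
    intervals: list[tuple[int, int, float]]  # (start, end, depth), 0-based half-open
    is_plastid: bool = False

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end, depth in self.intervals:
            if end <= start:
                raise ValidationError(
                    f"{self.sequence_id}: empty interval [{start},{end})"
                )
            if start < prev_end:
                raise ValidationError(
                    f"{self.sequence_id}: interval [{start},{end}) overlaps previous"
                )
            if depth < 0:
                raise ValidationError(f"{self.sequence_id}: negative depth at {start}")
            prev_end = end

    @property
    def length(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0

    def depth_array(self) -> np.ndarray:
        """Expand to a per-base depth vector (gaps filled with 0)."""
        arr = np.zeros(self.length)
        for start, end, depth in self.intervals:
            arr[start:end] = depth
        return arr

    def mean_depth(self) -> float:
        return float(self.depth_array().mean())

    def median_depth(self) -> float:
        return float(np.median(self.depth_array()))


def read_depth_track(
    path: str | Path, plastid_ids: set[str] | None = None
) -> dict[str, CoverageProfile]:
    """Read a BED-like (sequence, start, end, depth) TSV into profiles."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected 4 columns (seq, start, end, depth)")
    plastid_ids = plastid_ids or set()
    profiles: dict[str, CoverageProfile] = {}
    for seq_id, group in df.groupby(df.columns[0], sort=False):
        ivals = sorted(
            (int(s), int(e), float(d))
            for s, e, d in zip(group.iloc[:, 1], group.iloc[:, 2], group.iloc[:, 3])
        )
        profiles[str(seq_id)] = CoverageProfile(
            sequence_id=str(seq_id),
            intervals=ivals,
            is_plastid=str(seq_id) in plastid_ids,
        )
    return profiles


def write_depth_track(profiles: Iterable[CoverageProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        for prof in profiles:
            for start, end, depth in prof.intervals:
                d = int(depth) if float(depth).is_integer() else depth
                fh.write(f"{prof.sequence_id}\t{start}\t{end}\t{d}\n")


# ---------------------------------------------------------------------------
# SequenceSet


@dataclass
class SequenceSet:
    """Named nucleotide sequences (IUPAC alphabet, stored uppercase)."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise ValidationError(f"empty sequence for {name!r}")
            bad = set(seq) - IUPAC
            if bad:
                raise ValidationError(
                    f"{name!r}: non-IUPAC character {sorted(bad)[0]!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def items(self):
        return self.records.items()


def read_fasta(path: str | Path) -> SequenceSet:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"{path}: duplicate id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {rec.id!r}")
        records[rec.id] = seq
    return SequenceSet(records=records)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# helpers


def _read_tsv(path: str | Path, header: int | None | str = "infer") -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", comment="#", header=header, dtype=object, encoding="utf-8"
        ).apply(lambda col: col)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
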