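"""Synthetic-data generators for the hybrid eelgrass analysis.

The generators emulate the statistical structure the downstream analysis
assumes: two diverged haplotype transcriptomes with divergence-dependent
read misassignment between homeologs, negative-binomial counts under a
4-timepoint x 2-tissue x 3-replicate shade mesocosm design (with optional
replicate loss), inbred parental samples, clone/non-clone genome sets,
chromosome vs plastid coverage tracks, and codon-level sequence pairs
evolving under a chosen Ka/Ks regime.  Every generator is a pure function
of (config, seed) and emits ground truth for parameter-recovery tests.

Misassignment model
-------------------
A read from a homeolog with per-site divergence ``d`` overlaps at least
one diagnostic variant with probability ``1 - exp(-d * R)`` for read
length ``R``; reads with no diagnostic variant are assigned 50/50.  The
per-gene probability that a read lands on its true transcript is hence

    a_g = 1 - 0.5 * exp(-d_g * R),

ranging from 0.5 (identical homeologs) to 1 (fully diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    CoverageProfile,
    OrthologueMap,
    QuantTable,
    SampleSheet,
    SequenceSet,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"

CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        CODON_TABLE[stop] = "*"


_build_codon_table()


@dataclass
class SimConfig:
    """Configuration for all generators.

    Defaults mirror the mesocosm study design: 4 timepoints x 2 tissues x
    3 replicates for the hybrid and the inbred Z. marina (with the three
    lost Z. marina replicates dropped), plus wild-collected Z. pacifica
    samples with no timepoint.
    """

    n_genes: int = 2000
    read_length: int = 150
    # per-gene divergence ~ Gamma(shape, mean)
    divergence_shape: float = 2.0
    divergence_mean: float = 0.015
    # shade response
    pi_de: float = 0.15
    shade_lfc: float = 1.5
    # haplotype bias
    pi_bias: float = 0.10
    bias_lfc: float = 1.5
    # NB dispersion ~ LogNormal(meanlog, sdlog)
    dispersion_meanlog: float = -3.0
    dispersion_sdlog: float = 0.5
    # baseline expression ~ LogNormal around mean_depth
    mean_depth: float = 200.0
    depth_sdlog: float = 1.0
    # library-size factor range (uniform on log scale)
    libsize_spread: float = 1.5
    # design
    timepoints: tuple[str, ...] = ("t1", "t2", "t3", "t4")
    tissues: tuple[str, ...] = ("leaf", "rhizome")
    n_replicates: int = 3
    drop_lost_replicates: bool = True
    n_pacifica_wild: int = 7
    # GO simulation
    n_go_terms: int = 60
    n_target_terms: int = 3
    target_assoc_prob: float = 0.6
    background_assoc_prob: float = 0.04
    mean_terms_per_gene: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_de", "pi_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.pi_de + self.pi_bias > 1.0:
            raise ValueError("pi_de + pi_bias must not exceed 1")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass
class TruthSet:
    """Ground truth per gene pair, for parameter-recovery tests."""

    table: pd.DataFrame  # indexed by hap1 gene id
    target_terms: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def orthologue_map(self) -> OrthologueMap:
        return OrthologueMap(
            pairs=[(g, g.replace("h1.", "h2.", 1)) for g in self.table.index]
        )


def accuracy_from_divergence(divergence: np.ndarray, read_length: int) -> np.ndarray:
    """Expected mapping accuracy ``1 - 0.5 exp(-d R)`` per gene."""
    return 1.0 - 0.5 * np.exp(-np.asarray(divergence, dtype=float) * read_length)


def make_truth(config: SimConfig) -> TruthSet:
    """Draw the per-gene generative parameters and GO annotations."""
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_genes
    gene_ids = [f"h1.g{i:05d}" for i in range(n)]

    divergence = rng.gamma(
        config.divergence_shape, config.divergence_mean / config.divergence_shape, n
    )
    accuracy = accuracy_from_divergence(divergence, config.read_length)
    cds_length = 3 * rng.integers(150, 800, n)
    baseline = rng.lognormal(
        np.log(config.mean_depth) - 0.5 * config.depth_sdlog**2,
        config.depth_sdlog,
        n,
    )
    dispersion = rng.lognormal(config.dispersion_meanlog, config.dispersion_sdlog, n)

    # non-overlapping DE / bias labels keep truth evaluation unambiguous
    perm = rng.permutation(n)
    n_de = int(round(config.pi_de * n))
    n_bias = int(round(config.pi_bias * n))
    de_idx = perm[:n_de]
    bias_idx = perm[n_de : n_de + n_bias]
    shade_lfc = np.zeros(n)
    shade_lfc[de_idx] = rng.choice([-1.0, 1.0], n_de) * config.shade_lfc
    bias_lfc = np.zeros(n)
    bias_lfc[bias_idx] = rng.choice([-1.0, 1.0], n_bias) * config.bias_lfc

    terms = [f"GO:{7000000 + i:07d}" for i in range(config.n_go_terms)]
    target_terms = terms[: config.n_target_terms]
    go_assign: list[set[str]] = []
    p_bg = min(1.0, config.mean_terms_per_gene / max(1, config.n_go_terms))
    for i in range(n):
        got = {t for t in terms[config.n_target_terms :] if rng.random() < p_bg}
        p_target = (
            config.target_assoc_prob if shade_lfc[i] != 0 else config.background_assoc_prob
        )
        for t in target_terms:
            if rng.random() < p_target:
                got.add(t)
        go_assign.append(got)

    table = pd.DataFrame(
        {
            "divergence": divergence,
            "cds_length": cds_length,
            "baseline_mean": baseline,
            "dispersion": dispersion,
            "shade_lfc": shade_lfc,
            "bias_lfc": bias_lfc,
            "true_accuracy": accuracy,
            "is_shade_de": shade_lfc != 0,
            "is_biased": bias_lfc != 0,
            "go_terms": [";".join(sorted(s)) for s in go_assign],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return TruthSet(table=table, target_terms=target_terms)


def simulate_go_ontology(
    config: SimConfig,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """A random is_a DAG over the simulated term set (plus one root)."""
    rng = np.random.default_rng(config.rng_seed + 11)
    terms = {f"GO:{7000000 + i:07d}": f"synthetic process {i}" for i in range(config.n_go_terms)}
    root = "GO:0008150"
    terms[root] = "biological_process"
    ids = sorted(set(terms) - {root})
    edges = []
    for i, tid in enumerate(ids):
        if i == 0:
            edges.append((tid, root))
            continue
        parent = ids[rng.integers(0, i)] if rng.random() < 0.7 else root
        edges.append((tid, parent))
    return terms, edges


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB with variance mu + alpha mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def _design_rows(config: SimConfig) -> list[dict]:
    rows = []
    lost = {("zmarina", "leaf", "t3", "c"), ("zmarina", "rhizome", "t4", "b"),
            ("zmarina", "leaf", "t4", "c")}
    reps = "abcdefgh"[: config.n_replicates]
    for accession in ("hybrid", "zmarina"):
        for tissue in config.tissues:
            for tp in config.timepoints:
                for rep in reps:
                    if (
                        config.drop_lost_replicates
                        and (accession, tissue, tp, rep) in lost
                    ):
                        continue
                    rows.append(
                        {
                            "sample_id": f"{accession}_{tissue}_{tp}_{rep}",
                            "accession": accession,
                            "tissue": tissue,
                            "timepoint": tp,
                            "replicate": rep,
                        }
                    )
    for i in range(config.n_pacifica_wild):
        rows.append(
            {
                "sample_id": f"zpacifica_wild_{i + 1}",
                "accession": "zpacifica",
                "tissue": "leaf",
                "timepoint": None,
                "replicate": f"w{i + 1}",
            }
        )
    return rows


def design_sheet(config: SimConfig) -> SampleSheet:
    return SampleSheet(table=pd.DataFrame(_design_rows(config)))


def simulate_expression_experiment(
    truth: TruthSet, config: SimConfig
) -> tuple[dict[str, QuantTable], SampleSheet, pd.DataFrame]:
    """Simulate quant tables for every sample in the design.

    Hybrid samples carry both haplotypes with shade and bias effects and
    divergence-dependent misassignment; parental inbreds express a single
    haplotype, misassigned by the same per-gene accuracy.  Returns the
    quant tables keyed by sample id, the sample sheet, and the per-sample
    truth (library-size factors, shade indicator).
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    sheet = design_sheet(config)
    t = truth.table
    n = len(t)
    lam = t["baseline_mean"].to_numpy()
    alpha = t["dispersion"].to_numpy()
    beta = t["shade_lfc"].to_numpy()
    gamma = t["bias_lfc"].to_numpy()
    acc = t["true_accuracy"].to_numpy()
    length = t["cds_length"].to_numpy()
    eff_length = np.maximum(1.0, length - config.read_length + 1)

    shade_tps = {"t2", "t3"}
    omap = truth.orthologue_map()
    hap1_ids, hap2_ids = omap.hap1_ids, omap.hap2_ids

    quants: dict[str, QuantTable] = {}
    sample_truth_rows = []
    for row in sheet.table.itertuples(index=False):
        size = float(
            np.exp(rng.uniform(-np.log(config.libsize_spread), np.log(config.libsize_spread)))
        )
        shaded = row.timepoint in shade_tps
        if row.accession == "hybrid":
            mu1 = size * lam * np.power(2.0, beta * shaded)
            mu2 = size * lam * np.power(2.0, beta * shaded + gamma)
            k1 = _nb_draw(rng, mu1, alpha)
            k2 = _nb_draw(rng, mu2, alpha)
            stay1 = rng.binomial(k1, acc)
            stay2 = rng.binomial(k2, acc)
            obs1 = stay1 + (k2 - stay2)
            obs2 = stay2 + (k1 - stay1)
        else:
            mu = size * lam * np.power(2.0, beta * shaded)
            k = _nb_draw(rng, mu, alpha)
            if row.accession == "zmarina":
                obs1 = rng.binomial(k, acc)
                obs2 = k - obs1
            else:  # zpacifica: expected transcript is hap2
                obs2 = rng.binomial(k, acc)
                obs1 = k - obs2
        counts = np.concatenate([obs1, obs2]).astype(float)
        eff = np.concatenate([eff_length, eff_length])
        lengths = np.concatenate([length, length]).astype(int)
        rate = counts / eff
        tpm = rate / rate.sum() * 1e6 if rate.sum() > 0 else rate
        table = pd.DataFrame(
            {
                "length": lengths,
                "effective_length": eff,
                "tpm": tpm,
                "num_reads": counts,
            },
            index=pd.Index(hap1_ids + hap2_ids, name="Name"),
        )
        quants[row.sample_id] = QuantTable(sample_id=row.sample_id, table=table)
        sample_truth_rows.append(
            {"sample_id": row.sample_id, "size_factor": size, "shaded": shaded}
        )
    sample_truth = pd.DataFrame(sample_truth_rows).set_index("sample_id")
    return quants, sheet, sample_truth


# ---------------------------------------------------------------------------
# genomes, coverage, codons


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, length, dtype=np.int8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, hits.size, dtype=np.int8)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(BASES[b] for b in seq)


def simulate_clone_genomes(
    config: SimConfig,
    n_clones: int = 3,
    n_distinct: int = 2,
    genome_length: int = 100_000,
    error_rate: float = 1e-4,
    genotype_divergence: float = 5e-3,
    kmer_size: int = 21,
) -> tuple[SequenceSet, dict[str, str]]:
    """Clonal copies of one genotype plus distinct genotypes.

    Clones are iid-error copies of genotype ``G1``; distinct genotypes are
    independently mutated from a common ancestor at ``genotype_divergence``.
    Returns the sequences and a genome-id -> genotype-label map.
    """
    if genome_length < kmer_size:
        raise ValueError("genome length shorter than the k-mer size")
    rng = np.random.default_rng(config.rng_seed + 2)
    if genotype_divergence == 0 and n_distinct > 1:
        import logging

        logging.getLogger(__name__).warning(
            "genotype divergence 0: distinct genotypes are indistinguishable"
        )
    ancestor = _random_seq(rng, genome_length)
    genotypes = [
        _mutate(rng, ancestor, genotype_divergence) for _ in range(max(1, n_distinct))
    ]
    records: dict[str, str] = {}
    labels: dict[str, str] = {}
    for i in range(n_clones):
        name = f"clone_{i + 1}"
        records[name] = _to_str(_mutate(rng, genotypes[0], error_rate))
        labels[name] = "G1"
    for j in range(1, n_distinct):
        name = f"genotype_{j + 1}"
        records[name] = _to_str(_mutate(rng, genotypes[j], error_rate))
        labels[name] = f"G{j + 1}"
    return SequenceSet(records=records), labels


def simulate_coverage_tracks(
    config: SimConfig,
    chromosome_depth: float = 30.0,
    plastid_ratio: float = 100.0,
    n_chromosomes: int = 3,
    chromosome_length: int = 10_000,
    plastid_length: int = 10_000,
) -> list[CoverageProfile]:
    """Poisson per-base depth: chromosomes at ``lambda``, plastid at ``rho*lambda``."""
    if chromosome_depth <= 0:
        raise ValueError("chromosome depth must be positive")
    if plastid_ratio <= 0:
        raise ValueError("plastid ratio must be positive")
    rng = np.random.default_rng(config.rng_seed + 3)
    profiles = []
    for i in range(n_chromosomes):
        depths = rng.poisson(chromosome_depth, chromosome_length)
        profiles.append(
            CoverageProfile(
                sequence_id=f"chr{i + 1}",
                intervals=_run_length(depths),
                is_plastid=False,
            )
        )
    depths = rng.poisson(chromosome_depth * plastid_ratio, plastid_length)
    profiles.append(
        CoverageProfile(
            sequence_id="plastid", intervals=_run_length(depths), is_plastid=True
        )
    )
    return profiles


def _run_length(depths: np.ndarray) -> list[tuple[int, int, float]]:
    breaks = np.flatnonzero(np.diff(depths)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(depths)]])
    return [(int(s), int(e), float(depths[s])) for s, e in zip(starts, ends)]


def _translate(codon: str) -> str:
    return CODON_TABLE[codon]


def simulate_codon_pairs(
    config: SimConfig,
    n_codons: int = 300,
    n_substitutions: int = 30,
    omega: float = 0.2,
) -> tuple[str, str]:
    """A CDS pair diverged by accepted point substitutions under Ka/Ks regime ``omega``.

    Proposed single-nucleotide changes are accepted with relative rates
    1 : omega for synonymous : nonsynonymous (normalised so the faster
    class is accepted with probability 1); changes creating stop codons
    are always rejected.
    """
    if n_codons < 10:
        raise ValueError("need at least 10 codons for a stable estimate")
    rng = np.random.default_rng(config.rng_seed + 4)
    codons = []
    sense = sorted(set(CODON_TABLE) - STOP_CODONS)
    for _ in range(n_codons):
        codons.append(sense[rng.integers(0, len(sense))])
    ancestral = "".join(codons)
    derived = list(ancestral)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_nonsyn = min(1.0, omega)
    accepted = 0
    guard = 0
    while accepted < n_substitutions and guard < 200 * n_substitutions:
        guard += 1
        pos = int(rng.integers(0, len(derived)))
        old = derived[pos]
        new = BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        ci = pos // 3
        codon_old = "".join(derived[ci * 3 : ci * 3 + 3])
        codon_new = codon_old[: pos % 3] + new + codon_old[pos % 3 + 1 :]
        if codon_new in STOP_CODONS:
            continue
        syn = _translate(codon_new) == _translate(codon_old)
        p = p_syn if syn else p_nonsyn
        if rng.random() < p:
            derived[pos] = new
            accepted += 1
    return ancestral, "".join(derived)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` with a different RNG seed."""
    return replace(config, rng_seed=seed)
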