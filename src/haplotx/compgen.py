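"""K-mer genome comparison, NG86 Ka/Ks with clock dating, coverage ratios.

Canonical k-mer sets (lexicographic minimum of a window and its reverse
complement, odd k) support Jaccard-based clonality calls, UPGMA pangenome
clustering and windowed conservation anchors.  Synonymous/nonsynonymous
divergence between homeologous coding sequences is estimated with the
Nei-Gojobori (1986) counting method under Jukes-Cantor correction, and a
synonymous molecular clock converts Ks into a divergence time
T = Ks / (2 r) with r the synonymous substitution rate per site per year
(default 6.5e-9, the rice-calibrated rate commonly applied to monocots).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import CoverageProfile, SequenceSet
from .simulate import CODON_TABLE, STOP_CODONS

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_K = 21
DEFAULT_SYN_RATE = 6.5e-9


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerIndex:
    """Canonical k-mer set of one genome."""

    genome_id: str
    k: int
    kmers: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.kmers)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = revcomp(seq)
    n = len(seq)
    out = set()
    acgt = set("ACGT")
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if not acgt.issuperset(fwd):
            continue
        rev = rc[n - k - i : n - i]
        out.add(fwd if fwd <= rev else rev)
    return out


def build_kmer_set(seqs: SequenceSet, k: int = DEFAULT_K, genome_id: str = "") -> KmerIndex:
    """Canonical k-mers of all sequences; windows with non-ACGT are skipped."""
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids self-complementary k-mers)")
    if not 11 <= k <= 31:
        raise ValueError("k must lie in [11, 31]")
    if all(len(s) < k for _, s in seqs.items()):
        raise ValueError("all sequences shorter than k")
    kmers: set[str] = set()
    for _, seq in seqs.items():
        if len(seq) >= k:
            kmers |= _canonical_kmers(seq, k)
    return KmerIndex(genome_id=genome_id, k=k, kmers=kmers)


def jaccard_similarity(a: KmerIndex, b: KmerIndex) -> tuple[float, int, int, int]:
    """(J, shared, unique_to_a, unique_to_b) of two k-mer indices."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    shared = len(a.kmers & b.kmers)
    union = len(a.kmers | b.kmers)
    j = shared / union if union else 1.0
    return j, shared, len(a.kmers) - shared, len(b.kmers) - shared


def pairwise_cluster(indices: list[KmerIndex]) -> tuple[pd.DataFrame, str]:
    """1-Jaccard distance matrix and an average-linkage (UPGMA) newick tree.

    Leaves are sorted lexicographically before linkage so ties resolve
    deterministically.
    """
    if len(indices) < 2:
        raise ValueError("need at least two genomes")
    indices = sorted(indices, key=lambda ix: ix.genome_id)
    labels = [ix.genome_id for ix in indices]
    n = len(indices)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        jac, *_ = jaccard_similarity(indices[i], indices[j])
        dist[i, j] = dist[j, i] = 1.0 - jac
    linkage = hierarchy.average(squareform(dist, checks=False))
    tree = hierarchy.to_tree(linkage)
    newick = _to_newick(tree, labels) + ";"
    return pd.DataFrame(dist, index=labels, columns=labels), newick


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl / 2:.6g},{right}:{dr / 2:.6g})"


def window_conservation(
    sequence: str, pool: KmerIndex, window: int
) -> pd.DataFrame:
    """Fraction of each tiling window's canonical k-mers present in the pool.

    Windows are non-overlapping, 0-based half-open; a trailing partial
    window is reported with its true width.  Windows with no valid k-mer
    carry NaN.
    """
    k = pool.k
    if window < k:
        raise ValueError("window must be at least k")
    rows = []
    for start in range(0, len(sequence), window):
        end = min(start + window, len(sequence))
        if end - start < k:
            frac = np.nan
            n_kmers = 0
        else:
            kmers = _canonical_kmers(sequence[start:end], k)
            n_kmers = len(kmers)
            frac = (
                len(kmers & pool.kmers) / n_kmers if n_kmers else np.nan
            )
        rows.append({"start": start, "end": end, "n_kmers": n_kmers, "fraction": frac})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


@dataclass
class KaKsEstimate:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    saturated: bool = False
    codons_compared: int = 0


def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    At each position, the fraction of the three possible point mutations
    that preserve the amino acid is synonymous; mutations to stop codons
    count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TABLE[alt] == aa and alt not in STOP_CODONS:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _codon_path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over all minimal substitution paths a -> b.

    Paths traversing stop codons are excluded; if every path is blocked,
    all paths are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TABLE[cur] == CODON_TABLE[nxt] and nxt not in STOP_CODONS:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(sd, nd) for sd, nd, blocked in paths if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for sd, nd, _ in paths]
    sd = float(np.mean([x[0] for x in open_paths]))
    nd = float(np.mean([x[1] for x in open_paths]))
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance -(3/4) ln(1 - 4p/3); undefined at saturation p >= 0.75."""
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


AMBIGUOUS = set("RYSWKMBDHVN-")


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsEstimate:
    """Nei-Gojobori (1986) Ka/Ks between two aligned coding sequences.

    Sequences must have equal length, a multiple of 3, with no internal
    stop codons; codons containing gaps or ambiguity codes in either
    sequence are dropped pairwise.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal length")
    if len(cds_a) % 3:
        raise ValueError("length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3].upper(), cds_b[i : i + 3].upper()
        if set(ca) & AMBIGUOUS or set(cb) & AMBIGUOUS:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            if i + 3 < len(cds_a):
                raise ValueError(f"internal stop codon at position {i}")
            continue
        sa, na = _syn_fraction(ca)
        sb, nb = _syn_fraction(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _codon_path_counts(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    saturated = Ks is None or Ka is None
    ratio = None
    if not saturated and Ks is not None and Ks > 0 and Ka is not None:
        ratio = Ka / Ks
    return KaKsEstimate(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        Ks=Ks, Ka=Ka, ratio=ratio, saturated=saturated,
        codons_compared=n_codons,
    )


@dataclass
class ClockParams:
    """Synonymous molecular clock rate, substitutions/site/year."""

    rate: float = DEFAULT_SYN_RATE

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")


def divergence_time(ks: float, clock: ClockParams | None = None) -> float:
    """Years since divergence: T = Ks / (2 r)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    clock = clock or ClockParams()
    return ks / (2.0 * clock.rate)


# ---------------------------------------------------------------------------
# plastid relative coverage


def plastid_nuclear_ratio(profiles: list[CoverageProfile]) -> pd.DataFrame:
    """Median plastid depth over the average chromosome mean depth.

    One row per plastid sequence: the plastid's median per-base depth
    divided by the mean over chromosomes of each chromosome's mean depth.
    NaN when chromosome coverage is zero.
    """
    chroms = [p for p in profiles if not p.is_plastid]
    plastids = [p for p in profiles if p.is_plastid]
    if not chroms or not plastids:
        raise ValueError("need at least one chromosome and one plastid profile")
    chrom_mean = float(np.mean([c.mean_depth() for c in chroms]))
    rows = []
    for p in plastids:
        ratio = p.median_depth() / chrom_mean if chrom_mean > 0 else np.nan
        rows.append(
            {
                "plastid": p.sequence_id,
                "plastid_median_depth": p.median_depth(),
                "chromosome_mean_depth": chrom_mean,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows)
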