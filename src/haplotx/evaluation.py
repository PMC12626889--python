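"""Property-based evaluation of the pipeline against simulator ground truth.

Each function re-runs a complete slice of the pipeline on freshly
generated synthetic data and measures how well the method recovers the
generative truth (estimator error, error control, recall, ordering).
They back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from . import calibration, compgen, diffexpr, enrichment, simulate
from .io import GOResources, SequenceSet
from .simulate import SimConfig


# ---------------------------------------------------------------------------
# calibration recovery


def calibration_recovery(seed: int, n_genes: int = 2000, depth: float = 50.0) -> dict:
    """Median-accuracy estimation error and filter confusion at tau=0.90.

    Eight parental samples per species at the given mean per-gene depth.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        mean_depth=depth,
        n_replicates=1,
        drop_lost_replicates=False,
        n_pacifica_wild=8,
        rng_seed=seed,
    )
    truth = simulate.make_truth(cfg)
    quants, sheet, _ = simulate.simulate_expression_experiment(truth, cfg)
    parent_of = {
        r.sample_id: r.accession
        for r in sheet.table.itertuples()
        if r.accession in ("zmarina", "zpacifica")
    }
    table = calibration.accuracy_table(quants, truth.orthologue_map(), parent_of)
    med = table.median_accuracy().set_index("hap1_id").join(truth.table)
    mae = float((med["median_accuracy"] - med["true_accuracy"]).abs().mean())
    kept = set(calibration.median_accuracy_filter(table, 0.90).hap1_ids)
    t = truth.table
    low = set(t.index[t["true_accuracy"] < 0.85])
    high = set(t.index[t["true_accuracy"] > 0.95])
    return {
        "mae": mae,
        "n_parental_samples": len(parent_of),
        "low_removed_rate": len(low - kept) / len(low) if low else float("nan"),
        "high_retained_rate": len(high & kept) / len(high) if high else float("nan"),
        "n_genes": n_genes,
        "n_low": len(low),
        "n_high": len(high),
    }


# ---------------------------------------------------------------------------
# differential-expression error control and recovery


def _hybrid_leaf_shade(cfg: SimConfig):
    truth = simulate.make_truth(cfg)
    quants, sheet, _ = simulate.simulate_expression_experiment(truth, cfg)
    omap = truth.orthologue_map()
    mats = diffexpr.build_track_matrices(
        quants, sheet, omap, list(truth.table.index), "leaf"
    )
    return truth, quants, sheet, omap, mats["hybrid.hap1"]


def null_error_control(seed: int, n_genes: int = 5000) -> dict:
    """False-call fraction and p-value uniformity with no true effects.

    Shade (t2+t3, n=6) vs t1 (n=3) on the hybrid Hap1 leaf track.
    """
    cfg = SimConfig(
        n_genes=n_genes, pi_de=0.0, pi_bias=0.0,
        mean_depth=300, depth_sdlog=0.5, rng_seed=seed,
    )
    truth, quants, sheet, omap, cm = _hybrid_leaf_shade(cfg)
    cm.size_factors = diffexpr.size_factors_median_of_ratios(cm.counts)
    relab = cm.groups.replace({"t2": "shade", "t3": "shade"})
    cm = diffexpr.CountMatrix(cm.counts, relab, cm.size_factors)
    model = diffexpr.estimate_dispersions(cm)
    raw = diffexpr.nb_wald_contrast(cm, model, "t1", "shade")
    res = diffexpr.finalize_results(raw)
    p = raw["p"].dropna().to_numpy()
    return {
        "significant_fraction": float(res["significant"].mean()),
        "ks_distance": float(stats.kstest(p, "uniform").statistic),
        "n_genes": n_genes,
        "n_defined_p": int(p.size),
    }


def spiked_recovery(seed: int, n_genes: int = 2000) -> dict:
    """Recall and sign agreement for spiked shade and bias effects."""
    cfg = SimConfig(
        n_genes=n_genes, mean_depth=300, depth_sdlog=0.5, rng_seed=seed
    )
    truth = simulate.make_truth(cfg)
    quants, sheet, _ = simulate.simulate_expression_experiment(truth, cfg)
    omap = truth.orthologue_map()
    t = truth.table
    mats = diffexpr.build_track_matrices(
        quants, sheet, omap, list(t.index), "leaf"
    )
    shade = diffexpr.run_shade_contrasts(mats["hybrid.hap1"], "hybrid.hap1", "leaf")
    true_de = set(t.index[t["is_shade_de"]])
    called = shade.up | shade.down
    tp = called & true_de
    shade_recall = len(tp) / len(true_de)
    shade_sign = (
        sum((g in shade.up) == (t.at[g, "shade_lfc"] > 0) for g in tp) / len(tp)
        if tp
        else float("nan")
    )
    split = diffexpr.build_hybrid_split_matrix(quants, sheet, omap, list(t.index), "leaf")
    biases = diffexpr.run_bias_contrasts(split, "leaf")
    true_bias = set(t.index[t["is_biased"]])
    called_bias = set().union(*[b.hap1_biased | b.hap2_biased for b in biases])
    tp_bias = called_bias & true_bias
    sign_ok = total = 0
    for b in biases:
        for g in b.hap2_biased & true_bias:
            sign_ok += t.at[g, "bias_lfc"] > 0
            total += 1
        for g in b.hap1_biased & true_bias:
            sign_ok += t.at[g, "bias_lfc"] < 0
            total += 1
    return {
        "shade_recall": shade_recall,
        "shade_sign_agreement": shade_sign,
        "bias_recall": len(tp_bias) / len(true_bias),
        "bias_sign_agreement": sign_ok / total if total else float("nan"),
        "n_genes": n_genes,
        "n_true_de": len(true_de),
        "n_true_bias": len(true_bias),
    }


# ---------------------------------------------------------------------------
# exact oracles


def bh_oracle_deviation(seed: int, n_vectors: int = 1000) -> dict:
    """Max |BH - brute-force step-up| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(1e-12, 1.0, int(rng.integers(1, 100)))
        ours = diffexpr.bh_adjust(p)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        sp = p[order]
        brute_sorted = [
            min(min(sp[j] * m / (j + 1) for j in range(i, m)), 1.0)
            for i in range(m)
        ]
        brute = np.empty(m)
        brute[order] = brute_sorted
        worst = max(worst, float(np.abs(ours - brute).max()))
    return {"max_abs_deviation": worst, "n_vectors": n_vectors}


def fisher_oracle_deviation(seed: int, n_tables: int = 300) -> dict:
    """Max relative error of the hypergeometric tail vs exact fraction sums."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        N = int(rng.integers(5, 501))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        ours = float(stats.hypergeom.sf(k - 1, N, K, n))
        denom = math.comb(N, n)
        exact = sum(
            math.comb(K, x) * math.comb(N - K, n - x)
            for x in range(k, min(K, n) + 1)
        ) / denom
        if exact > 0:
            worst = max(worst, abs(ours - exact) / exact)
    return {"max_rel_error": worst, "n_tables": n_tables}


def _oracle_codon_counts(ca: str, cb: str) -> tuple[float, float, float, float]:
    """Exhaustive-path (S, N, Sd, Nd) for one codon pair, written from the
    definitions with its own translation lookup."""
    from Bio.Seq import Seq

    stops = {"TAA", "TAG", "TGA"}

    def tr(c: str) -> str:
        return str(Seq(c).translate())

    def sites(codon: str) -> float:
        s = 0.0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in stops and tr(alt) == tr(codon):
                    s += 1 / 3
        return s

    diff = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in stops:
                blocked = True
            if nxt not in stops and tr(nxt) == tr(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [(s, n) for s, n, b in paths if not b] or [(s, n) for s, n, _ in paths]
    S = (sites(ca) + sites(cb)) / 2
    return (
        S,
        3.0 - S,
        float(np.mean([u[0] for u in usable])),
        float(np.mean([u[1] for u in usable])),
    )


def ng86_oracle_sweep() -> dict:
    """Max deviation of NG86 counts from path enumeration over all 61x61
    sense-codon pairs."""
    sense = sorted(set(simulate.CODON_TABLE) - simulate.STOP_CODONS)
    worst = 0.0
    n_pairs = 0
    for ca in sense:
        for cb in sense:
            est = compgen.ng86_kaks(ca, cb)
            S, N, Sd, Nd = _oracle_codon_counts(ca, cb)
            worst = max(
                worst,
                abs(est.S - S),
                abs(est.N - N),
                abs(est.Sd - Sd),
                abs(est.Nd - Nd),
            )
            n_pairs += 1
    return {"max_abs_deviation": worst, "n_pairs": n_pairs}


def jaccard_oracle_deviation(seed: int, n_trials: int = 200) -> dict:
    """Jaccard vs naive set arithmetic on random k-mer-like string sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        xs = {str(x) for x in rng.integers(0, 60, rng.integers(1, 50))}
        ys = {str(y) for y in rng.integers(0, 60, rng.integers(1, 50))}
        a = compgen.KmerIndex("a", 21, xs)
        b = compgen.KmerIndex("b", 21, ys)
        j = compgen.jaccard_similarity(a, b)[0]
        worst = max(worst, abs(j - len(xs & ys) / len(xs | ys)))
    return {"max_abs_deviation": worst, "n_trials": n_trials}


# ---------------------------------------------------------------------------
# enrichment recovery


def enrichment_recovery(seed: int, n_runs: int = 20, n_genes: int = 1500) -> dict:
    """How often the simulator's spiked GO terms reach padj < 0.05."""
    import networkx as nx

    n_ok = 0
    for i in range(n_runs):
        cfg = SimConfig(n_genes=n_genes, rng_seed=seed + 1000 * i)
        truth = simulate.make_truth(cfg)
        terms, edges = simulate.simulate_go_ontology(cfg)
        dag = nx.DiGraph()
        dag.add_nodes_from(terms)
        dag.add_edges_from(edges)
        gene2go = {
            g: set(t.split(";")) - {""} for g, t in truth.table["go_terms"].items()
        }
        go = GOResources(gene2go=gene2go, dag=dag)
        study = set(truth.table.index[truth.table["is_shade_de"]])
        res = enrichment.go_enrichment(study, set(truth.table.index), go)
        sig = set(res.loc[res["significant"], "term_id"])
        n_ok += set(truth.target_terms) <= sig
    return {"n_recovered": n_ok, "n_runs": n_runs, "n_genes": n_genes}


# ---------------------------------------------------------------------------
# clonality ordering


def _clade_leaves(newick: str, clones: set[str]) -> bool:
    """Whether the clones form a clade: some parenthesised group's leaf set
    equals the clone set."""
    # scan balanced groups of the newick string
    stack: list[set[str]] = []
    current = ""
    groups = []
    leafsets: list[set[str]] = []
    for ch in newick:
        if ch == "(":
            stack.append(set())
            current = ""
        elif ch in ",)":
            name = current.split(":")[0].strip()
            if name:
                for s in stack:
                    s.add(name)
            current = ""
            if ch == ")":
                leafsets.append(stack.pop())
        else:
            current += ch
    return clones in leafsets or clones == set().union(*leafsets) if leafsets else False


def clonality_ordering(
    seed: int, n_runs: int = 20, genome_length: int = 100_000
) -> dict:
    """Within-clone vs between-genotype Jaccard separation across seeded runs."""
    ordering_ok = clade_ok = 0
    min_within = 1.0
    max_between = 0.0
    for i in range(n_runs):
        cfg = SimConfig(rng_seed=seed + 7919 * i)
        seqs, labels = simulate.simulate_clone_genomes(cfg, genome_length=genome_length)
        indices = [
            compgen.build_kmer_set(SequenceSet(records={g: s}), 21, genome_id=g)
            for g, s in seqs.items()
        ]
        within, between = [], []
        for a, b in itertools.combinations(indices, 2):
            j = compgen.jaccard_similarity(a, b)[0]
            if labels[a.genome_id] == labels[b.genome_id]:
                within.append(j)
            else:
                between.append(j)
        ordering_ok += min(within) > max(between)
        min_within = min(min_within, min(within))
        max_between = max(max_between, max(between))
        _, newick = compgen.pairwise_cluster(indices)
        clones = {g for g, lab in labels.items() if lab == "G1"}
        clade_ok += _clade_leaves(newick, clones)
    return {
        "n_ordering_ok": ordering_ok,
        "n_clade_ok": clade_ok,
        "n_runs": n_runs,
        "min_within_jaccard": min_within,
        "max_between_jaccard": max_between,
    }


# ---------------------------------------------------------------------------
# clock and plastid ratio


def clock_and_plastid(seed: int) -> dict:
    """Clock round-trip identity, hand-arithmetic plastid fixture, and
    recovery of a simulated plastid:nuclear ratio."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(100):
        T = float(rng.uniform(1e3, 1e8))
        r = float(rng.uniform(1e-10, 1e-7))
        back = compgen.divergence_time(2 * r * T, compgen.ClockParams(rate=r))
        worst = max(worst, abs(back - T) / T)
    from .io import CoverageProfile

    fixture = [
        CoverageProfile("c1", [(0, 100, 10.0)]),
        CoverageProfile("c2", [(0, 100, 20.0)]),
        CoverageProfile("c3", [(0, 100, 30.0)]),
        CoverageProfile("pl", [(0, 100, 2000.0)], is_plastid=True),
    ]
    fixture_ratio = float(compgen.plastid_nuclear_ratio(fixture)["ratio"].iloc[0])
    profiles = simulate.simulate_coverage_tracks(
        SimConfig(rng_seed=seed), chromosome_depth=30, plastid_ratio=50
    )
    sim_ratio = float(compgen.plastid_nuclear_ratio(profiles)["ratio"].iloc[0])
    return {
        "clock_max_rel_error": worst,
        "fixture_ratio": fixture_ratio,
        "simulated_ratio": sim_ratio,
        "simulated_rho_true": 50.0,
        "dated_Ma_at_ks_0_01521": compgen.divergence_time(0.01521) / 1e6,
    }
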