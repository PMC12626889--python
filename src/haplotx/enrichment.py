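"""GO term over-representation by one-sided Fisher (hypergeometric) tests.

For each term with at least one population annotation, the upper-tail
hypergeometric probability P(X >= k) of drawing k study hits from a
population of N genes with K annotated is computed, BH-adjusted across
tested terms, and reported with the fold enrichment (k/n)/(K/N).
Annotation propagation to is_a/part_of ancestors is optional and off by
default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import GOResources

logger = logging.getLogger(__name__)


def propagate_annotations(go: GOResources) -> GOResources:
    """Close every gene's term set under the ancestor relation (idempotent)."""
    import networkx as nx

    anc_cache: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in anc_cache:
            anc_cache[term] = (
                set(nx.descendants(go.dag, term)) if term in go.dag else set()
            )
        return anc_cache[term]

    closed = {
        gene: set().union(terms, *(ancestors(t) for t in terms))
        for gene, terms in go.gene2go.items()
    }
    return GOResources(gene2go=closed, dag=go.dag, n_unknown_terms=go.n_unknown_terms)


def go_enrichment(
    study: set[str],
    population: set[str],
    go: GOResources,
    propagate: bool = False,
    fdr: float = 0.05,
    direction: str = "up",
) -> pd.DataFrame:
    """Over-representation of every annotated term in the study set.

    Returns a DataFrame with columns term_id, term_name, k, n, K, N,
    fold, p, padj, significant, direction, sorted by p.  Terms with no
    population annotation are skipped and excluded from the BH family.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    if not study:
        logger.warning("empty study set; no enrichment computed")
        return _empty_result()
    if propagate:
        go = propagate_annotations(go)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for term in go.gene2go.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    N, n = len(population), len(study)
    records = []
    for term, K in sorted(term_pop.items()):
        k = term_study.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        records.append(
            {
                "term_id": term,
                "term_name": go.term_name(term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold": fold,
                "p": min(max(p, 5e-324), 1.0),
            }
        )
    df = pd.DataFrame(records)
    df["padj"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["padj"] < fdr
    df["direction"] = direction
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "term_id", "term_name", "k", "n", "K", "N",
            "fold", "p", "padj", "significant", "direction",
        ]
    )
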