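"""Haplotype splitting and negative-binomial Wald differential expression.

The engine follows the standard bulk RNA-seq recipe: median-of-ratios
library-size normalisation, per-gene negative-binomial dispersion with a
1/mean trend and geometric-mean shrinkage, a log-link NB GLM fitted by
iteratively reweighted least squares for each two-group contrast, a Wald
test on the group coefficient, and Benjamini-Hochberg adjustment.
Significance requires both adjusted P <= 0.05 and |log2 fold change|
>= 0.5 (both thresholds configurable).

Two analyses are built on the engine:

* shade contrasts — low-light timepoints (t2+t3) pooled as replicates and
  compared against full light t1 (control) and t4 (recovery); a gene is
  shade-responsive if significant in either contrast, separately for each
  expression track (hybrid Hap1, hybrid Hap2, inbred Z. marina) and tissue;
* haplotype-bias contrasts — within each hybrid timepoint x tissue, the
  Hap1 and Hap2 subsample columns are compared as two groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import OrthologueMap, QuantTable, SampleSheet

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8
DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 0.5


@dataclass
class CountMatrix:
    """Genes x samples count matrix with group labels and size factors."""

    counts: pd.DataFrame
    groups: pd.Series  # per-sample labels, index = sample ids
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not yet computed")
        return self.counts / self.size_factors

    def subset(self, sample_ids: list[str], groups: pd.Series | None = None) -> "CountMatrix":
        sf = None if self.size_factors is None else self.size_factors[sample_ids]
        return CountMatrix(
            counts=self.counts[sample_ids],
            groups=self.groups[sample_ids] if groups is None else groups,
            size_factors=sf,
        )


@dataclass
class DispersionModel:
    """Per-gene NB dispersion: method-of-moments, trend, shrunken final."""

    mom_alpha: pd.Series
    trend_a0: float
    trend_a1: float
    final_alpha: pd.Series

    def trend(self, mu: np.ndarray) -> np.ndarray:
        return self.trend_a0 + self.trend_a1 / np.maximum(mu, 1e-12)


# ---------------------------------------------------------------------------
# splitting


def split_hybrid_quant(
    quant: QuantTable, omap: OrthologueMap, retained: list[str] | None = None
) -> pd.DataFrame:
    """Split one hybrid quant into Hap1/Hap2 count columns keyed by hap1 id.

    Returns a DataFrame with columns ``<sample>.hap1`` and ``<sample>.hap2``.
    Pairs whose hap2 transcript is missing from the table count 0 there.
    """
    counts = quant.table["num_reads"]
    universe = set(quant.table.index)
    pairs = omap.pairs
    if retained is not None:
        kept = set(retained)
        pairs = [(h1, h2) for h1, h2 in pairs if h1 in kept]
    missing = [h2 for _, h2 in pairs if h2 not in universe]
    if missing:
        logger.warning(
            "%s: %d hap2 transcripts absent, counted as 0", quant.sample_id, len(missing)
        )
    idx = [h1 for h1, _ in pairs]
    c1 = np.array([float(counts.get(h1, 0.0)) for h1, _ in pairs])
    c2 = np.array([float(counts.get(h2, 0.0)) for _, h2 in pairs])
    return pd.DataFrame(
        {f"{quant.sample_id}.hap1": c1, f"{quant.sample_id}.hap2": c2},
        index=pd.Index(idx, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# normalisation and dispersion


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference."""
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "median-of-ratios needs a pseudo-reference fallback"
        )
    ref = np.exp(np.log(arr[positive]).mean(axis=1))
    factors = np.median(arr[positive] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(cm: CountMatrix) -> DispersionModel:
    """Method-of-moments NB dispersion with a 1/mean trend and shrinkage.

    Moments are taken within group (residual variance pooled across
    groups) so that real condition effects do not inflate the dispersion.
    The trend alpha(mu) = a0 + a1/mu is fit by non-negative least squares
    over genes with positive moment estimates; the final dispersion is
    the geometric mean of the per-gene moment estimate and the trend
    value, floored at 1e-8.
    """
    if cm.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate dispersion")
    q = cm.normalized()
    xim = float((1.0 / cm.size_factors).mean())
    genes = q.index
    num = np.zeros(len(genes))
    den = np.zeros(len(genes))
    total_df = 0
    for _, cols in cm.groups.groupby(cm.groups).groups.items():
        sub = q[list(cols)].to_numpy(dtype=float)
        n_g = sub.shape[1]
        if n_g < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (n_g - 1) * (v - xim * m)
        den += (n_g - 1) * m**2
        total_df += n_g - 1
    if total_df == 0:
        raise ValueError("no group has two or more samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    mom = pd.Series(np.where(np.isfinite(mom), np.maximum(mom, 0.0), np.nan),
                    index=genes, name="mom_alpha")

    mu_bar = q.mean(axis=1).to_numpy(dtype=float)
    use = (mom.to_numpy() > 0) & (mu_bar > 0)
    if use.sum() < 10:
        logger.warning("fewer than 10 genes with positive moment dispersion; trend only")
        a0, a1 = float(np.nanmedian(mom[mom > 0])) if (mom > 0).any() else 0.01, 0.0
        trend_vals = np.full(len(genes), max(a0, ALPHA_FLOOR))
        final = pd.Series(np.maximum(trend_vals, ALPHA_FLOOR), index=genes)
        return DispersionModel(mom, a0, a1, final)
    design = np.column_stack([np.ones(use.sum()), 1.0 / mu_bar[use]])
    coef, _ = optimize.nnls(design, mom.to_numpy()[use])
    a0, a1 = float(coef[0]), float(coef[1])
    trend_vals = np.maximum(a0 + a1 / np.maximum(mu_bar, 1e-12), ALPHA_FLOOR)
    logmom = 0.5 * np.log(np.maximum(mom.to_numpy(), ALPHA_FLOOR))
    final = np.exp(np.where(np.isnan(logmom), np.log(trend_vals), logmom + 0.5 * np.log(trend_vals)))
    final = pd.Series(np.maximum(final, ALPHA_FLOOR), index=genes, name="final_alpha")
    return DispersionModel(mom, a0, a1, final)


# ---------------------------------------------------------------------------
# NB GLM Wald contrast


def _irls_two_group(
    y: np.ndarray,
    indicator: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit log mu = b0 + b1*indicator + offset by IRLS; return (beta, cov, ok)."""
    X = np.column_stack([np.ones_like(indicator, dtype=float), indicator.astype(float)])
    q = y / np.exp(offset)
    m0 = q[indicator == 0].mean()
    m1 = q[indicator == 1].mean()
    eps = 1e-8
    beta = np.array([np.log(max(m0, eps)), np.log(max(m1, eps) / max(m0, eps))])
    ok = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, np.full((2, 2), np.nan), False
        if not np.all(np.isfinite(new)):
            return beta, np.full((2, 2), np.nan), False
        delta = np.abs(new - beta).max()
        beta = new
        if delta < tol:
            ok = True
            break
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return beta, np.full((2, 2), np.nan), False
    return beta, cov, ok


def nb_wald_contrast(
    cm: CountMatrix,
    model: DispersionModel,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``group_b`` relative to ``group_a``.

    Returns a DataFrame (index = gene) with base_mean, log2fc, se,
    wald_z, p; log2fc > 0 means higher expression in ``group_b``.
    Genes with no reads in either group, or whose IRLS fails, carry NaN p.
    """
    sel = cm.groups.isin([group_a, group_b])
    cols = list(cm.groups.index[sel])
    n_a = int((cm.groups[cols] == group_a).sum())
    n_b = int((cm.groups[cols] == group_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need at least one sample")
    if min(n_a, n_b) < 2:
        logger.warning("a group has a single sample; estimates will be unstable")
    indicator = (cm.groups[cols] == group_b).to_numpy().astype(float)
    sf = cm.size_factors[cols].to_numpy(dtype=float)
    offset = np.log(sf)
    counts = cm.counts[cols].to_numpy(dtype=float)
    alphas = model.final_alpha.reindex(cm.counts.index).to_numpy(dtype=float)

    ln2 = np.log(2.0)
    out = np.full((counts.shape[0], 5), np.nan)
    for i in range(counts.shape[0]):
        y = counts[i]
        base_mean = (y / sf).mean()
        out[i, 0] = base_mean
        if y.sum() == 0:
            continue
        beta, cov, ok = _irls_two_group(y, indicator, offset, alphas[i])
        lfc = beta[1] / ln2
        out[i, 1] = lfc
        if not ok or not np.isfinite(cov[1, 1]) or cov[1, 1] <= 0:
            continue
        se = np.sqrt(cov[1, 1]) / ln2
        z = lfc / se
        out[i, 2] = se
        out[i, 3] = z
        out[i, 4] = 2.0 * stats.norm.sf(abs(z))
    df = pd.DataFrame(
        out,
        index=cm.counts.index,
        columns=["base_mean", "log2fc", "se", "wald_z", "p"],
    )
    # exact-zero p underflow: clamp into (0, 1]
    df["p"] = df["p"].clip(lower=5e-324, upper=1.0)
    df.loc[out[:, 4] != out[:, 4], "p"] = np.nan
    return df


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (defined p-values only)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("bh_adjust requires defined p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def finalize_results(
    df: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
) -> pd.DataFrame:
    """Attach BH-adjusted p and the significance flag to a contrast table."""
    df = df.copy()
    defined = df["p"].notna()
    padj = np.full(len(df), np.nan)
    if defined.any():
        padj[defined.to_numpy()] = bh_adjust(df.loc[defined, "p"].to_numpy())
    df["padj"] = padj
    df["significant"] = (
        (df["padj"] <= alpha) & (df["log2fc"].abs() >= lfc_threshold)
    ).fillna(False)
    return df


# ---------------------------------------------------------------------------
# study-level drivers


def build_track_matrices(
    quants: dict[str, QuantTable],
    sheet: SampleSheet,
    omap: OrthologueMap,
    retained: list[str],
    tissue: str,
    zmarina_sum_haplotypes: bool = True,
) -> dict[str, CountMatrix]:
    """Per-track count matrices for one tissue, keyed by hap1 gene id.

    Tracks: ``hybrid.hap1`` and ``hybrid.hap2`` (split hybrid subsamples)
    and ``zmarina`` (inbred parent; haplotype mappings summed per pair by
    default, hap1-only with ``zmarina_sum_haplotypes=False``).
    """
    kept_pairs = [(h1, h2) for h1, h2 in omap.pairs if h1 in set(retained)]
    kept_map = OrthologueMap(pairs=kept_pairs)
    hyb_cols, hap1_cols, hap2_cols = {}, [], []
    groups = {}
    for sid in sheet.samples(accession="hybrid", tissue=tissue):
        tp = sheet.table.loc[sheet.table["sample_id"] == sid, "timepoint"].iloc[0]
        split = split_hybrid_quant(quants[sid], kept_map)
        for hap in ("hap1", "hap2"):
            col = f"{sid}.{hap}"
            hyb_cols[col] = split[col]
            (hap1_cols if hap == "hap1" else hap2_cols).append(col)
            groups[col] = tp
    matrices: dict[str, CountMatrix] = {}
    if hyb_cols:
        hyb = pd.DataFrame(hyb_cols)
        for track, cols in (("hybrid.hap1", hap1_cols), ("hybrid.hap2", hap2_cols)):
            sub = hyb[cols]
            matrices[track] = CountMatrix(
                counts=sub,
                groups=pd.Series({c: groups[c] for c in cols}),
            )
    zm_cols = {}
    zm_groups = {}
    for sid in sheet.samples(accession="zmarina", tissue=tissue):
        tp = sheet.table.loc[sheet.table["sample_id"] == sid, "timepoint"].iloc[0]
        counts = quants[sid].table["num_reads"]
        c1 = np.array([float(counts.get(h1, 0.0)) for h1, _ in kept_pairs])
        c2 = np.array([float(counts.get(h2, 0.0)) for _, h2 in kept_pairs])
        zm_cols[sid] = pd.Series(
            c1 + c2 if zmarina_sum_haplotypes else c1,
            index=[h1 for h1, _ in kept_pairs],
        )
        zm_groups[sid] = tp
    if zm_cols:
        matrices["zmarina"] = CountMatrix(
            counts=pd.DataFrame(zm_cols), groups=pd.Series(zm_groups)
        )
    return matrices


def build_hybrid_split_matrix(
    quants: dict[str, QuantTable],
    sheet: SampleSheet,
    omap: OrthologueMap,
    retained: list[str],
    tissue: str,
) -> CountMatrix:
    """Combined hybrid split matrix (hap1 and hap2 columns) for one tissue.

    Groups are timepoints; haplotype identity is carried by the column
    suffix.  This is the input for the bias contrasts.
    """
    kept_pairs = [(h1, h2) for h1, h2 in omap.pairs if h1 in set(retained)]
    kept_map = OrthologueMap(pairs=kept_pairs)
    cols = {}
    groups = {}
    for sid in sheet.samples(accession="hybrid", tissue=tissue):
        tp = sheet.table.loc[sheet.table["sample_id"] == sid, "timepoint"].iloc[0]
        split = split_hybrid_quant(quants[sid], kept_map)
        for hap in ("hap1", "hap2"):
            col = f"{sid}.{hap}"
            cols[col] = split[col]
            groups[col] = tp
    if not cols:
        raise ValueError(f"no hybrid samples for tissue {tissue!r}")
    return CountMatrix(counts=pd.DataFrame(cols), groups=pd.Series(groups))


@dataclass
class ShadeResult:
    """Up/down shade-responsive gene sets for one track and tissue."""

    track: str
    tissue: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_shade_contrasts(
    cm: CountMatrix,
    track: str,
    tissue: str,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
) -> ShadeResult:
    """Shade (t2+t3) vs t1 and vs t4 on one track matrix.

    The matrix's groups must be timepoints.  Reduced-light samples are
    pooled into one ``shade`` group; a gene is up (down) if significantly
    higher (lower) in shade in either contrast.
    """
    relabeled = cm.groups.replace({"t2": "shade", "t3": "shade"})
    cm = CountMatrix(counts=cm.counts, groups=relabeled, size_factors=cm.size_factors)
    if cm.size_factors is None:
        cm.size_factors = size_factors_median_of_ratios(cm.counts)
    model = estimate_dispersions(cm)
    result = ShadeResult(track=track, tissue=tissue)
    for ref in ("t1", "t4"):
        if (relabeled == ref).sum() == 0 or (relabeled == "shade").sum() == 0:
            logger.warning("%s/%s: missing group for shade vs %s; skipped", track, tissue, ref)
            continue
        raw = nb_wald_contrast(cm, model, group_a=ref, group_b="shade")
        res = finalize_results(raw, alpha=alpha, lfc_threshold=lfc_threshold)
        result.contrasts[f"shade_vs_{ref}"] = res
        sig = res[res["significant"]]
        result.up |= set(sig.index[sig["log2fc"] > 0])
        result.down |= set(sig.index[sig["log2fc"] < 0])
    return result


@dataclass
class BiasResult:
    """Haplotype-bias calls for one timepoint and tissue."""

    timepoint: str
    tissue: str
    hap1_biased: set[str] = field(default_factory=set)
    hap2_biased: set[str] = field(default_factory=set)
    table: pd.DataFrame | None = None


def run_bias_contrasts(
    hybrid_split: CountMatrix,
    tissue: str,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
) -> list[BiasResult]:
    """Hap1 vs Hap2 contrasts per timepoint on the hybrid split matrix.

    ``hybrid_split`` holds both ``.hap1`` and ``.hap2`` columns with
    groups of the form ``<timepoint>`` and column names carrying the
    haplotype suffix.  log2fc > 0 marks Hap2-biased genes.
    """
    if hybrid_split.size_factors is None:
        hybrid_split.size_factors = size_factors_median_of_ratios(hybrid_split.counts)
    # dispersion from the full split matrix: residual moments within each
    # (timepoint, haplotype) cell, pooled across cells
    cells = pd.Series(
        {
            c: f"{tp}.{'hap2' if c.endswith('.hap2') else 'hap1'}"
            for c, tp in hybrid_split.groups.items()
        }
    )
    full = CountMatrix(
        counts=hybrid_split.counts, groups=cells, size_factors=hybrid_split.size_factors
    )
    model = estimate_dispersions(full)
    results = []
    for tp in sorted(set(hybrid_split.groups)):
        cols = list(hybrid_split.groups.index[hybrid_split.groups == tp])
        haps = pd.Series(
            {c: ("hap2" if c.endswith(".hap2") else "hap1") for c in cols}
        )
        if min((haps == "hap1").sum(), (haps == "hap2").sum()) < 2:
            logger.warning("%s/%s: fewer than 2 replicates per haplotype; skipped", tp, tissue)
            continue
        sub = hybrid_split.subset(cols, groups=haps)
        raw = nb_wald_contrast(sub, model, group_a="hap1", group_b="hap2")
        res = finalize_results(raw, alpha=alpha, lfc_threshold=lfc_threshold)
        sig = res[res["significant"]]
        results.append(
            BiasResult(
                timepoint=tp,
                tissue=tissue,
                hap1_biased=set(sig.index[sig["log2fc"] < 0]),
                hap2_biased=set(sig.index[sig["log2fc"] > 0]),
                table=res,
            )
        )
    return results
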