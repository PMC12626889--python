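import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haplotx import diffexpr, simulate
from haplotx.diffexpr import CountMatrix
from haplotx.io import OrthologueMap

from conftest import make_quant


def two_group_matrix(counts_a, counts_b, genes=None):
    """CountMatrix with groups A (columns a*) and B (columns b*)."""
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    cols = {f"a{i}": a[:, i] for i in range(a.shape[1])}
    cols |= {f"b{i}": b[:, i] for i in range(b.shape[1])}
    df = pd.DataFrame(cols, index=genes or [f"g{i}" for i in range(a.shape[0])])
    groups = pd.Series({c: c[0].upper() for c in df.columns})
    return CountMatrix(counts=df, groups=groups)


class TestSplit:
    def test_pair_counts_land_in_columns(self, toy_map):
        q = make_quant("h1", {"a1": 12, "b1": 8, "a2": 1, "b2": 2, "a3": 0, "b3": 5})
        split = diffexpr.split_hybrid_quant(q, toy_map)
        assert split.at["a1", "h1.hap1"] == 12
        assert split.at["a1", "h1.hap2"] == 8

    def test_missing_hap2_counts_zero_with_warning(self, caplog):
        omap = OrthologueMap(pairs=[("a1", "b1")])
        q = make_quant("h1", {"a1": 7})
        with caplog.at_level("WARNING"):
            split = diffexpr.split_hybrid_quant(q, omap)
        assert split.at["a1", "h1.hap2"] == 0.0
        assert any("absent" in r.message for r in caplog.records)

    def test_split_conserves_pair_totals(self, small_experiment, small_truth):
        quants, sheet, _ = small_experiment
        omap = small_truth.orthologue_map()
        sid = sheet.samples(accession="hybrid")[0]
        split = diffexpr.split_hybrid_quant(quants[sid], omap)
        q = quants[sid]
        totals = np.array(
            [q.num_reads(h1) + q.num_reads(h2) for h1, h2 in omap.pairs]
        )
        np.testing.assert_allclose(split.sum(axis=1).to_numpy(), totals)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = diffexpr.size_factors_median_of_ratios(counts)
        np.testing.assert_allclose(sf.to_numpy(), [1.0, 1.0])

    def test_doubled_column_hand_fixture(self):
        a = np.array([10, 20, 30, 40, 50], dtype=float)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        sf = diffexpr.size_factors_median_of_ratios(counts)
        # reference = geometric mean => ratios 1/sqrt2 and sqrt2
        np.testing.assert_allclose(
            sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_poisson_scaled_recovery(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(5, 1, 2000)
        true = np.array([1.0, 1.5, 0.7])
        counts = pd.DataFrame(
            {f"s{i}": rng.poisson(base * t) for i, t in enumerate(true)}
        )
        sf = diffexpr.size_factors_median_of_ratios(counts)
        est = sf.to_numpy() / np.exp(np.log(sf.to_numpy()).mean())
        want = true / np.exp(np.log(true).mean())
        np.testing.assert_allclose(est, want, rtol=0.03)

    def test_no_all_positive_gene_suggests_fallback(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            diffexpr.size_factors_median_of_ratios(counts)


class TestDispersions:
    def _matrix(self, arr, groups=None):
        df = pd.DataFrame(
            np.asarray(arr, dtype=float),
            columns=[f"s{i}" for i in range(np.asarray(arr).shape[1])],
        )
        g = pd.Series(groups or {c: "A" for c in df.columns})
        cm = CountMatrix(counts=df, groups=g)
        cm.size_factors = pd.Series(1.0, index=df.columns)
        return cm

    def test_constant_counts_zero_moment(self):
        cm = self._matrix(np.tile([[100.0]], (20, 6)))
        model = diffexpr.estimate_dispersions(cm)
        assert (model.mom_alpha.fillna(0) == 0).all()
        assert (model.final_alpha > 0).all()

    def test_recovers_truth_within_factor_two(self):
        rng = np.random.default_rng(1)
        mu, alpha = 200.0, 0.05
        counts = simulate._nb_draw(rng, np.full((500, 6), mu), np.full((500, 6), alpha))
        cm = self._matrix(counts)
        model = diffexpr.estimate_dispersions(cm)
        med = float(model.final_alpha.median())
        assert alpha / 2 < med < alpha * 2

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, (50, 6)).astype(float)
        cm1 = self._matrix(counts)
        cm2 = self._matrix(counts)
        m1 = diffexpr.estimate_dispersions(cm1)
        m2 = diffexpr.estimate_dispersions(cm2)
        pd.testing.assert_series_equal(m1.final_alpha, m2.final_alpha)

    def test_group_effect_not_counted_as_dispersion(self):
        # strong mean shift between groups must not inflate alpha
        rng = np.random.default_rng(3)
        a = rng.poisson(100, (300, 3)).astype(float)
        b = rng.poisson(800, (300, 3)).astype(float)
        cm = self._matrix(
            np.hstack([a, b]),
            groups={f"s{i}": ("A" if i < 3 else "B") for i in range(6)},
        )
        model = diffexpr.estimate_dispersions(cm)
        assert float(model.final_alpha.median()) < 0.02


class TestWaldContrast:
    def _fit(self, cm):
        cm.size_factors = diffexpr.size_factors_median_of_ratios(cm.counts)
        model = diffexpr.estimate_dispersions(cm)
        return diffexpr.nb_wald_contrast(cm, model, "A", "B")

    def test_exact_doubling_converges_to_lfc_one(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(10_000, (200, 3)).astype(float)
        cm = two_group_matrix(base, 2 * base)
        res = self._fit(cm)
        # size factors absorb a global doubling; fix factors to 1 instead
        cm.size_factors = pd.Series(1.0, index=cm.counts.columns)
        model = diffexpr.estimate_dispersions(cm)
        res = diffexpr.nb_wald_contrast(cm, model, "A", "B")
        assert res["log2fc"].mean() == pytest.approx(1.0, abs=0.01)

    def test_all_zero_gene_undefined_p(self):
        cm = two_group_matrix(
            [[0, 0, 0], [10, 12, 9]], [[0, 0, 0], [11, 10, 13]]
        )
        res = self._fit(cm)
        assert np.isnan(res.loc["g0", "p"])
        assert np.isfinite(res.loc["g1", "p"])

    def test_reversing_groups_negates_lfc(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, (100, 6)).astype(float)
        cm = two_group_matrix(counts[:, :3], counts[:, 3:])
        cm.size_factors = pd.Series(1.0, index=cm.counts.columns)
        model = diffexpr.estimate_dispersions(cm)
        fwd = diffexpr.nb_wald_contrast(cm, model, "A", "B")
        rev = diffexpr.nb_wald_contrast(cm, model, "B", "A")
        np.testing.assert_allclose(
            fwd["log2fc"].to_numpy(), -rev["log2fc"].to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            fwd["p"].to_numpy(), rev["p"].to_numpy(), atol=1e-10
        )

    def test_null_pvalues_near_uniform(self):
        rng = np.random.default_rng(6)
        counts = simulate._nb_draw(
            rng, np.full((2000, 9), 200.0), np.full((2000, 9), 0.05)
        ).astype(float)
        cm = two_group_matrix(counts[:, :6], counts[:, 6:])
        res = self._fit(cm)
        from scipy import stats

        p = res["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").statistic < 0.05


class TestBH:
    def test_hand_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(diffexpr.bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.37]), [0.37])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(7)

        def brute(p):
            # padj_(i) = min_{j >= i} p_(j) * m / j, straight off the definition
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            sp = p[order]
            adj_sorted = [
                min(min(sp[j] * m / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)
            ]
            out = np.empty(m)
            out[order] = adj_sorted
            return out

        for _ in range(50):
            p = rng.uniform(1e-6, 1, rng.integers(1, 40))
            np.testing.assert_allclose(diffexpr.bh_adjust(p), brute(p), atol=1e-12)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.uniform(1e-12, 1, rng.integers(1, 200))
            ours = diffexpr.bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                diffexpr.bh_adjust(bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=100))
    def test_padj_at_least_p_and_monotone(self, pvals):
        p = np.array(pvals)
        adj = diffexpr.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestStudyContrasts:
    def test_shade_union_semantics(self, de_experiment):
        truth, quants, sheet = de_experiment
        omap = truth.orthologue_map()
        mats = diffexpr.build_track_matrices(
            quants, sheet, omap, list(truth.table.index), "leaf"
        )
        res = diffexpr.run_shade_contrasts(mats["hybrid.hap1"], "hybrid.hap1", "leaf")
        assert set(res.contrasts) == {"shade_vs_t1", "shade_vs_t4"}
        union_up = set()
        for table in res.contrasts.values():
            sig = table[table["significant"]]
            union_up |= set(sig.index[sig["log2fc"] > 0])
        assert res.up == union_up

    def test_shade_recovery_and_signs(self, de_experiment):
        truth, quants, sheet = de_experiment
        t = truth.table
        omap = truth.orthologue_map()
        mats = diffexpr.build_track_matrices(
            quants, sheet, omap, list(t.index), "leaf"
        )
        res = diffexpr.run_shade_contrasts(mats["hybrid.hap1"], "hybrid.hap1", "leaf")
        true_de = set(t.index[t["is_shade_de"]])
        called = res.up | res.down
        assert len(called & true_de) / len(true_de) >= 0.8
        agree = sum(
            (g in res.up) == (t.at[g, "shade_lfc"] > 0) for g in called & true_de
        )
        assert agree / len(called & true_de) >= 0.99

    def test_bias_label_swap_symmetry(self, de_experiment):
        truth, quants, sheet = de_experiment
        omap = truth.orthologue_map()
        split = diffexpr.build_hybrid_split_matrix(
            quants, sheet, omap, list(truth.table.index)[:200], "leaf"
        )
        swapped_cols = {
            c: (c[:-5] + ".hap1" if c.endswith(".hap2") else c[:-5] + ".hap2")
            for c in split.counts.columns
        }
        swapped = CountMatrix(
            counts=split.counts.rename(columns=swapped_cols),
            groups=split.groups.rename(index=swapped_cols),
        )
        res = diffexpr.run_bias_contrasts(split, "leaf")
        res_swapped = diffexpr.run_bias_contrasts(swapped, "leaf")
        for a, b in zip(res, res_swapped):
            assert a.hap1_biased == b.hap2_biased
            assert a.hap2_biased == b.hap1_biased

    def test_bias_recovery(self, de_experiment):
        truth, quants, sheet = de_experiment
        t = truth.table
        omap = truth.orthologue_map()
        split = diffexpr.build_hybrid_split_matrix(
            quants, sheet, omap, list(t.index), "leaf"
        )
        results = diffexpr.run_bias_contrasts(split, "leaf")
        called = set().union(*[r.hap1_biased | r.hap2_biased for r in results])
        true_bias = set(t.index[t["is_biased"]])
        assert len(called & true_bias) / len(true_bias) >= 0.8
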