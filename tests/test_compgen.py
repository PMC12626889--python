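import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplotx import compgen, simulate
from haplotx.compgen import ClockParams, KmerIndex
from haplotx.io import SequenceSet


# --- independent oracles ----------------------------------------------------

def naive_canonical_kmers(seq: str, k: int) -> set[str]:
    """Brute-force canonical k-mer enumeration via Biopython reverse complement."""
    from Bio.Seq import Seq

    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= set("ACGT"):
            rc = str(Seq(w).reverse_complement())
            out.add(min(w, rc))
    return out


def biopython_translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


SENSE_CODONS = sorted(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if biopython_translate(c) != "*"
)


def oracle_codon_counts(ca: str, cb: str):
    """(S, N, Sd, Nd) for one codon pair by exhaustive path enumeration,
    classifying each step with Biopython's translation table."""
    stops = {"TAA", "TAG", "TGA"}

    def sites(codon):
        s = 0.0
        aa = biopython_translate(codon)
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in stops and biopython_translate(alt) == aa:
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
            if nxt not in stops and biopython_translate(nxt) == biopython_translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [(s, n) for s, n, b in paths if not b] or [(s, n) for s, n, _ in paths]
    S = (sites(ca) + sites(cb)) / 2
    Sd = float(np.mean([u[0] for u in usable]))
    Nd = float(np.mean([u[1] for u in usable]))
    return S, 3.0 - S, Sd, Nd


# --- k-mers -----------------------------------------------------------------

class TestKmers:
    def test_matches_naive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), rng.integers(25, 200)))
            got = compgen.build_kmer_set(
                SequenceSet(records={"s": seq}), k=11, genome_id="s"
            ).kmers
            assert got == naive_canonical_kmers(seq, 11)

    def test_short_example(self):
        got = compgen._canonical_kmers("ACGTA", 3)
        assert got == naive_canonical_kmers("ACGTA", 3)

    def test_invariant_under_reverse_complement(self):
        seq = "ACGTTGCATGGCATACGATCGATTACA"
        a = compgen.build_kmer_set(SequenceSet(records={"s": seq}), 11)
        b = compgen.build_kmer_set(
            SequenceSet(records={"s": compgen.revcomp(seq)}), 11
        )
        assert a.kmers == b.kmers

    def test_windows_with_n_skipped(self):
        seq = "ACGTACGTACG" + "N" + "ACGTACGTACG"
        got = compgen.build_kmer_set(SequenceSet(records={"s": seq}), 11).kmers
        assert got == naive_canonical_kmers(seq, 11)
        assert len(got) < len(seq) - 11 + 1

    def test_even_or_out_of_range_k_rejected(self):
        seqs = SequenceSet(records={"s": "ACGT" * 20})
        for k in (12, 9, 33):
            with pytest.raises(ValueError):
                compgen.build_kmer_set(seqs, k)

    def test_all_sequences_too_short_rejected(self):
        with pytest.raises(ValueError):
            compgen.build_kmer_set(SequenceSet(records={"s": "ACGTT"}), 21)


class TestJaccard:
    def test_identity_disjoint_and_half(self):
        a = KmerIndex("a", 11, {"x", "y", "z"})
        b = KmerIndex("b", 11, {"y", "z", "w"})
        assert compgen.jaccard_similarity(a, a)[0] == 1.0
        assert compgen.jaccard_similarity(
            a, KmerIndex("c", 11, {"q"})
        )[0] == 0.0
        j, shared, ua, ub = compgen.jaccard_similarity(a, b)
        assert (j, shared, ua, ub) == (0.5, 2, 1, 1)

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            compgen.jaccard_similarity(KmerIndex("a", 11), KmerIndex("b", 13))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.sets(st.integers(0, 50), min_size=1),
        st.sets(st.integers(0, 50), min_size=1),
    )
    def test_symmetric_and_matches_set_arithmetic(self, xs, ys):
        a = KmerIndex("a", 11, {str(x) for x in xs})
        b = KmerIndex("b", 11, {str(y) for y in ys})
        jab = compgen.jaccard_similarity(a, b)[0]
        jba = compgen.jaccard_similarity(b, a)[0]
        assert jab == jba == len(xs & ys) / len(xs | ys)


class TestCluster:
    def test_identical_pair_joins_first(self):
        a = KmerIndex("beta", 11, {"x", "y"})
        b = KmerIndex("alpha", 11, {"x", "y"})
        c = KmerIndex("gamma", 11, {"x", "q", "r"})
        dist, newick = compgen.pairwise_cluster([a, b, c])
        assert "(alpha:0,beta:0)" in newick
        assert (dist.to_numpy().diagonal() == 0).all()
        np.testing.assert_allclose(dist.to_numpy(), dist.to_numpy().T)

    def test_clones_form_clade(self):
        from skbio import TreeNode
        import io as stdio

        cfg = simulate.SimConfig(rng_seed=17)
        seqs, labels = simulate.simulate_clone_genomes(cfg, genome_length=20_000)
        indices = [
            compgen.build_kmer_set(SequenceSet(records={g: s}), 21, genome_id=g)
            for g, s in seqs.items()
        ]
        _, newick = compgen.pairwise_cluster(indices)
        tree = TreeNode.read(stdio.StringIO(newick), convert_underscores=False)
        clones = [g for g, lab in labels.items() if lab == "G1"]
        lca = tree.lca(clones)
        assert {t.name for t in lca.tips()} == set(clones)


class TestWindowConservation:
    def test_self_pool_fully_conserved(self):
        seq = "ACGTTGCATGGCATACGATCGATTACAGGCATCAGTTACG" * 5
        pool = compgen.build_kmer_set(SequenceSet(records={"s": seq}), 11)
        frac = compgen.window_conservation(seq, pool, 50)["fraction"]
        assert (frac.dropna() == 1.0).all()

    def test_disjoint_pool_zero(self):
        pool = compgen.build_kmer_set(SequenceSet(records={"s": "A" * 50}), 11)
        frac = compgen.window_conservation("CGCGTATGCGCATTGACGAT" * 5, pool, 50)[
            "fraction"
        ]
        assert (frac.dropna() == 0.0).all()

    def test_step_change_at_breakpoint(self):
        rng = np.random.default_rng(3)
        shared = "".join(rng.choice(list("ACGT"), 500))
        novel = "".join(rng.choice(list("ACGT"), 500))
        chromosome = shared + novel
        pool = compgen.build_kmer_set(SequenceSet(records={"p": shared}), 21)
        win = compgen.window_conservation(chromosome, pool, 100)
        first = win[win["end"] <= 500]["fraction"]
        last = win[win["start"] >= 500]["fraction"]
        assert first.min() > 0.9
        assert last.max() < 0.1

    def test_window_below_k_rejected(self):
        pool = compgen.build_kmer_set(SequenceSet(records={"s": "ACGT" * 10}), 11)
        with pytest.raises(ValueError):
            compgen.window_conservation("ACGT" * 10, pool, 5)

    def test_partial_last_window_true_width(self):
        seq = "ACGTTGCATGGCATACGATCGATTACAGGCA"  # 31 bp
        pool = compgen.build_kmer_set(SequenceSet(records={"s": seq}), 11)
        win = compgen.window_conservation(seq, pool, 20)
        assert list(win["end"])[-1] == 31


class TestNG86:
    def test_identical_sequences_zero(self):
        est = compgen.ng86_kaks("ATGGCT", "ATGGCT")
        assert est.Sd == est.Nd == 0
        assert est.Ka == 0 and est.Ks == 0 and est.ratio is None

    def test_phe_phe_single_synonymous(self):
        est = compgen.ng86_kaks("TTT", "TTC")
        assert est.Nd == 0 and est.Sd == 1
        assert est.Ka == 0
        assert est.pS > 0

    def test_sites_sum_to_three_per_codon(self):
        for codon in SENSE_CODONS:
            s, n = compgen._syn_fraction(codon)
            assert s + n == pytest.approx(3.0)

    def test_counts_match_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            codons_a = rng.choice(SENSE_CODONS, 30)
            codons_b = [
                rng.choice(SENSE_CODONS) if rng.random() < 0.3 else c
                for c in codons_a
            ]
            a, b = "".join(codons_a), "".join(codons_b)
            est = compgen.ng86_kaks(a, b)
            S = N = Sd = Nd = 0.0
            for ca, cb in zip(codons_a, codons_b):
                s, n, sd, nd = oracle_codon_counts(ca, cb)
                S += s
                N += n
                Sd += sd
                Nd += nd
            assert est.S == pytest.approx(S, abs=1e-9)
            assert est.N == pytest.approx(N, abs=1e-9)
            assert est.Sd == pytest.approx(Sd, abs=1e-9)
            assert est.Nd == pytest.approx(Nd, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(SENSE_CODONS, 40))
        b = "".join(rng.choice(SENSE_CODONS, 40))
        try:
            ab = compgen.ng86_kaks(a, b)
            ba = compgen.ng86_kaks(b, a)
        except ValueError:
            return
        assert ab.Sd == pytest.approx(ba.Sd)
        assert ab.Nd == pytest.approx(ba.Nd)
        assert ab.S == pytest.approx(ba.S)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compgen.ng86_kaks("ATG", "ATGGCT")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            compgen.ng86_kaks("ATGTAAGCT", "ATGTAAGCT")

    def test_purifying_regime_recovered(self):
        ratios = []
        for seed in range(10):
            cfg = simulate.SimConfig(rng_seed=seed)
            a, b = simulate.simulate_codon_pairs(cfg, 300, 50, omega=0.2)
            est = compgen.ng86_kaks(a, b)
            if est.ratio is not None:
                ratios.append(est.ratio)
        assert np.mean(ratios) < 1.0


class TestClock:
    def test_zero_ks_zero_time(self):
        assert compgen.divergence_time(0.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(1e3, 1e8),
        st.floats(1e-10, 1e-7),
    )
    def test_round_trip_identity(self, T, r):
        clock = ClockParams(rate=r)
        assert compgen.divergence_time(2 * r * T, clock) == pytest.approx(T, rel=1e-12)

    def test_headline_rate_and_ks(self):
        # Ks 0.01521 at the rice-calibrated rate dates to 1.17 Myr
        T = compgen.divergence_time(0.01521, ClockParams(rate=6.5e-9))
        assert T == pytest.approx(1.17e6, rel=1e-3)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            compgen.divergence_time(-0.1)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            ClockParams(rate=0.0)


class TestPlastidRatio:
    def _profile(self, name, depth, length=100, plastid=False):
        from haplotx.io import CoverageProfile

        return CoverageProfile(
            sequence_id=name, intervals=[(0, length, depth)], is_plastid=plastid
        )

    def test_hand_arithmetic(self):
        profiles = [
            self._profile("c1", 10),
            self._profile("c2", 20),
            self._profile("c3", 30),
            self._profile("pl", 2000, plastid=True),
        ]
        res = compgen.plastid_nuclear_ratio(profiles)
        assert res["ratio"].iloc[0] == pytest.approx(100.0)

    def test_equal_depth_unit_ratio(self):
        profiles = [self._profile("c1", 25), self._profile("pl", 25, plastid=True)]
        assert compgen.plastid_nuclear_ratio(profiles)["ratio"].iloc[0] == 1.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            compgen.plastid_nuclear_ratio([self._profile("c1", 10)])

    def test_simulated_rho_recovered(self):
        profiles = simulate.simulate_coverage_tracks(
            simulate.SimConfig(rng_seed=8), chromosome_depth=30, plastid_ratio=50
        )
        res = compgen.plastid_nuclear_ratio(profiles)
        assert res["ratio"].iloc[0] == pytest.approx(50, rel=0.05)
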