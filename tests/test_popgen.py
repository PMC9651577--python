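"""Diversity, neutrality and differentiation statistics vs independent oracles."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from fawclans.io import AlignedSequenceSet
from fawclans.popgen import (diversity, fst_matrix, fst_pair, fu_li_f_star,
                             fu_li_f_star_constants, tajima_constants,
                             tajimas_d)


def aln(*seqs):
    return AlignedSequenceSet({f"s{i}": s for i, s in enumerate(seqs)})


def brute_force_kbar(seqs):
    """Oracle: mean pairwise differences by direct string comparison."""
    strings = list(seqs)
    diffs = [
        sum(x != y for x, y in zip(a, b))
        for a, b in combinations(strings, 2)
    ]
    return sum(diffs) / len(diffs)


class TestDiversity:
    def test_all_distinct_hd_is_one(self):
        d = diversity(aln("AAAA", "AAAT", "AATT", "ATTT"))
        assert d.hd == pytest.approx(1.0)

    def test_monomorphic(self):
        d = diversity(aln("ACGT", "ACGT", "ACGT"))
        assert d.hd == 0.0 and d.pi == 0.0 and d.S == 0

    def test_worked_example(self):
        d = diversity(aln("AAAA", "AAAT", "AATT"))
        assert d.S == 2
        assert d.k_bar == pytest.approx(4 / 3)
        assert d.pi == pytest.approx(1 / 3)
        assert d.k_bar == pytest.approx(
            brute_force_kbar(["AAAA", "AAAT", "AATT"]))

    def test_hd_two_haplotypes(self):
        # counts (2,1), n=3: hd = (3/2)(1 - 5/9) = 2/3
        d = diversity(aln("AAAA", "AAAA", "TTTT"))
        assert d.hd == pytest.approx(2 / 3)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            strings = ["".join(rng.choice(list("ACGT"), size=12))
                       for _ in range(rng.integers(3, 9))]
            d = diversity(AlignedSequenceSet(
                {f"x{i}": s for i, s in enumerate(strings)}))
            assert d.k_bar == pytest.approx(brute_force_kbar(strings))

    def test_input_order_invariance(self):
        strings = ["ACGT", "ACGA", "TCGA", "ACGT"]
        d1 = diversity(AlignedSequenceSet(
            {f"a{i}": s for i, s in enumerate(strings)}))
        d2 = diversity(AlignedSequenceSet(
            {f"a{i}": s for i, s in enumerate(reversed(strings))}))
        assert d1.k_bar == d2.k_bar and d1.hd == d2.hd and d1.S == d2.S

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            diversity(aln("ACGT"))

    def test_all_sites_deleted(self):
        with pytest.raises(ValueError, match="deletion"):
            diversity(aln("A-", "-A"))


def _tajima_oracle_n4():
    """High-precision evaluation of D for the worked n=4, S=1 case."""
    n = 4
    a1 = Fraction(1, 1) + Fraction(1, 2) + Fraction(1, 3)
    a2 = Fraction(1, 1) + Fraction(1, 4) + Fraction(1, 9)
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    S = 1
    k_bar = Fraction(1, 2)
    var = e1 * S + e2 * S * (S - 1)
    return float(k_bar - S / a1) / math.sqrt(float(var))


class TestTajimasD:
    def test_monomorphic_undefined(self):
        r = tajimas_d(aln("AAA", "AAA", "AAA", "AAA"))
        assert r.status == "undefined_S0" and math.isnan(r.value)

    def test_worked_n4_example(self):
        r = tajimas_d(aln("AAA", "AAA", "AAA", "AAT"))
        assert r.S == 1 and r.k_bar == pytest.approx(0.5)
        assert r.value == pytest.approx(_tajima_oracle_n4(), abs=1e-6)
        assert r.value == pytest.approx(-0.612, abs=1e-3)

    def test_matches_tskit_on_simulated_data(self):
        # independent implementation check: simulate with msprime, compare
        # against tskit's Tajima's D on the same variant matrix
        import msprime

        ts = msprime.sim_ancestry(samples=10, ploidy=1, sequence_length=500,
                                  random_seed=5)
        ts = msprime.sim_mutations(ts, rate=5e-3, random_seed=5,
                                   model=msprime.BinaryMutationModel())
        G = ts.genotype_matrix()          # sites x samples, 0/1
        L = 500
        n = G.shape[1]
        seqs = []
        for j in range(n):
            row = ["A"] * L
            for s_idx, site in enumerate(ts.sites()):
                if G[s_idx, j]:
                    row[int(site.position)] = "T"
            seqs.append("".join(row))
        ours = tajimas_d(AlignedSequenceSet(
            {f"g{i}": s for i, s in enumerate(seqs)}))
        assert ours.value == pytest.approx(float(ts.Tajimas_D()), rel=1e-6)


def _fstar_oracle_n4(variant="corrected"):
    """Direct evaluation of F* for the n=4 single-singleton alignment."""
    n = 4
    a = 1 + 1 / 2 + 1 / 3
    b = 1 + 1 / 4 + 1 / 9
    a1 = a + 1 / n
    v = ((2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
         + 2 * (n - 1) * a / n**2 - 8 * b / n) / (a * a + b)
    if variant == "corrected":
        u = (n / (n - 1) + (n + 1) / (3 * (n - 1)) - 4 / (n * (n - 1))
             + 2 * (n + 1) / (n - 1) ** 2 * (a1 - 2 * n / (n + 1))) / a - v
    else:
        u = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * a1)
             / (3 * n * (n - 1))) / a - v
    S, eta, k_bar = 1, 1, 0.5
    return (k_bar - eta * (n - 1) / n) / math.sqrt(u * S + v * S * S)


class TestFuLiFStar:
    def test_monomorphic_undefined(self):
        r = fu_li_f_star(aln("AAA", "AAA", "AAA", "AAA"))
        assert r.status == "undefined_S0"

    @pytest.mark.parametrize("variant", ["corrected", "original"])
    def test_worked_n4_example(self, variant):
        r = fu_li_f_star(aln("AAA", "AAA", "AAA", "AAT"), variant=variant)
        assert r.eta_s == 1
        assert r.value == pytest.approx(_fstar_oracle_n4(variant), abs=1e-6)

    def test_variants_differ(self):
        c = fu_li_f_star_constants(10, "corrected")
        o = fu_li_f_star_constants(10, "original")
        assert c["v_f"] == o["v_f"]
        assert c["u_f"] != o["u_f"]

    def test_shares_counts_with_tajima(self):
        # D and F* computed on one input must agree on S, eta_s, k_bar
        seqs = aln("ACGTAC", "ACGTAT", "ACGAAC", "TCGTAC", "ACGTAC")
        d = tajimas_d(seqs)
        f = fu_li_f_star(seqs)
        assert (d.S, d.eta_s, d.k_bar) == (f.S, f.eta_s, f.k_bar)

    def test_singleton_excess_is_negative(self):
        # 9 identical + 5 sequences each carrying one private variant
        base = "A" * 40
        seqs = {f"m{i}": base for i in range(9)}
        for i in range(5):
            seqs[f"x{i}"] = base[:i] + "T" + base[i + 1:]
        r = fu_li_f_star(AlignedSequenceSet(seqs))
        assert r.value < 0

    def test_intermediate_excess_is_positive(self):
        # two haplotypes at frequency 7/7 differing at 6 sites: no singletons
        a = "A" * 40
        b = "T" * 6 + "A" * 34
        seqs = {f"a{i}": a for i in range(7)} | {f"b{i}": b for i in range(7)}
        r = fu_li_f_star(AlignedSequenceSet(seqs))
        assert r.eta_s == 0 and r.value > 0


class TestFst:
    def test_identical_monomorphic_populations_degenerate_zero(self):
        a = aln("AAAA", "AAAA")
        b = AlignedSequenceSet({"t0": "AAAA", "t1": "AAAA"})
        r = fst_pair(a, b)
        assert r.fst == 0.0 and r.degenerate

    def test_fixed_difference_is_one(self):
        a = aln("AAAA", "AAAA")
        b = AlignedSequenceSet({"t0": "TTTT", "t1": "TTTT"})
        r = fst_pair(a, b)
        assert r.hw == 0.0 and r.hb == pytest.approx(4.0)
        assert r.fst == 1.0

    def test_worked_example_against_brute_force(self):
        a = aln("AAAA", "AAAT")
        b = AlignedSequenceSet({"t0": "TTTA", "t1": "TTTT"})
        r = fst_pair(a, b)
        # Hw = (1 + 1)/2 = 1; Hb = (3+4+4+3)/4 = 3.5
        assert r.hw == pytest.approx(1.0)
        assert r.hb == pytest.approx(3.5)
        assert r.fst == pytest.approx(1 - 1 / 3.5)

    def test_matrix_symmetry(self):
        rng = np.random.default_rng(2)
        groups = {}
        for g in "abc":
            groups[g] = AlignedSequenceSet({
                f"{g}{i}": "".join(rng.choice(list("ACGT"), size=30))
                for i in range(4)
            })
        labels, m = fst_matrix(groups)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_shared_ids_rejected(self):
        a = aln("AAAA", "AAAT")
        with pytest.raises(ValueError, match="share"):
            fst_pair(a, a)
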