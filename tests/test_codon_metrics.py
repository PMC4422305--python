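"""Codon-usage indices, checked against hand counts and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.cds_io import CodingSequence
from cubkit.codon_metrics import (
    CodonCountTable,
    aromo,
    cai,
    cai_weights,
    count_codons,
    enc,
    expected_enc,
    gc_partitions,
    gravy,
    rscu,
    silent_composition,
)
from cubkit.genetic_code import (
    ALL_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    SYN_FAMILIES,
)

from conftest import make_cds, random_count_table

# ---------------------------------------------------------------- oracles


def expand_to_codon_list(table):
    """Flatten a count table into an explicit list of codon strings."""
    out = []
    for c, n in table.counts.items():
        out.extend([c] * n)
    return out


def brute_rscu(table):
    codons = expand_to_codon_list(table)
    out = {}
    for aa, fam in SYN_FAMILIES.items():
        total = sum(1 for c in codons if c in fam)
        for c in fam:
            out[c] = (
                len(fam) * codons.count(c) / total if total else math.nan
            )
    return out


def brute_gc_partitions(table):
    codons = expand_to_codon_list(table)
    gc_by_pos = [
        sum(1 for c in codons if c[pos] in "GC") / len(codons) for pos in range(3)
    ]
    return (sum(gc_by_pos) / 3, *gc_by_pos, (gc_by_pos[0] + gc_by_pos[1]) / 2)


def brute_silent(table):
    codons = [
        c
        for c in expand_to_codon_list(table)
        if c in CODON_TO_AA and DEGENERACY[CODON_TO_AA[c]] > 1
    ]
    comp = {b: sum(1 for c in codons if c[2] == b) / len(codons) for b in "ACGT"}
    return (comp["C"] + comp["G"], comp["A"], comp["T"], comp["C"], comp["G"])


# ---------------------------------------------------------------- counting


class TestCountCodons:
    def test_terminal_stop_excluded(self):
        t = count_codons(CodingSequence("g1", "ATGAAATAA"))
        assert t.counts["ATG"] == 1 and t.counts["AAA"] == 1
        assert t.counts["TAA"] == 0
        assert t.n_codons == 2

    def test_pooling_doubles_counts(self):
        g = make_cds(["GCC", "GCA"] * 10)
        single = count_codons(g)
        pooled = count_codons([g, g])
        assert pooled.n_codons == 2 * single.n_codons
        assert all(pooled.counts[c] == 2 * single.counts[c] for c in ALL_CODONS)

    def test_non_multiple_of_3_raises(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            count_codons(CodingSequence("g1", "ATGAATA"))

    def test_table_addition_matches_pooling(self):
        a, b = make_cds(["GCC"] * 5), make_cds(["TTT"] * 5)
        assert count_codons(a) + count_codons(b) == count_codons([a, b])


# ---------------------------------------------------------------- RSCU


class TestRSCU:
    def test_published_ala_pool(self):
        # 4-fold family: RSCU = 4 * 818 / (288+818+133+575)
        t = CodonCountTable({"GCT": 288, "GCC": 818, "GCA": 133, "GCG": 575})
        assert rscu(t)["GCC"] == pytest.approx(4 * 818 / 1814)
        assert round(rscu(t)["GCC"], 2) == 1.80

    def test_published_arg_pool(self):
        t = CodonCountTable(
            {"CGT": 81, "CGC": 22, "CGA": 93, "CGG": 24, "AGA": 325, "AGG": 95}
        )
        assert round(rscu(t)["AGA"], 2) == 3.05

    def test_uniform_family_gives_one(self):
        t = CodonCountTable({c: 7 for c in SYN_FAMILIES["A"]})
        assert all(rscu(t)[c] == pytest.approx(1.0) for c in SYN_FAMILIES["A"])

    def test_met_trp_are_one_when_present(self):
        t = CodonCountTable({"ATG": 3, "TGG": 2})
        vals = rscu(t)
        assert vals["ATG"] == 1.0 and vals["TGG"] == 1.0

    def test_absent_family_is_nan(self):
        t = CodonCountTable({"AAA": 5})
        assert math.isnan(rscu(t)["GCC"])

    def test_stop_family_on_request(self):
        t = CodonCountTable({"TAA": 2, "TAG": 1, "TGA": 0, "AAA": 1})
        vals = rscu(t, include_stops=True)
        assert vals["TAA"] == pytest.approx(2.0)
        assert "TAA" not in rscu(t)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 200))
    def test_family_sums_equal_degeneracy(self, seed, n):
        table = random_count_table(np.random.default_rng(seed), n)
        vals = rscu(table)
        for aa in DEGENERATE_AAS:
            fam = SYN_FAMILIES[aa]
            if sum(table.counts[c] for c in fam) == 0:
                continue
            assert sum(vals[c] for c in fam) == pytest.approx(len(fam))

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = random_count_table(rng, 50)
            expected = brute_rscu(table)
            got = rscu(table)
            for c in expected:
                assert got[c] == pytest.approx(expected[c], nan_ok=True)


# ------------------------------------------------------- GC / silent sites


class TestGCPartitions:
    def test_all_gcg_gene(self):
        t = CodonCountTable({"GCG": 30})
        gc, gc1, gc2, gc3, gc12 = gc_partitions(t)
        assert gc == gc1 == gc2 == gc3 == gc12 == 1.0

    def test_hand_counted_two_codons(self):
        t = CodonCountTable({"ATG": 1, "AAA": 1})
        gc, gc1, gc2, gc3, gc12 = gc_partitions(t)
        assert (gc1, gc2, gc3, gc12) == (0.0, 0.0, 0.5, 0.0)
        assert gc == pytest.approx(0.5 / 3)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            gc_partitions(CodonCountTable())

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            table = random_count_table(rng, 50)
            assert gc_partitions(table) == pytest.approx(brute_gc_partitions(table))


class TestSilentComposition:
    def test_lys_only(self):
        gc3s, a3s, t3s, c3s, g3s = silent_composition(CodonCountTable({"AAA": 5}))
        assert (gc3s, a3s) == (0.0, 1.0)

    def test_met_only_undefined(self):
        with pytest.raises(ValueError, match="no synonymous"):
            silent_composition(CodonCountTable({"ATG": 7}))

    def test_two_ala_codons(self):
        gc3s, a3s, t3s, c3s, g3s = silent_composition(
            CodonCountTable({"GCC": 1, "GCA": 1})
        )
        assert (c3s, a3s, gc3s) == (0.5, 0.5, 0.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_simplex_constraint(self, seed):
        table = random_count_table(np.random.default_rng(seed), 60)
        try:
            gc3s, a3s, t3s, c3s, g3s = silent_composition(table)
        except ValueError:
            return
        assert a3s + t3s + c3s + g3s == pytest.approx(1.0, abs=1e-12)
        assert gc3s == pytest.approx(c3s + g3s, abs=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = random_count_table(rng, 50)
            assert silent_composition(table) == pytest.approx(brute_silent(table))

    def test_opportunity_method_differs_for_restricted_families(self):
        # Lys offers only A/G third bases: under per-opportunity denominators
        # its codons do not dilute the C3s denominator
        t = CodonCountTable({"AAA": 10, "GCC": 10})
        simple = silent_composition(t, method="simple")
        opp = silent_composition(t, method="opportunity")
        assert simple[3] == pytest.approx(0.5)  # c3s over all 20 codons
        assert opp[3] == pytest.approx(1.0)  # C only competes where offered


# ---------------------------------------------------------------- ENc


class TestENc:
    def test_one_codon_per_amino_acid_gives_20(self):
        counts = {SYN_FAMILIES[aa][0]: 5 for aa in DEGENERATE_AAS}
        assert enc(CodonCountTable(counts)) == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self):
        counts = {c: 300 for aa in DEGENERATE_AAS for c in SYN_FAMILIES[aa]}
        assert enc(CodonCountTable(counts)) == pytest.approx(61.0, abs=0.2)

    def test_uniform_synthetic_genes_mean_in_59_61(self, uniform_genes):
        mean_enc = np.mean([g.enc for g in uniform_genes])
        assert 59.0 <= mean_enc <= 61.0

    def test_two_fold_family_f_zero_excluded(self):
        # one codon each in a 2-fold family: F = (2*0.5 - 1)/1 = 0, which is
        # dropped from the class average rather than zeroing it
        counts = {SYN_FAMILIES[aa][0]: 5 for aa in DEGENERATE_AAS}
        counts["AAA"] = 1
        counts["AAG"] = 1
        biased = enc(CodonCountTable(counts))
        assert biased == pytest.approx(20.0)

    def test_f_zero_everywhere_in_class_undefined(self):
        # every 2-fold family split 1/1 -> whole class average missing
        counts = {}
        for aa in DEGENERATE_AAS:
            fam = SYN_FAMILIES[aa]
            if len(fam) == 2:
                counts[fam[0]] = 1
                counts[fam[1]] = 1
            else:
                counts[fam[0]] = 5
        assert math.isnan(enc(CodonCountTable(counts)))

    def test_missing_ile_imputed_from_neighbour_classes(self):
        counts = {
            SYN_FAMILIES[aa][0]: 5 for aa in DEGENERATE_AAS if DEGENERACY[aa] != 3
        }
        assert enc(CodonCountTable(counts)) == pytest.approx(20.0)

    def test_bounds_on_random_genes(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            v = enc(random_count_table(rng, 300))
            if not math.isnan(v):
                assert 20.0 <= v <= 61.0


class TestExpectedENc:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_reference_points(self, s, expected):
        assert expected_enc(s) == pytest.approx(expected)

    def test_matches_formula_on_grid(self):
        for s in np.linspace(0, 1, 11):
            direct = 2 + s + 29 / (s**2 + (1 - s) ** 2)
            assert expected_enc(s) == pytest.approx(direct)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            expected_enc(bad)


# ---------------------------------------------------------------- CAI


class TestCAI:
    def test_equal_reference_usage_gives_unit_weights(self):
        ref = CodonCountTable({c: 4 for c in SYN_FAMILIES["A"]})
        w = cai_weights(ref)
        assert all(w.w[c] == pytest.approx(1.0) for c in SYN_FAMILIES["A"])

    def test_nine_to_one_family(self):
        ref = CodonCountTable({"AAA": 9, "AAG": 1})
        w = cai_weights(ref)
        assert w.w["AAA"] == pytest.approx(1.0)
        assert w.w["AAG"] == pytest.approx(1 / 9)

    def test_absent_codon_gets_floor(self):
        ref = CodonCountTable({"AAA": 9})
        assert cai_weights(ref).w["AAG"] == 0.01

    def test_absent_family_floored_and_logged(self, caplog):
        ref = CodonCountTable({"AAA": 9})
        with caplog.at_level("WARNING"):
            w = cai_weights(ref)
        assert all(w.w[c] == 0.01 for c in SYN_FAMILIES["A"])
        assert "floor" in caplog.text

    def test_gene_of_maximal_codons_scores_one(self):
        ref = CodonCountTable({"AAA": 9, "AAG": 1, "GCC": 5, "GCA": 1})
        w = cai_weights(ref)
        gene = CodonCountTable({"AAA": 10, "GCC": 4})
        assert cai(gene, w) == pytest.approx(1.0)

    def test_geometric_mean_of_two_codons(self):
        w = cai_weights(CodonCountTable({"AAA": 4, "AAG": 1}))
        gene = CodonCountTable({"AAA": 1, "AAG": 1})
        assert cai(gene, w) == pytest.approx(math.sqrt(0.25))

    def test_invariant_to_table_duplication(self):
        w = cai_weights(CodonCountTable({"AAA": 4, "AAG": 1, "GCC": 3, "GCT": 1}))
        gene = CodonCountTable({"AAA": 3, "GCT": 2})
        doubled = gene + gene
        assert cai(gene, w) == pytest.approx(cai(doubled, w))

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(9)
        w = cai_weights(random_count_table(rng, 500))
        for _ in range(10):
            v = cai(random_count_table(rng, 60), w)
            assert v <= 1.0 + 1e-12

    def test_no_eligible_codons_is_nan(self):
        w = cai_weights(CodonCountTable({"AAA": 1}))
        assert math.isnan(cai(CodonCountTable({"ATG": 5}), w))


# ------------------------------------------------------- GRAVY / aromaticity


class TestTranslationIndices:
    def test_poly_arg_gravy(self):
        assert gravy(CodonCountTable({"CGT": 20})) == pytest.approx(-4.5)

    def test_poly_ile_gravy(self):
        assert gravy(CodonCountTable({"ATT": 20})) == pytest.approx(4.5)

    def test_equal_arg_ile_mix(self):
        assert gravy(CodonCountTable({"CGT": 10, "ATT": 10})) == pytest.approx(0.0)

    def test_poly_phe_aromo(self):
        assert aromo(CodonCountTable({"TTT": 15})) == pytest.approx(1.0)

    def test_poly_lys_aromo(self):
        assert aromo(CodonCountTable({"AAA": 15})) == pytest.approx(0.0)

    def test_one_trp_in_ten(self):
        assert aromo(CodonCountTable({"TGG": 1, "AAA": 9})) == pytest.approx(0.1)
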