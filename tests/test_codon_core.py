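"""Codon counting and per-gene usage indices."""

import math

import numpy as np
import pytest
from Bio.Data import CodonTable
from hypothesis import given, settings
from hypothesis import strategies as st

from codonscape import (
    CdsRecord,
    CodonCountTable,
    INFORMATIVE_CODONS,
    SYNONYMOUS_FAMILIES,
    aromaticity,
    build_cai_weights,
    cai,
    count_codons,
    enc,
    expected_enc,
    gc_by_position,
    gravy,
    pr2_coordinates,
    rscu,
)
from codonscape.codon_core import DEGENERACY_CLASSES, STANDARD_CODE, STOP_CODONS

from conftest import make_cds, one_codon_per_family, uniform_counts

# independent source for the code table: Biopython's standard table
_BIO = CodonTable.unambiguous_dna_by_id[1]


def biopython_families() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in _BIO.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    for aa in ("M", "W"):
        del fams[aa]
    return fams


def test_genetic_code_matches_biopython():
    assert set(STOP_CODONS) == set(_BIO.stop_codons)
    for codon, aa in _BIO.forward_table.items():
        assert STANDARD_CODE[codon] == aa
    fams = biopython_families()
    assert {aa: sorted(f) for aa, f in fams.items()} == {
        aa: sorted(f) for aa, f in SYNONYMOUS_FAMILIES.items()
    }
    # 9 two-fold, 1 three-fold (Ile), 5 four-fold, 3 six-fold; 59 codons total
    assert {k: len(v) for k, v in DEGENERACY_CLASSES.items()} == {2: 9, 3: 1, 4: 5, 6: 3}
    assert sum(k * len(v) for k, v in DEGENERACY_CLASSES.items()) == 59


class TestCounting:
    def test_basic_counts(self):
        t = count_codons(make_cds(["ATG", "AAA", "AAG", "TAA"]))
        assert t.counts == {"ATG": 1, "AAA": 1, "AAG": 1, "TAA": 1}
        assert t.n_codons == 3  # terminal stop excluded

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="no sense codons"):
            count_codons(make_cds(["TAA"]))
        with pytest.raises(ValueError, match="multiple of 3"):
            count_codons(CdsRecord("g", "ATGA"))

    def test_concatenation_additivity(self, rng):
        codons = [c for c in INFORMATIVE_CODONS]
        s1 = [codons[i] for i in rng.integers(0, 59, 30)]
        s2 = [codons[i] for i in rng.integers(0, 59, 40)]
        combined = count_codons(make_cds(s1 + s2))
        summed = count_codons(make_cds(s1)) + count_codons(make_cds(s2))
        assert combined.counts == summed.counts


class TestGcByPosition:
    @pytest.mark.parametrize(
        "codons, expect",
        [
            (["GCG"] * 5, (1.0, 1.0, 1.0)),
            (["AAA"] * 5, (0.0, 0.0, 0.0)),
            (["GCG", "ATA"] * 3, (0.5, 0.5, 0.5)),
        ],
    )
    def test_hand_counts(self, codons, expect):
        _, gc1, gc2, gc3, _ = gc_by_position(count_codons(make_cds(codons)))
        assert (gc1, gc2, gc3) == expect

    def test_gc3s_excludes_invariant_third_positions(self):
        # ATG (G) and TGG (G) inflate gc3 but must not touch gc3s
        t = count_codons(make_cds(["ATG", "TGG", "AAA", "AAA"]))
        _, _, _, gc3, gc3s = gc_by_position(t)
        assert gc3 == 0.5
        assert gc3s == 0.0


class TestRscu:
    def test_uniform_usage_is_neutral(self):
        values = rscu(uniform_counts())
        assert all(math.isclose(v, 1.0) for v in values.values())

    def test_lysine_example(self):
        t = CodonCountTable("g", {"AAA": 3, "AAG": 1})
        values = rscu(t)
        assert values["AAA"] == pytest.approx(1.5)
        assert values["AAG"] == pytest.approx(0.5)

    def test_missing_family_reported_missing(self):
        values = rscu(CodonCountTable("g", {"AAA": 2}))
        assert math.isnan(values["GCT"])  # Ala unobserved

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_degeneracy(self, seed):
        rng = np.random.default_rng(seed)
        counts = {
            c: int(rng.integers(0, 30))
            for fam in SYNONYMOUS_FAMILIES.values()
            for c in fam
        }
        t = CodonCountTable("g", counts)
        if t.n_codons == 0:
            return
        values = rscu(t)
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            total = sum(counts[c] for c in fam)
            s = sum(values[c] for c in fam)
            if total == 0:
                assert all(math.isnan(values[c]) for c in fam)
            else:
                assert s == pytest.approx(len(fam))

    def test_oracle_equivalence_random_genes(self, rng):
        """RSCU matches a dictionary-enumeration brute force on random genes."""
        fams = biopython_families()
        codons = sorted(set(STANDARD_CODE) - STOP_CODONS)
        for _ in range(100):
            gene = [codons[i] for i in rng.integers(0, len(codons), 60)]
            mine = rscu(count_codons(make_cds(gene)))
            for aa, fam in fams.items():
                xs = {c: gene.count(c) for c in fam}
                tot = sum(xs.values())
                for c in fam:
                    if tot == 0:
                        assert math.isnan(mine[c])
                    else:
                        assert mine[c] == pytest.approx(xs[c] / (tot / len(fam)))


class TestEnc:
    def test_minimum_one_codon_per_family(self):
        clamped, raw = enc(one_codon_per_family())
        assert clamped == 20.0
        assert raw == pytest.approx(20.0)

    def test_maximum_uniform_usage(self):
        clamped, raw = enc(uniform_counts(copies=20))
        assert clamped == 61.0
        assert raw > 61.0  # finite-count F underestimates 1/k; clamp applies

    def test_f_statistic_hand_value(self):
        # single 2-fold family, counts (3, 1): F = (4 * 0.625 - 1) / 3 = 0.5
        n, sum_p2 = 4, 0.75**2 + 0.25**2
        assert (n * sum_p2 - 1) / (n - 1) == pytest.approx(0.5)
        # the same family alone leaves other classes undefined except via
        # Wright's 3-fold imputation, so ENC is missing
        clamped, _ = enc(CodonCountTable("g", {"AAA": 3, "AAG": 1}))
        assert math.isnan(clamped)

    def test_oracle_equivalence_random_genes(self, rng):
        """ENC matches an independently coded Wright formula on random genes."""
        fams = biopython_families()
        codons = sorted(set(STANDARD_CODE) - STOP_CODONS)
        checked = 0
        for _ in range(100):
            gene = [codons[i] for i in rng.integers(0, len(codons), 120)]
            mine, _ = enc(count_codons(make_cds(gene)))
            f_sums: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
            for aa, fam in fams.items():
                ns = [gene.count(c) for c in fam]
                n = sum(ns)
                if n <= 1:
                    continue
                f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
                if f > 0:
                    f_sums[len(fam)].append(f)
            if not all(f_sums[k] for k in (2, 4, 6)):
                continue
            fm = {k: sum(v) / len(v) for k, v in f_sums.items() if v}
            if 3 not in fm:
                fm[3] = (fm[2] + fm[4]) / 2
            expected = 2 + 9 / fm[2] + 1 / fm[3] + 5 / fm[4] + 3 / fm[6]
            assert mine == pytest.approx(min(max(expected, 20), 61))
            checked += 1
        assert checked > 90

    def test_skew_decreases_enc(self):
        """Making one 2-fold family more skewed lowers ENC."""

        def gene_with_lys_split(a: int, g: int) -> CodonCountTable:
            base = {fam[0]: 30 for fam in SYNONYMOUS_FAMILIES.values()}
            base.update({fam[1]: 30 for fam in SYNONYMOUS_FAMILIES.values()})
            base["AAA"], base["AAG"] = a, g
            return CodonCountTable("g", base)

        values = [enc(gene_with_lys_split(30 + d, 30 - d))[0] for d in (0, 10, 20, 30)]
        assert values == sorted(values, reverse=True)

    def test_range_on_simulated_genes(self, mutation_indices):
        encs = np.array([ix.enc_obs for ix in mutation_indices])
        encs = encs[~np.isnan(encs)]
        assert ((encs >= 20) & (encs <= 61)).all()


class TestExpectedEnc:
    @pytest.mark.parametrize("s, value", [(0.5, 60.5), (1.0, 32.0), (0.0, 31.0)])
    def test_direct_values(self, s, value):
        assert expected_enc(s) == pytest.approx(value)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.0, 1.0))
    def test_symmetry_up_to_linear_term(self, s):
        assert expected_enc(s) - s == pytest.approx(expected_enc(1 - s) - (1 - s))

    def test_domain(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)


class TestProteinIndices:
    @pytest.mark.parametrize("protein, value", [("I", 4.5), ("R", -4.5), ("IR", 0.0)])
    def test_gravy(self, protein, value):
        assert gravy(protein) == pytest.approx(value)

    @pytest.mark.parametrize("protein, value", [("FYW", 1.0), ("FAAA", 0.25), ("AAAA", 0.0)])
    def test_aromaticity(self, protein, value):
        assert aromaticity(protein) == pytest.approx(value)

    def test_errors(self):
        for fn in (gravy, aromaticity):
            with pytest.raises(ValueError):
                fn("")
            with pytest.raises(ValueError):
                fn("AXA")


class TestCai:
    def test_weight_construction(self):
        ref = [CodonCountTable("r", {"AAA": 8, "AAG": 2})]
        w = build_cai_weights(ref)
        assert w["AAA"] == 1.0
        assert w["AAG"] == pytest.approx(0.25)
        # unobserved family -> uninformative weights of 1
        assert w["GCT"] == 1.0

    def test_uniform_reference_gives_unit_weights(self):
        w = build_cai_weights([uniform_counts()])
        assert all(v == 1.0 for v in w.values())

    def test_zero_counts_floored(self):
        w = build_cai_weights([CodonCountTable("r", {"AAA": 10})])
        assert w["AAG"] == pytest.approx(0.05)  # 0.5 / 10

    def test_geometric_mean(self):
        w = {c: 1.0 for fam in SYNONYMOUS_FAMILIES.values() for c in fam}
        w["AAG"] = 0.25
        t = CodonCountTable("g", {"AAA": 1, "AAG": 1})
        assert cai(t, w) == pytest.approx(0.5)
        assert cai(CodonCountTable("g", {"AAA": 5}), w) == 1.0

    def test_monotone_in_weight_substitution(self):
        ref = [CodonCountTable("r", {"AAA": 8, "AAG": 2, "GCT": 4, "GCC": 1})]
        w = build_cai_weights(ref)
        lower = cai(CodonCountTable("g", {"AAG": 3, "GCC": 2}), w)
        higher = cai(CodonCountTable("g", {"AAA": 3, "GCT": 2}), w)
        assert higher >= lower


class TestPr2:
    def test_parity_point(self):
        t = count_codons(make_cds(["GCA", "GCT", "GCG", "GCC"] * 3))
        assert pr2_coordinates(t) == pytest.approx((0.5, 0.5))

    def test_pure_ag_usage(self):
        t = count_codons(make_cds(["GCA", "GCG"] * 4))
        x, y = pr2_coordinates(t)
        assert x == 1.0 and y == 1.0

    def test_restricted_to_fourfold_families(self):
        # Lys codons are 2-fold: alone they leave PR2 undefined
        with pytest.raises(ValueError):
            pr2_coordinates(count_codons(make_cds(["AAA", "AAG"])))
        # adding them must not move the coordinates
        base = ["GCA", "GCT", "GCG", "GCC"]
        with_lys = base + ["AAA"] * 10
        assert pr2_coordinates(count_codons(make_cds(base))) == pr2_coordinates(
            count_codons(make_cds(with_lys))
        )

    def test_mutation_regime_clusters_at_parity(self, mutation_dataset):
        from codonscape import count_codons as cc, pool_counts

        pooled = pool_counts([cc(r) for r in mutation_dataset.records])
        x, y = pr2_coordinates(pooled)
        assert abs(x - 0.5) < 0.02
        assert abs(y - 0.5) < 0.02
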