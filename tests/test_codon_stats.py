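"""Codon statistics: counting, GC, RSCU, ENC, aggregation, neutrality, CA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonclim.climate_correlation import pearson_pvalue
from codonclim.codon_stats import (
    AMINO_ACIDS,
    CODON_INDEX,
    CODONS,
    STANDARD_CODE,
    aggregate_sample_features,
    amino_acid_fractions,
    correspondence_analysis,
    count_codons,
    enc,
    expected_enc,
    family_homozygosity,
    gc_by_position,
    neutrality_regression,
    per_gene_table,
    rscu,
    strong_bias_genes,
)

from conftest import counts_to_dict, random_codon_counts, wright_enc_reference


def vec(**codons) -> np.ndarray:
    v = np.zeros(64, dtype=np.int64)
    for codon, n in codons.items():
        v[CODON_INDEX[codon]] = n
    return v


class TestGeneticCode:
    def test_family_size_multiset(self):
        sizes = sorted(len(v) for v in STANDARD_CODE.families.values())
        assert sizes == [1, 1, 2, 2, 2, 2, 2, 2, 2, 2, 2, 3, 4, 4, 4, 4, 4, 6, 6, 6]
        assert len(STANDARD_CODE.stop_codons) == 3
        assert len(STANDARD_CODE.codon_to_aa) == 61


class TestCountCodons:
    @pytest.mark.parametrize(
        "seq,expected,stops,skipped",
        [
            ("ATGGCTTAA", {"ATG": 1, "GCT": 1}, {"TAA": 1}, 0),
            ("ATGNNTGCT", {"ATG": 1, "GCT": 1}, {}, 1),
            ("ATGGC", {"ATG": 1}, {}, 1),  # trailing partial triplet
            ("auggcu", {"ATG": 1, "GCT": 1}, {}, 0),  # RNA, lower case
            ("", {}, {}, 0),
        ],
    )
    def test_frame_and_ambiguity_rules(self, seq, expected, stops, skipped):
        counts, n_skipped = count_codons(seq)
        observed = counts_to_dict(counts)
        assert observed == {**expected, **stops}
        assert n_skipped == skipped


class TestGCByPosition:
    def test_all_gc_codon(self):
        gc = gc_by_position(vec(GCG=2))
        assert (gc.gc1, gc.gc2, gc.gc3, gc.gc12) == (1.0, 1.0, 1.0, 1.0)

    def test_atg(self):
        gc = gc_by_position(vec(ATG=1))
        assert (gc.gc1, gc.gc2, gc.gc3, gc.gc12) == (0.0, 0.0, 1.0, 0.0)

    def test_two_codon_hand_count(self):
        gc = gc_by_position(vec(ATG=1, GCT=1))
        assert (gc.gc1, gc.gc2, gc.gc3, gc.gc12) == (0.5, 0.5, 0.5, 0.5)

    def test_stop_codons_excluded(self):
        with_stop = gc_by_position(vec(ATG=1, GCT=1, TAA=5))
        without = gc_by_position(vec(ATG=1, GCT=1))
        assert with_stop == without

    def test_zero_codons_undefined(self):
        assert all(math.isnan(x) for x in gc_by_position(np.zeros(64, dtype=int)))


class TestRSCU:
    def test_glycine_worked_family(self):
        values = rscu(vec(GGA=3, GGC=1))
        assert values[CODON_INDEX["GGA"]] == pytest.approx(3.0)
        assert values[CODON_INDEX["GGC"]] == pytest.approx(1.0)
        assert values[CODON_INDEX["GGG"]] == pytest.approx(0.0)
        assert values[CODON_INDEX["GGT"]] == pytest.approx(0.0)

    def test_uniform_usage_gives_all_ones(self):
        counts = np.zeros(64, dtype=np.int64)
        for codons in STANDARD_CODE.families.values():
            for c in codons:
                counts[CODON_INDEX[c]] = 7
        values = rscu(counts)
        sense = [CODON_INDEX[c] for c in STANDARD_CODE.codon_to_aa]
        assert np.allclose(values[sense], 1.0)

    def test_absent_family_undefined_not_zero(self):
        values = rscu(vec(ATG=5))  # glycine family absent
        for c in STANDARD_CODE.families["G"]:
            assert math.isnan(values[CODON_INDEX[c]])
        assert values[CODON_INDEX["ATG"]] == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sum_equals_degeneracy(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_codon_counts(rng)
        values = rscu(counts)
        for aa, codons in STANDARD_CODE.families.items():
            idx = [CODON_INDEX[c] for c in codons]
            if counts[idx].sum() > 0:
                assert np.nansum(values[idx]) == pytest.approx(len(codons), abs=1e-9)
            else:
                assert np.isnan(values[idx]).all()


class TestENC:
    def test_family_homozygosity_worked(self):
        assert family_homozygosity([3, 1]) == pytest.approx(0.5)
        assert family_homozygosity([5, 0]) == pytest.approx(1.0)
        assert math.isnan(family_homozygosity([1, 0]))

    def test_family_homozygosity_floor(self):
        # (1,1,1,1): F-hat = (4*0.25-1)/3 = 0 -> clamped to 1/4
        assert family_homozygosity([1, 1, 1, 1]) == pytest.approx(0.25)

    def test_maximal_bias_gives_20(self):
        counts = np.zeros(64, dtype=np.int64)
        for codons in STANDARD_CODE.families.values():
            counts[CODON_INDEX[codons[0]]] = 50
        assert enc(counts) == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self):
        counts = np.zeros(64, dtype=np.int64)
        for codons in STANDARD_CODE.families.values():
            for c in codons:
                counts[CODON_INDEX[c]] = 500
        assert enc(counts) == pytest.approx(61.0, abs=0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            counts = random_codon_counts(rng)
            expected = wright_enc_reference(counts_to_dict(counts))
            observed = enc(counts)
            if math.isnan(expected):
                assert math.isnan(observed)
            else:
                assert observed == pytest.approx(expected, abs=1e-9)

    def test_undefined_when_fourfold_class_absent(self):
        # only two-fold and six-fold families counted
        counts = vec(TTT=3, TTC=2, CTT=4, CTC=1)
        assert math.isnan(enc(counts))

    def test_duplication_near_invariance_at_large_n(self, rng):
        counts = rng.integers(20, 60, size=64).astype(np.int64)
        counts *= 30  # n >= 1000 per family
        assert enc(counts * 2) == pytest.approx(enc(counts), abs=0.1)


class TestExpectedENC:
    @pytest.mark.parametrize("gc3,value", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_printed_formula_values(self, gc3, value):
        assert expected_enc(gc3) == pytest.approx(value)

    def test_symmetric_with_maximum_at_half(self):
        for s in np.linspace(0.0, 0.5, 11):
            assert expected_enc(s) - s == pytest.approx(expected_enc(1 - s) - (1 - s))
            assert expected_enc(s) <= 60.5 + 1e-12

    def test_domain_error(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)


class TestAminoAcidFractions:
    def test_met_trp_only(self):
        frac = amino_acid_fractions(vec(ATG=2, TGG=2))
        d = dict(zip(AMINO_ACIDS, frac))
        assert d["M"] == pytest.approx(0.5)
        assert d["W"] == pytest.approx(0.5)
        assert sum(d.values()) == pytest.approx(1.0)

    def test_hand_count(self):
        frac = amino_acid_fractions(vec(GCT=1, GCC=1, GGA=2))
        d = dict(zip(AMINO_ACIDS, frac))
        assert d["A"] == pytest.approx(0.5)
        assert d["G"] == pytest.approx(0.5)

    def test_sums_to_one(self, rng):
        for _ in range(20):
            counts = random_codon_counts(rng)
            if counts.sum() > 0:
                assert np.nansum(amino_acid_fractions(counts)) == pytest.approx(1.0)


class TestStrongBias:
    def test_boundary_inclusive(self):
        stats = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "enc": [20.0, 35.0, 35.01, 61.0]}
        )
        assert strong_bias_genes(stats) == ["a", "b"]
        assert strong_bias_genes(stats, threshold=61) == ["a", "b", "c", "d"]

    def test_all_undefined_gives_empty(self):
        stats = pd.DataFrame({"gene_id": ["a"], "enc": [float("nan")]})
        assert strong_bias_genes(stats) == []


class TestAggregateSampleFeatures:
    def test_mean_of_two_genes(self):
        records = {"g1": "GCTGCTGCTGCT", "g2": "ATTATTATTATT"}
        stats, counts = per_gene_table(records)
        feat = aggregate_sample_features("s1", "all", stats, counts)
        assert feat.mean_gc12 == pytest.approx(stats["gc12"].mean())
        assert feat.n_genes == 2
        assert feat.aa_usage.sum() == pytest.approx(100.0)

    def test_single_gene_identity(self):
        records = {"g1": "ATGGCTGGATTT"}
        stats, counts = per_gene_table(records)
        feat = aggregate_sample_features("s1", "all", stats, counts)
        assert feat.mean_gc3 == pytest.approx(stats["gc3"].iloc[0])
        assert feat.mean_gc12 == pytest.approx(stats["gc12"].iloc[0])

    def test_pooled_counts_differ_from_mean_of_fractions(self):
        # length-heterogeneous toy: g1 = 1 Ala codon, g2 = 3 Gly codons
        records = {"g1": "GCT", "g2": "GGAGGAGGA"}
        stats, counts = per_gene_table(records)
        feat = aggregate_sample_features("s1", "all", stats, counts)
        # pooled: Ala 1/4, Gly 3/4 (mean-of-fractions would be 50/50)
        assert feat.aa_usage["A"] == pytest.approx(25.0)
        assert feat.aa_usage["G"] == pytest.approx(75.0)

    def test_gene_subset_selection(self):
        records = {"g1": "GCTGCT", "g2": "GGAGGA"}
        stats, counts = per_gene_table(records)
        feat = aggregate_sample_features(
            "s1", "single_copy_orthologue", stats, counts, gene_ids=["g1"]
        )
        assert feat.n_genes == 1
        assert feat.aa_usage["A"] == pytest.approx(100.0)

    def test_empty_gene_set_error(self):
        records = {"g1": "GCTGCT"}
        stats, counts = per_gene_table(records)
        with pytest.raises(ValueError, match="s1"):
            aggregate_sample_features("s1", "other", stats, counts, gene_ids=[])

    def test_rscu_family_sums_from_pooled_counts(self):
        records = {"g1": "GGAGGAGGAGGC", "g2": "GGTGGG"}
        stats, counts = per_gene_table(records)
        feat = aggregate_sample_features("s1", "all", stats, counts)
        gly = feat.rscu[list(STANDARD_CODE.families["G"])]
        assert gly.sum() == pytest.approx(4.0)


class TestNeutralityRegression:
    def test_identity_line(self):
        x = np.linspace(0.3, 0.7, 10)
        fit = neutrality_regression(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_printed_p_consistent_with_rounded_r(self):
        # the published p (1.64e-5 at n = 27) must be reachable from some r
        # that rounds to the published 0.73
        p_lo = pearson_pvalue(0.735, 27)
        p_hi = pearson_pvalue(0.725, 27)
        assert p_lo < 1.64e-5 < p_hi

    def test_null_p_uniform(self, rng):
        pvals = []
        for _ in range(300):
            x = rng.normal(size=27)
            y = rng.normal(size=27)
            pvals.append(neutrality_regression(x, y).p)
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 1e-3

    def test_degenerate_variance_error(self):
        with pytest.raises(ValueError, match="constant"):
            neutrality_regression([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


class TestCorrespondenceAnalysis:
    def test_rank_one_table_has_zero_inertia(self):
        row = np.array([1.0, 2.0, 3.0, 4.0])
        table = pd.DataFrame(np.outer([1, 2, 5], row))
        ca = correspondence_analysis(table)
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_chi_square_identity(self, rng):
        from conftest import chi_square_over_n_reference

        for _ in range(20):
            table = pd.DataFrame(rng.integers(1, 40, size=(5, 8)).astype(float))
            ca = correspondence_analysis(table)
            assert ca.total_inertia == pytest.approx(
                chi_square_over_n_reference(table.to_numpy()), abs=1e-8
            )

    def test_principal_coordinates_match_eigendecomposition(self, rng):
        # independent route: eigen-decompose S S^T instead of the SVD
        table = pd.DataFrame(rng.integers(1, 30, size=(3, 4)).astype(float))
        X = table.to_numpy()
        P = X / X.sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        eigval, eigvec = np.linalg.eigh(S @ S.T)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        ca = correspondence_analysis(table)
        k = len(ca.inertia)
        assert np.allclose(np.sort(ca.inertia)[::-1], eigval[:k], atol=1e-10)
        for j in range(k):
            if eigval[j] < 1e-12:
                continue
            expected = eigvec[:, j] * np.sqrt(eigval[j]) / np.sqrt(r)
            observed = ca.row_coords.iloc[:, j].to_numpy()
            agree = np.allclose(observed, expected, atol=1e-8)
            flipped = np.allclose(observed, -expected, atol=1e-8)
            assert agree or flipped

    def test_all_zero_column_rejected(self):
        table = pd.DataFrame([[1.0, 0.0], [2.0, 0.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            correspondence_analysis(table)
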