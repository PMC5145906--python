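"""Allele frequencies and the SH / IR / HL heterozygosity estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedavoid import (
    GenotypeTable,
    allele_frequencies,
    estimate_all,
    homozygosity_by_loci,
    internal_relatedness,
    standardized_heterozygosity,
)
from pedavoid.estimators import GenotypeError


def table_from(rows, loci):
    """rows: {id: [(a, b) or None, ...]} in locus order."""
    cols = {}
    for k, locus in enumerate(loci):
        cols[f"{locus}.1"] = [rows[i][k][0] if rows[i][k] else np.nan
                              for i in rows]
        cols[f"{locus}.2"] = [rows[i][k][1] if rows[i][k] else np.nan
                              for i in rows]
    return GenotypeTable.from_wide(pd.DataFrame(cols, index=list(rows)))


class TestAlleleFrequencies:
    def test_direct_counting(self):
        g = table_from({"x": [("A", "A")], "y": [("A", "B")]}, ["L1"])
        freqs = allele_frequencies(g)
        lf = freqs["L1"]
        assert lf.frequencies["A"] == 0.75
        assert lf.frequencies["B"] == 0.25
        assert lf.h_obs == 0.5
        assert lf.h_exp == pytest.approx(0.375)

    def test_missing_genotypes_excluded_from_counts(self):
        g = table_from({"x": [("A", "A")], "y": [None]}, ["L1"])
        lf = allele_frequencies(g)["L1"]
        assert lf.n_typed == 1
        assert lf.frequencies["A"] == 1.0

    def test_monomorphic_locus(self):
        g = table_from({"x": [("A", "A")], "y": [("A", "A")]}, ["L1"])
        lf = allele_frequencies(g)["L1"]
        assert lf.h_exp == 0.0 and lf.h_obs == 0.0

    def test_untyped_locus_dropped_with_warning(self):
        g = table_from({"x": [("A", "A"), None], "y": [("A", "B"), None]},
                       ["L1", "L2"])
        with pytest.warns(UserWarning, match="L2"):
            freqs = allele_frequencies(g)
        assert "L2" not in freqs

    def test_empty_table_is_an_error(self):
        with pytest.raises(GenotypeError):
            allele_frequencies(GenotypeTable(individuals=[], loci=[], data={}))

    def test_half_call_rejected(self):
        df = pd.DataFrame({"L1.1": ["A"], "L1.2": [np.nan]}, index=["x"])
        with pytest.raises(GenotypeError, match="half"):
            GenotypeTable.from_wide(df)


class TestStandardizedHeterozygosity:
    def test_het_at_half_of_loci_with_hobs_half_gives_one(self):
        # four loci, population H_obs = 0.5 at each; focal het at 2 of 4
        rows = {
            "f": [("A", "B"), ("A", "B"), ("A", "A"), ("A", "A")],
            "o": [("A", "A"), ("A", "A"), ("A", "B"), ("A", "B")],
        }
        g = table_from(rows, ["L1", "L2", "L3", "L4"])
        freqs = allele_frequencies(g)
        assert standardized_heterozygosity("f", g, freqs) == pytest.approx(1.0)

    def test_all_homozygous_gives_zero(self):
        rows = {"f": [("A", "A"), ("B", "B")],
                "o": [("A", "B"), ("A", "B")]}
        g = table_from(rows, ["L1", "L2"])
        freqs = allele_frequencies(g)
        assert standardized_heterozygosity("f", g, freqs) == 0.0

    def test_fully_heterozygous_against_mean_hobs(self):
        # population H_obs 0.8 on average over the focal's typed loci
        freqs = allele_frequencies(table_from(
            {f"i{k}": [("A", "B")] if k < 4 else [("A", "A")]
             for k in range(5)}, ["L1"]))
        assert freqs["L1"].h_obs == 0.8
        g = table_from({"f": [("A", "B")]}, ["L1"])
        assert standardized_heterozygosity("f", g, freqs) \
            == pytest.approx(1 / 0.8)

    def test_all_monomorphic_denominator_undefined(self):
        rows = {"f": [("A", "A")], "o": [("A", "A")]}
        g = table_from(rows, ["L1"])
        freqs = allele_frequencies(g)
        assert np.isnan(standardized_heterozygosity("f", g, freqs))


class TestInternalRelatedness:
    def test_all_homozygous_is_one_regardless_of_frequencies(self):
        rows = {"f": [("A", "A"), ("C", "C")],
                "o": [("A", "B"), ("C", "D")]}
        g = table_from(rows, ["L1", "L2"])
        freqs = allele_frequencies(g)
        assert internal_relatedness("f", g, freqs) == pytest.approx(1.0)

    def test_single_het_locus_with_even_frequencies_is_minus_one(self):
        g = table_from({"f": [("A", "B")], "o": [("A", "B")]}, ["L1"])
        freqs = allele_frequencies(g)
        assert internal_relatedness("f", g, freqs) == pytest.approx(-1.0)

    def test_two_locus_worked_example(self):
        # hom for an allele at freq 0.5; het with two freq-0.25 alleles:
        # IR = (2 - 1.5) / (4 - 1.5) = 0.2
        g = table_from({
            "f": [("A", "A"), ("C", "D")],
            "x": [("A", "B"), ("C", "E")],
            "y": [("B", "B"), ("D", "E")],
            "z": [("A", "B"), ("E", "E")],
        }, ["L1", "L2"])
        freqs = allele_frequencies(g)
        assert freqs["L1"].frequencies["A"] == 0.5
        assert freqs["L2"].frequencies["C"] == 0.25
        assert freqs["L2"].frequencies["D"] == 0.25
        assert internal_relatedness("f", g, freqs) == pytest.approx(0.2)


class TestHomozygosityByLoci:
    def test_all_homozygous_is_one(self):
        rows = {"f": [("A", "A"), ("C", "C")],
                "o": [("A", "B"), ("C", "D")]}
        g = table_from(rows, ["L1", "L2"])
        freqs = allele_frequencies(g)
        assert homozygosity_by_loci("f", g, freqs) == 1.0

    def test_all_heterozygous_is_zero(self):
        rows = {"f": [("A", "B"), ("C", "D")],
                "o": [("A", "A"), ("C", "C")]}
        g = table_from(rows, ["L1", "L2"])
        freqs = allele_frequencies(g)
        assert homozygosity_by_loci("f", g, freqs) == 0.0

    def test_equal_diversity_split(self):
        # two loci with the same expected heterozygosity, one hom one het
        g = table_from({
            "f": [("A", "A"), ("C", "D")],
            "x": [("A", "B"), ("C", "C")],
            "y": [("B", "A"), ("D", "D")],
            "z": [("B", "B"), ("D", "C")],
        }, ["L1", "L2"])
        freqs = allele_frequencies(g)
        assert freqs["L1"].h_exp == pytest.approx(freqs["L2"].h_exp)
        assert homozygosity_by_loci("f", g, freqs) == pytest.approx(0.5)


class TestEstimateAll:
    def test_correlation_signs_on_simulated_population(
            self, sim_population_genotyped):
        est = estimate_all(sim_population_genotyped.genotypes, min_loci=10)
        assert est.correlations[("HL", "SH")] < 0
        assert est.correlations[("IR", "SH")] < 0
        assert est.correlations[("HL", "IR")] > 0

    def test_single_individual_correlations_undefined(self):
        g = table_from({"f": [("A", "B")]}, ["L1"])
        est = estimate_all(g, min_loci=1)
        assert all(np.isnan(v) for v in est.correlations.values())

    def test_identical_genotypes_zero_variance_undefined(self):
        g = table_from({f"i{k}": [("A", "B"), ("C", "C")] for k in range(5)},
                       ["L1", "L2"])
        est = estimate_all(g, min_loci=1)
        assert all(np.isnan(v) for v in est.correlations.values())

    def test_min_loci_filter_keeps_rows_with_nan(self):
        g = table_from({"f": [("A", "B"), None], "o": [("A", "A"), ("C", "D")]},
                       ["L1", "L2"])
        est = estimate_all(g, min_loci=2)
        assert np.isnan(est.table.loc["f", "SH"])
        assert not np.isnan(est.table.loc["o", "SH"])
        assert est.table.loc["f", "n_loci"] == 1

    def test_summary_mentions_correlations(self, sim_population_genotyped):
        est = estimate_all(sim_population_genotyped.genotypes, min_loci=10)
        assert "HL ~ SH" in est.summary()


@st.composite
def genotype_tables(draw):
    n_ind = draw(st.integers(2, 6))
    n_loci = draw(st.integers(1, 5))
    alleles = "ABCD"
    rows = {}
    for i in range(n_ind):
        genos = []
        for _ in range(n_loci):
            if draw(st.booleans()) or i == 0:  # individual 0 fully typed
                a = draw(st.sampled_from(alleles))
                b = draw(st.sampled_from(alleles))
                genos.append((a, b))
            else:
                genos.append(None)
        rows[f"i{i}"] = genos
    return rows, [f"L{k}" for k in range(n_loci)]


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(genotype_tables())
    def test_bounds(self, table_spec):
        rows, loci = table_spec
        g = table_from(rows, loci)
        freqs = allele_frequencies(g)
        for ind in rows:
            sh = standardized_heterozygosity(ind, g, freqs)
            ir = internal_relatedness(ind, g, freqs)
            hl = homozygosity_by_loci(ind, g, freqs)
            if not np.isnan(sh):
                assert sh >= 0
            if not np.isnan(ir):
                assert -1 - 1e-12 <= ir <= 1 + 1e-12
            if not np.isnan(hl):
                assert 0 <= hl <= 1

    def test_locus_order_invariance(self, sim_population_genotyped):
        g = sim_population_genotyped.genotypes
        wide = g.to_wide()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(g.loci))
        cols = []
        for k in perm:
            cols += [f"{g.loci[k]}.1", f"{g.loci[k]}.2"]
        g2 = GenotypeTable.from_wide(wide[cols])
        a = estimate_all(g, min_loci=1).table
        b = estimate_all(g2, min_loci=1).table
        pd.testing.assert_frame_equal(a[["SH", "IR", "HL"]],
                                      b[["SH", "IR", "HL"]])

    def test_estimators_track_pedigree_F_directionally(
            self, sim_population_genotyped):
        from scipy import stats
        sim = sim_population_genotyped
        est = estimate_all(sim.genotypes, min_loci=1)
        joined = est.table.join(sim.true_F).dropna()
        assert (joined["F"] > 0).sum() >= 5  # inbred lineages present
        assert stats.spearmanr(joined["F"], joined["HL"]).statistic > 0
        assert stats.spearmanr(joined["F"], joined["IR"]).statistic > 0
        assert stats.spearmanr(joined["F"], joined["SH"]).statistic < 0
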