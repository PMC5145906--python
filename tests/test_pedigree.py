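"""Pedigree construction, kinship recursion, depth truncation,
classification and the gene-dropping oracle."""

import numpy as np
import pytest

from pedavoid import PedigreeError, build_pedigree, prevalence_summary
from pedavoid import examples as ex
from tests.conftest import random_pedigree


def trio():
    return [
        dict(id="S", sex="M"),
        dict(id="D", sex="F"),
        dict(id="O", sire="S", dam="D", sex="F"),
    ]


class TestBuildAndValidate:
    def test_minimal_pedigree_no_stubs(self):
        ped = build_pedigree(trio())
        assert len(ped) == 3
        assert ped.report.n_stubs == 0

    def test_referenced_absent_parent_becomes_flagged_stub(self):
        ped = build_pedigree([dict(id="O", sire="S", dam="D", sex="F")])
        assert len(ped) == 3
        assert ped.report.n_stubs == 2
        assert ped["S"].is_stub and ped["D"].is_stub

    def test_self_parent_is_an_error_naming_the_individual(self):
        with pytest.raises(PedigreeError, match="A"):
            build_pedigree([dict(id="A", sire="A", dam=None, sex="M")])

    def test_two_cycle_is_detected(self):
        rows = [dict(id="A", sire="B", dam=None, sex="M"),
                dict(id="B", sire="A", dam=None, sex="M")]
        with pytest.raises(PedigreeError, match="cycle"):
            build_pedigree(rows)

    def test_known_female_sire_is_an_error(self):
        rows = [dict(id="X", sex="F"), dict(id="D", sex="F"),
                dict(id="O", sire="X", dam="D", sex="M")]
        with pytest.raises(PedigreeError, match="X"):
            build_pedigree(rows)

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            build_pedigree([dict(id="A", sex="M"), dict(id="A", sex="F")])

    def test_parent_born_after_offspring_warns_or_errors(self):
        import datetime as dt
        rows = [dict(id="P", sex="M", birth_date=dt.date(2010, 1, 1)),
                dict(id="D", sex="F"),
                dict(id="O", sire="P", dam="D", sex="F",
                     birth_date=dt.date(2005, 1, 1))]
        ped = build_pedigree(rows)
        assert len(ped.report.date_violations) == 1
        with pytest.raises(PedigreeError, match="date-order"):
            build_pedigree(rows, strict_dates=True)


class TestCompleteDepth:
    def test_founder_depth_zero(self):
        ped = build_pedigree(trio())
        assert ped.ancestor_complete_depth("S") == 0

    def test_known_parents_only(self):
        ped = build_pedigree(trio())
        assert ped.ancestor_complete_depth("O") == 1

    def test_grandparents_complete_great_grandparents_missing(self):
        # all four grandparents recorded as founders: three-generation
        # complete, i.e. depth 2
        m = ex.half_sibs("paternal")
        ped = m.pedigree
        assert ped.ancestor_complete_depth(m.offspring) == 2

    def test_stub_parent_breaks_completeness(self):
        ped = build_pedigree([dict(id="O", sire="S", dam="D", sex="F")])
        assert ped.ancestor_complete_depth("O") == 0

    def test_unknown_id_raises(self):
        ped = build_pedigree(trio())
        with pytest.raises(KeyError):
            ped.ancestor_complete_depth("nope")


class TestKinship:
    def test_two_founders_unrelated(self):
        ped = build_pedigree(trio())
        assert ped.kinship("S", "D").f == 0.0
        assert ped.relatedness("S", "D").r == 0.0

    def test_parent_offspring_f_quarter_r_half(self):
        ped = build_pedigree(trio())
        assert ped.kinship("S", "O").f == 0.25
        assert ped.relatedness("S", "O").r == 0.5

    def test_self_kinship_of_non_inbred_is_half(self):
        ped = build_pedigree(trio())
        assert ped.kinship("O", "O").f == 0.5

    def test_full_siblings_f_quarter(self):
        m = ex.full_sibs()
        ped = m.pedigree
        sire, dam = ped.parents(m.offspring)
        assert ped.kinship(sire, dam).f == 0.25

    def test_paternal_half_siblings_r_quarter(self):
        m = ex.half_sibs("paternal")
        ped = m.pedigree
        sire, dam = ped.parents(m.offspring)
        assert ped.relatedness(sire, dam).r == 0.25

    def test_symmetry_on_random_pedigrees(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ped = random_pedigree(rng, n=25)
            ids = ped.ids
            for _ in range(20):
                i, j = (ids[int(rng.integers(len(ids)))] for _ in range(2))
                assert ped.kinship(i, j).f == ped.kinship(j, i).f

    def test_r_equals_twice_f_on_random_pairs(self):
        rng = np.random.default_rng(8)
        ped = random_pedigree(rng, n=30)
        ids = ped.ids
        for _ in range(30):
            i, j = (ids[int(rng.integers(len(ids)))] for _ in range(2))
            assert ped.relatedness(i, j).r == 2 * ped.kinship(i, j).f


class TestInbreedingCoefficient:
    @pytest.mark.parametrize("example,depth,expected", [
        (ex.parent_offspring("paternal"), 2, 0.25),
        (ex.half_sibs("paternal"), 2, 0.125),
        (ex.half_sibs("maternal"), 2, 0.125),
        (ex.half_cousins(), 3, 0.03125),
        (ex.half_avuncular(), 3, 0.0625),
        (ex.full_cousins(), 3, 0.0625),
    ])
    def test_canonical_matings(self, example, depth, expected):
        ped = example.pedigree
        assert ped.inbreeding_coefficient(example.offspring, depth).F == expected

    def test_cousin_inbreeding_invisible_at_grandparent_depth(self):
        m = ex.half_cousins()
        ped = m.pedigree
        assert ped.inbreeding_coefficient(m.offspring, 3).F == 0.03125
        assert ped.inbreeding_coefficient(m.offspring, 2).F == 0.0

    def test_founder_child_not_inbred(self):
        ped = build_pedigree(trio())
        assert ped.inbreeding_coefficient("O").F == 0.0

    def test_missing_parent_gives_undefined_not_zero(self):
        ped = build_pedigree([dict(id="D", sex="F"),
                              dict(id="O", sire=None, dam="D", sex="F")])
        case = ped.inbreeding_coefficient("O")
        assert case.F is None and not case.defined

    def test_depth_monotonicity_on_random_pedigrees(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            ped = random_pedigree(rng, n=30)
            for iid in ped.ids:
                if ped.parents(iid)[0] is None:
                    continue
                fs = [ped.inbreeding_coefficient(iid, d).F for d in range(5)]
                assert all(a <= b + 1e-15 for a, b in zip(fs, fs[1:]))


class TestClassification:
    @pytest.mark.parametrize("example,depth,label,line", [
        (ex.half_sibs("paternal"), 2, "paternal half-sibs", "paternal"),
        (ex.parent_offspring("paternal"), 2, "parent-offspring", "paternal"),
        (ex.full_cousins(), 3, "first cousins", "maternal-and-paternal"),
        (ex.half_avuncular("sire", "sire", "sire"), 3, "uncle-niece",
         "paternal"),
        (ex.half_avuncular("dam", "sire", "dam"), 3, "aunt-nephew",
         "maternal-and-paternal"),
    ])
    def test_relationship_and_line(self, example, depth, label, line):
        case = example.pedigree.classify_inbreeding(example.offspring, depth)
        assert [(k.relationship, k.kin_line) for k in case.kin_paths] \
            == [(label, line)]

    def test_non_inbred_gets_empty_classification(self):
        ped = build_pedigree(trio())
        case = ped.classify_inbreeding("O", 2)
        assert case.F == 0.0 and case.kin_paths == ()

    @pytest.mark.parametrize("example,depth", [
        (ex.half_sibs("paternal"), 2),
        (ex.full_sibs(), 2),
        (ex.parent_offspring("maternal"), 2),
        (ex.half_avuncular(), 3),
        (ex.half_cousins(), 3),
        (ex.full_cousins(), 3),
    ])
    def test_path_contributions_reproduce_F(self, example, depth):
        case = example.pedigree.classify_inbreeding(example.offspring, depth)
        assert sum(k.contribution for k in case.kin_paths) \
            == pytest.approx(case.F, abs=1e-15)

    def test_contributions_reproduce_F_on_random_pedigrees(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            ped = random_pedigree(rng, n=22)
            for iid in ped.ids:
                case = ped.classify_inbreeding(iid, 4)
                if case.F:
                    total = sum(k.contribution for k in case.kin_paths)
                    assert total == pytest.approx(case.F, abs=1e-12)


class TestGeneDrop:
    def test_founder_exactly_zero(self):
        ped = build_pedigree(trio())
        res = ped.gene_drop_F("S", 2000, seed=1)
        assert res.F_hat == 0.0

    def test_full_sib_offspring_matches_quarter(self):
        m = ex.full_sibs()
        res = m.pedigree.gene_drop_F(m.offspring, 100_000, seed=2)
        se = np.sqrt(0.25 * 0.75 / 100_000)
        assert abs(res.F_hat - 0.25) < 3 * se

    def test_cousin_offspring_matches_closed_form(self):
        m = ex.half_cousins()
        res = m.pedigree.gene_drop_F(m.offspring, 100_000, seed=3)
        se = np.sqrt(0.03125 * (1 - 0.03125) / 100_000)
        assert abs(res.F_hat - 0.03125) < 3 * se

    def test_rejects_nonpositive_replicates(self):
        ped = build_pedigree(trio())
        with pytest.raises(ValueError):
            ped.gene_drop_F("O", 0)


class TestPrevalence:
    def test_percentages_round_to_two_decimals(self):
        from pedavoid.pedigree import InbreedingCase
        inbred = [InbreedingCase(f"i{k}", 0.125, 2) for k in range(21)]
        outbred = [InbreedingCase(f"o{k}", 0.0, 2) for k in range(2669 - 21)]
        summary = prevalence_summary(inbred + outbred)
        assert summary.overall["percent_inbred"] == 0.79
        assert summary.overall["n_inbred"] == 21

        inbred = [InbreedingCase(f"i{k}", 0.03125, 3) for k in range(45)]
        outbred = [InbreedingCase(f"o{k}", 0.0, 3) for k in range(609 - 45)]
        summary = prevalence_summary(inbred + outbred)
        assert summary.overall["percent_inbred"] == 7.39

    def test_no_inbred_gives_zero(self):
        from pedavoid.pedigree import InbreedingCase
        cases = [InbreedingCase(f"o{k}", 0.0, 2) for k in range(10)]
        summary = prevalence_summary(cases)
        assert summary.overall["percent_inbred"] == 0.0
        assert np.isnan(summary.overall["mean_F_among_inbred"])

    def test_cohort_counts_sum_to_overall(self):
        from pedavoid.pedigree import InbreedingCase
        rng = np.random.default_rng(5)
        cases = [InbreedingCase(f"i{k}", float(rng.random() < 0.1) * 0.125, 2)
                 for k in range(200)]
        cohorts = {f"i{k}": k % 4 for k in range(200)}
        summary = prevalence_summary(cases, cohorts)
        assert summary.per_cohort["n_inbred"].sum() \
            == summary.overall["n_inbred"]
        assert summary.per_cohort["n_individuals"].sum() \
            == summary.overall["n_individuals"]
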