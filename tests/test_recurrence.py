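import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nactmut import refdata
from nactmut.cohort import SampleRecord
from nactmut.recurrence import (
    PresenceMatrix,
    case_unique_genes,
    emergent_cross_reference,
    exclusivity,
    presence_from_gene_sets,
    recurrent_genes,
    site_venn,
)


@pytest.fixture(scope="module")
def reference_matrices():
    sets = refdata.exclusivity_gene_sets()
    return {
        stratum: presence_from_gene_sets(sets, stratum)
        for stratum in ("any", "pre_only", "post_only", "stable_within_case",
                        "emergent_within_case")
    }


@pytest.fixture(scope="module")
def groups():
    return refdata.platinum_groups()


class TestBuildPresence:
    def test_any_vs_post_only(self):
        sets = {"A": {"pre": {"g"}, "post": set()}, "B": {"pre": set(), "post": set()}}
        any_m = presence_from_gene_sets(sets, "any")
        post_m = presence_from_gene_sets(sets, "post_only")
        assert bool(any_m.data.loc["g", "A"])
        assert "g" not in post_m.genes  # never detected post-treatment

    def test_emergent_stratum_requires_both_timepoints(self):
        with pytest.raises(ValueError, match="timepoint"):
            presence_from_gene_sets({"A": {"pre": {"g"}}}, "emergent_within_case")

    def test_unknown_stratum(self):
        with pytest.raises(ValueError, match="stratum"):
            presence_from_gene_sets({}, "bogus")

    def test_emergent_gene_counted_once_at_case_level(self, reference_matrices):
        # emergent at both post-treatment sites of one case -> one case-level entry
        em = reference_matrices["emergent_within_case"]
        assert int(em.data.loc["ADGRV1"].sum()) == 2  # two resistant cases, once each


class TestExclusivity:
    def test_toy(self):
        sets = {
            "R1": {"pre": {"g1", "g2"}, "post": set()},
            "R2": {"pre": {"g1"}, "post": set()},
            "S1": {"pre": {"g2"}, "post": set()},
            "S2": {"pre": set(), "post": set()},
        }
        m = presence_from_gene_sets(sets, "any")
        excl = exclusivity(m, {"R1": "resistant", "R2": "resistant",
                               "S1": "sensitive", "S2": "sensitive"})
        assert excl.resistant_exclusive_recurrent == {"g1"}
        assert excl.sensitive_exclusive_recurrent == frozenset()

    def test_reference_pattern_counts(self, reference_matrices, groups):
        excl = exclusivity(reference_matrices["any"], groups, min_resistant=2)
        assert len(excl.resistant_exclusive_recurrent) == refdata.RESISTANT_EXCLUSIVE_COUNT
        assert len(excl.sensitive_exclusive_recurrent) == refdata.SENSITIVE_EXCLUSIVE_COUNT

    def test_reference_pre_stratum(self, reference_matrices, groups):
        excl = exclusivity(reference_matrices["pre_only"], groups, min_resistant=2)
        assert excl.resistant_exclusive_recurrent == refdata.PRE_EXCLUSIVE_RESISTANT
        assert excl.sensitive_exclusive_recurrent == refdata.PRE_EXCLUSIVE_SENSITIVE

    def test_reference_post_stratum(self, reference_matrices, groups):
        excl = exclusivity(reference_matrices["post_only"], groups, min_resistant=2)
        assert excl.resistant_exclusive_recurrent == refdata.POST_EXCLUSIVE_RESISTANT
        assert excl.sensitive_exclusive_recurrent == frozenset()

    def test_ubiquitous_genes_excluded(self):
        sets = {
            c: {"pre": {"g"}, "post": set()} for c in ("R1", "R2", "S1")
        }
        m = presence_from_gene_sets(sets, "any")
        excl = exclusivity(m, {"R1": "resistant", "R2": "resistant", "S1": "sensitive"})
        assert not excl.resistant_exclusive_recurrent
        assert not excl.sensitive_exclusive_recurrent

    def test_single_group_rejected(self):
        m = presence_from_gene_sets({"R1": {"pre": {"g"}, "post": set()}}, "any")
        with pytest.raises(ValueError):
            exclusivity(m, {"R1": "resistant"})

    def test_disjointness_invariant(self, reference_matrices, groups):
        excl = exclusivity(reference_matrices["any"], groups)
        assert not (excl.resistant_exclusive_recurrent & excl.sensitive_exclusive_recurrent)

    def test_permutation_stability(self, groups):
        sets = refdata.exclusivity_gene_sets()
        m1 = presence_from_gene_sets(sets, "any")
        reordered = dict(reversed(list(sets.items())))
        m2 = presence_from_gene_sets(reordered, "any")
        e1, e2 = exclusivity(m1, groups), exclusivity(m2, groups)
        assert e1.resistant_exclusive_recurrent == e2.resistant_exclusive_recurrent
        assert e1.sensitive_exclusive_recurrent == e2.sensitive_exclusive_recurrent


class TestEmergentCrossReference:
    def test_reference_narrowing(self, reference_matrices, groups):
        shared, exclusive = emergent_cross_reference(
            reference_matrices["emergent_within_case"],
            reference_matrices["any"],
            groups,
        )
        assert shared == refdata.SHARED_EMERGENT_RESISTANT  # 6 genes
        assert exclusive == refdata.EMERGENT_EXCLUSIVE_RESISTANT  # narrowed to 4

    def test_stable_stratum_shared_between_resistant(self, reference_matrices, groups):
        stable = reference_matrices["stable_within_case"]
        resistant = [c for c in stable.cases if groups[c] == "resistant"]
        counts = stable.data[resistant].sum(axis=1)
        assert set(stable.data.index[counts >= 2]) == set(refdata.STABLE_SHARED_RESISTANT)


class TestRecurrentGenes:
    def test_reference_top_hits(self, reference_matrices):
        rec = recurrent_genes(reference_matrices["any"], min_cases=2)
        assert rec["MUC2"] == 5
        assert rec["DDX11"] == rec["TP53"] == 4
        assert rec["TUBA3D"] == 4

    def test_threshold(self, reference_matrices):
        rec5 = recurrent_genes(reference_matrices["any"], min_cases=5)
        assert rec5 == {"MUC2": 5}

    def test_single_case_gene_excluded(self):
        m = presence_from_gene_sets(
            {"A": {"pre": {"g"}, "post": set()}, "B": {"pre": set(), "post": set()}},
            "any",
        )
        assert recurrent_genes(m, min_cases=2) == {}

    def test_deterministic_tie_order(self):
        sets = {
            "A": {"pre": {"zeta", "alpha"}, "post": set()},
            "B": {"pre": {"zeta", "alpha"}, "post": set()},
        }
        rec = recurrent_genes(presence_from_gene_sets(sets, "any"), min_cases=2)
        assert list(rec) == ["alpha", "zeta"]

    def test_min_cases_validated(self, reference_matrices):
        with pytest.raises(ValueError):
            recurrent_genes(reference_matrices["any"], min_cases=1)


class TestCaseUniqueGenes:
    def test_unique_fraction(self):
        sets = {
            "A": {"pre": {f"u{i}" for i in range(45)} | {f"s{i}" for i in range(21)},
                  "post": set()},
            "B": {"pre": {f"s{i}" for i in range(21)}, "post": set()},
        }
        m = presence_from_gene_sets(sets, "any")
        unique, total, pct = case_unique_genes(m)["A"]
        assert (unique, total, pct) == (45, 66, 68)


class TestSiteVenn:
    def test_trivial_shared_gene(self):
        comparison = site_venn("c", {"a": {"g"}, "b": {"g"}, "d": {"g"}})
        assert comparison.named["all_samples"] == {"g"}

    def test_regions_partition_universe(self):
        comparison = site_venn(
            "c", {"a": {"g1", "g2"}, "b": {"g2", "g3"}, "d": {"g3", "g4"}}
        )
        sizes = sum(len(g) for g in comparison.regions.values())
        assert sizes == len(comparison.universe) == 4

    def test_two_disjoint_samples(self):
        comparison = site_venn("c", {"a": {"g1"}, "b": {"g2"}})
        assert comparison.regions[frozenset({"a"})] == {"g1"}
        assert comparison.regions[frozenset({"b"})] == {"g2"}
        assert frozenset({"a", "b"}) not in comparison.regions

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            site_venn("c", {"a": {"g"}})

    def test_named_categories_three_sample_fixture(self):
        # constructed to 8 all-sample / 2 both-post-emergent /
        # 10 ovary-only-emergent / 14 omentum-only-emergent
        all_genes = {f"A{i}" for i in range(8)}
        both_post = {f"B{i}" for i in range(2)}
        ov_only = {f"V{i}" for i in range(10)}
        om_only = {f"M{i}" for i in range(14)}
        pre_om = all_genes | {"preX"}
        post_ov = all_genes | both_post | ov_only
        post_om = all_genes | both_post | om_only
        comparison = site_venn(
            "case3",
            {"pre-om": pre_om, "post-ov": post_ov, "post-om": post_om},
            pre_sample="pre-om",
            sites={"pre-om": "omentum", "post-ov": "ovary", "post-om": "omentum"},
        )
        assert len(comparison.named["all_samples"]) == 8
        assert len(comparison.named["emergent_both_post"]) == 2
        assert len(comparison.named["emergent_only_ovary"]) == 10
        assert len(comparison.named["emergent_only_omentum"]) == 14
        # both omental samples, irrespective of treatment
        assert comparison.named["both_same_site"] == all_genes

    @given(
        st.dictionaries(
            st.sampled_from(["s1", "s2", "s3", "s4"]),
            st.sets(st.sampled_from([f"g{i}" for i in range(10)]), max_size=10),
            min_size=2,
            max_size=4,
        )
    )
    def test_partition_property(self, gene_sets):
        comparison = site_venn("c", gene_sets)
        seen: set[str] = set()
        for genes in comparison.regions.values():
            assert not (seen & genes)  # exactly one region per gene
            seen |= genes
        universe = set().union(*gene_sets.values())
        assert seen == universe


class TestPresenceMatrixValidation:
    def test_duplicate_labels_rejected(self):
        frame = pd.DataFrame(
            [[True], [False]], index=["g", "g"], columns=["A"]
        )
        with pytest.raises(ValueError, match="unique"):
            PresenceMatrix(data=frame, stratum="any")
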