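import dataclasses
import math

import numpy as np
import pytest

from nactmut.classify import summarize_counts
from nactmut.overlap import case_shared_fractions, gene_status
from nactmut.recurrence import build_presence, exclusivity
from nactmut.simulate import (
    SyntheticConfig,
    expected_vaf,
    noiseless,
    simulate_cohort,
    truth_statistics,
    write_cohort,
)


def small_config(**overrides) -> SyntheticConfig:
    defaults = dict(
        truncal_mutations=20,
        subclonal_mut_mean=8.0,
        post_private_mut_mean=6.0,
        n_genes=200,
        seed=11,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="module")
def noiseless_cohort():
    return simulate_cohort(noiseless(small_config(multisite_case=2)))


def _by_case_timepoint(cohort):
    out = {}
    for s in cohort.samples:
        out.setdefault(s.case_id, {"pre": {}, "post": {}})[s.timepoint][
            s.sample_id
        ] = cohort.variants[s.sample_id]
    return out


class TestConfigValidation:
    def test_fraction_length(self):
        with pytest.raises(ValueError):
            SyntheticConfig(pre_clone_fractions=(0.5, 0.5))

    def test_fractions_sum(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticConfig(pre_clone_fractions=(0.5, 0.2, 0.1, 0.1))

    def test_depth_positive(self):
        with pytest.raises(ValueError):
            SyntheticConfig(exome_depth=0)


class TestExpectedVaf:
    def test_diploid_clonal(self):
        # purity 0.8, clonal het SNV on CN 2: 0.8 / 2
        assert expected_vaf(0.8, 1.0, 2) == pytest.approx(0.4)

    def test_subclonal_scales_linearly(self):
        assert expected_vaf(0.8, 0.25, 2) == pytest.approx(0.1)

    def test_amplification_dilutes(self):
        assert expected_vaf(0.8, 1.0, 8) < expected_vaf(0.8, 1.0, 2)


class TestDeterminism:
    def test_same_seed_same_tables(self, tmp_path):
        cfg = small_config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(cfg), d1)
        write_cohort(simulate_cohort(cfg), d2)
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_different_seed_differs(self):
        a = simulate_cohort(small_config(seed=1))
        b = simulate_cohort(small_config(seed=2))
        assert a.variants != b.variants


class TestNoiselessOracleEquivalence:
    def test_counts_match_truth(self, noiseless_cohort):
        stats = truth_statistics(noiseless_cohort.truth)
        for sid, calls in noiseless_cohort.variants.items():
            summary = summarize_counts(calls)
            truth = stats["per_sample_counts"][sid]
            assert summary.total_somatic == truth["total_somatic"]
            assert summary.exonic == truth["exonic"]
            assert summary.synonymous_snv == truth["synonymous_snv"]
            assert summary.nonsynonymous_snv == truth["nonsynonymous_snv"]
            assert summary.stop_gain_loss == truth["stop_gain_loss"]
            assert summary.nonsyn_total == truth["nonsyn_total"]
            assert summary.nonsyn_gene_count == truth["nonsyn_gene_count"]

    def test_shared_fractions_match_truth(self, noiseless_cohort):
        stats = truth_statistics(noiseless_cohort.truth)
        for case_id, tp in _by_case_timepoint(noiseless_cohort).items():
            for sf in case_shared_fractions(tp["pre"], tp["post"]):
                truth_shared, truth_total = stats["per_sample_shared"][sf.sample_id][sf.basis]
                assert (sf.shared, sf.total) == (truth_shared, truth_total), (
                    case_id, sf.sample_id, sf.basis
                )

    def test_gene_status_matches_truth_partitions(self, noiseless_cohort):
        stats = truth_statistics(noiseless_cohort.truth)
        for case_id, tp in _by_case_timepoint(noiseless_cohort).items():
            table = gene_status(case_id, tp["pre"], tp["post"])
            truth = stats["per_case"][case_id]
            assert table.stable == truth["stable"]
            assert table.emergent == truth["emergent"]
            assert table.lost == truth["lost"]

    def test_exclusivity_matches_truth(self, noiseless_cohort):
        stats = truth_statistics(noiseless_cohort.truth)
        matrix = build_presence(noiseless_cohort.variants, noiseless_cohort.samples, "any")
        groups = {c.case_id: c.platinum_status for c in noiseless_cohort.cases}
        excl = exclusivity(matrix, groups, min_resistant=2)
        assert excl.resistant_exclusive_recurrent == stats["resistant_exclusive"]
        assert excl.sensitive_exclusive_recurrent == stats["sensitive_exclusive"]

    def test_resistant_bottleneck_creates_lost_and_emergent(self, noiseless_cohort):
        stats = truth_statistics(noiseless_cohort.truth)
        resistant = [c for c, d in stats["per_case"].items() if d["group"] == "resistant"]
        assert any(stats["per_case"][c]["emergent"] for c in resistant)
        assert any(stats["per_case"][c]["lost"] for c in resistant)


class TestTruncalOnlyLimit:
    def test_all_fractions_100(self):
        cfg = noiseless(
            small_config(subclonal_mut_mean=0.0, post_private_mut_mean=0.0,
                         multisite_case=None)
        )
        cohort = simulate_cohort(cfg)
        for case_id, tp in _by_case_timepoint(cohort).items():
            for sf in case_shared_fractions(tp["pre"], tp["post"]):
                assert sf.pct == 100, (case_id, sf.sample_id, sf.basis)

    def test_post_private_clone_drives_emergence(self):
        cfg = noiseless(small_config(subclonal_mut_mean=0.0, post_private_mut_mean=12.0))
        cohort = simulate_cohort(cfg)
        stats = truth_statistics(cohort.truth)
        for case_id, truth in stats["per_case"].items():
            ct = cohort.truth.cases[case_id]
            expected = {
                m.gene for m in ct.clone_mutations["post_private"] if m.is_nonsyn
            } - truth["pre_genes"]
            assert truth["emergent"] == expected


class TestDetectionThresholds:
    def test_min_vaf_monotonicity(self):
        counts = []
        for min_vaf in (0.0, 0.05, 0.10, 0.20, 0.40):
            cfg = small_config(min_vaf=min_vaf, min_alt_reads=0)
            cohort = simulate_cohort(cfg)
            counts.append({sid: len(v) for sid, v in cohort.variants.items()})
        for lo, hi in zip(counts, counts[1:]):
            for sid in lo:
                assert hi[sid] <= lo[sid]

    def test_min_alt_monotonicity(self):
        lo = simulate_cohort(small_config(min_alt_reads=0))
        hi = simulate_cohort(small_config(min_alt_reads=10))
        for sid in lo.variants:
            assert len(hi.variants[sid]) <= len(lo.variants[sid])

    def test_detected_sharing_not_inflated_near_detection_limit(self):
        # dropout can only remove sharing: over many replicates the mean
        # detected pre-sample shared fraction stays at or below the truth,
        # within a one-sided tolerance
        detected, truth_vals = [], []
        for seed in range(200):
            cfg = SyntheticConfig(
                n_resistant=1,
                n_sensitive=1,
                truncal_mutations=10,
                subclones_per_case=2,
                subclonal_mut_mean=6.0,
                pre_clone_fractions=(0.6, 0.3, 0.1),
                resistant_bottleneck_weights=(0.2, 0.0, 3.0),
                sensitive_bottleneck_weights=(1.0, 0.5, 1.0),
                post_private_mut_mean=4.0,
                exome_depth=40,
                min_alt_reads=3,
                min_vaf=0.05,
                n_genes=120,
                seed=seed,
            )
            cohort = simulate_cohort(cfg)
            stats = truth_statistics(cohort.truth)
            for case_id, tp in _by_case_timepoint(cohort).items():
                for sf in case_shared_fractions(tp["pre"], tp["post"]):
                    if sf.basis != "gene" or not sf.sample_id.endswith("-1"):
                        continue
                    if not sf.defined:
                        continue
                    t_shared, t_total = stats["per_sample_shared"][sf.sample_id]["gene"]
                    if t_total == 0:
                        continue
                    detected.append(sf.shared / sf.total)
                    truth_vals.append(t_shared / t_total)
        assert len(detected) >= 200
        assert np.mean(detected) <= np.mean(truth_vals) + 0.02


class TestTruthInternals:
    def test_clone_fractions_sum_to_one(self, noiseless_cohort):
        for ct in noiseless_cohort.truth.cases.values():
            for sid, fracs in ct.sample_clone_fractions.items():
                assert math.isclose(sum(fracs.values()), 1.0, abs_tol=1e-9), sid

    def test_keys_globally_unique(self, noiseless_cohort):
        keys = []
        for ct in noiseless_cohort.truth.cases.values():
            for muts in ct.clone_mutations.values():
                keys.extend(m.key for m in muts)
        assert len(keys) == len(set(keys))

    def test_multisite_case_has_two_post_samples(self, noiseless_cohort):
        sim3 = [s for s in noiseless_cohort.samples if s.case_id == "SIM3"]
        assert sum(s.timepoint == "post" for s in sim3) == 2
        assert {s.site for s in sim3 if s.timepoint == "post"} == {"omentum", "ovary"}

    def test_manifest_platinum_labels(self, noiseless_cohort):
        groups = {c.case_id: c.platinum_status for c in noiseless_cohort.cases}
        assert sum(g == "resistant" for g in groups.values()) == 3
        assert sum(g == "sensitive" for g in groups.values()) == 2
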