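"""Bundled reference dataset: a five-case paired pre/post-NACT cohort.

Summary-level data from a published five-case high-grade serous ovarian
carcinoma cohort (three platinum-resistant, two platinum-sensitive
cases), used throughout the documentation, tests and acceptance checks:
clinical metadata, per-sample mutation count decompositions, pre/post
shared-fraction numerators/denominators, and a reconstructed
gene-by-(case, timepoint) presence pattern for the recurrently mutated
group-exclusive genes.

Only summary numbers are bundled; per-mutation coordinates are not part
of the source material, so fixtures that need full variant lists are
constructed programmatically to match these counts.
"""

from __future__ import annotations

from nactmut.cohort import CaseRecord, SampleRecord


def reference_cases() -> list[CaseRecord]:
    """Clinical metadata for the five cases."""
    return [
        CaseRecord(
            case_id="case1", stage="IIIa", nact_cycles=5, total_cycles=9,
            ca125_pre=81, ca125_pct_decrease=84, residual_disease="none",
            time_to_recurrence=4.6, time_to_death_or_fu=21.4,
            vital_status="DOD", platinum_status="resistant",
        ),
        CaseRecord(
            case_id="case2", stage="IIIc", nact_cycles=5, total_cycles=5,
            ca125_pre=180, ca125_pct_decrease=62, residual_disease=">1cm",
            time_to_recurrence=4.4, time_to_death_or_fu=12.1,
            vital_status="DOD", platinum_status="resistant",
        ),
        CaseRecord(
            case_id="case3", stage="IIIb", nact_cycles=4, total_cycles=7,
            ca125_pre=96, ca125_pct_decrease=82, residual_disease="none",
            time_to_recurrence=3.6, time_to_death_or_fu=18.1,
            vital_status="DOD", platinum_status="resistant",
        ),
        CaseRecord(
            case_id="case4", stage="IIIb", nact_cycles=3, total_cycles=6,
            ca125_pre=1634, ca125_pct_decrease=98, residual_disease=">1cm",
            time_to_recurrence=19.5, time_to_death_or_fu=47.9,
            vital_status="AWD", platinum_status="sensitive",
        ),
        CaseRecord(
            case_id="case5", stage="IIIc", nact_cycles=3, total_cycles=6,
            ca125_pre=4659, ca125_pct_decrease=96, residual_disease="<=1cm",
            time_to_recurrence=20.9, time_to_death_or_fu=42.2,
            vital_status="AWD", platinum_status="sensitive",
        ),
    ]


def reference_samples() -> list[SampleRecord]:
    """The 11 exome-sequenced tumor samples (pre and post treatment)."""
    rows = [
        ("1-1", "case1", "pre", "omentum"),
        ("1-2", "case1", "post", "pelvic_nodule"),
        ("2-1", "case2", "pre", "omentum"),
        ("2-2", "case2", "post", "omentum"),
        ("3-1", "case3", "pre", "omentum"),
        ("3-2", "case3", "post", "ovary"),
        ("3-3", "case3", "post", "omentum"),
        ("4-1", "case4", "pre", "omentum"),
        ("4-2", "case4", "post", "stomach_nodule"),
        ("5-1", "case5", "pre", "unspecified"),
        ("5-2", "case5", "post", "bowel_nodule"),
    ]
    return [
        SampleRecord(sample_id=sid, case_id=cid, timepoint=tp, site=site, platform="exome")
        for sid, cid, tp, site in rows
    ]


#: Per-sample count decomposition:
#: (total somatic, exonic, synonymous SNV, nonsynonymous SNV, stopgain/stoploss)
COUNT_SUMMARY: dict[str, tuple[int, int, int, int, int]] = {
    "1-1": (333, 71, 24, 47, 0),
    "1-2": (5652, 1735, 904, 821, 10),
    "2-1": (427, 116, 34, 77, 5),
    "2-2": (543, 120, 45, 73, 2),
    "3-1": (399, 65, 25, 38, 2),
    "3-2": (351, 61, 27, 32, 2),
    "3-3": (298, 55, 23, 31, 1),
    "4-1": (539, 128, 33, 88, 7),
    "4-2": (510, 137, 39, 92, 6),
    "5-1": (1412, 436, 216, 211, 9),
    "5-2": (703, 106, 35, 69, 2),
}

#: Position-basis shared/total (non-synonymous mutations) per sample.
SHARED_POSITION: dict[str, tuple[int, int]] = {
    "1-1": (6, 47),
    "1-2": (6, 831),
    "2-1": (34, 82),
    "2-2": (34, 75),
    "3-1": (26, 40),
    "3-2": (21, 34),
    "3-3": (13, 32),
    "4-1": (41, 95),
    "4-2": (41, 98),
    "5-1": (35, 220),
    "5-2": (35, 71),
}

#: Gene-basis shared/total (distinct mutated genes) per sample.
SHARED_GENE: dict[str, tuple[int, int]] = {
    "1-1": (8, 47),
    "1-2": (8, 691),
    "2-1": (33, 80),
    "2-2": (33, 65),
    "3-1": (27, 40),
    "3-2": (21, 33),
    "3-3": (14, 30),
    "4-1": (42, 95),
    "4-2": (42, 98),
    "5-1": (35, 209),
    "5-2": (35, 60),
}

#: Per-case (unique genes, total mutated genes) across the cohort.
CASE_UNIQUE_GENES: dict[str, tuple[int, int]] = {
    "case1": (666, 730),
    "case2": (88, 112),
    "case3": (45, 66),
    "case4": (125, 151),
    "case5": (183, 234),
}

#: Per-case (emergent genes, post-timepoint gene universe).
CASE_EMERGENT_GENES: dict[str, tuple[int, int]] = {
    "case1": (683, 691),
    "case2": (32, 65),
    "case3": (26, 53),
    "case4": (56, 98),
    "case5": (25, 60),
}

# ---------------------------------------------------------------------------
# Reconstructed gene-by-(case, timepoint) presence pattern for the
# recurrently mutated group-exclusive genes, plus decoy genes mutated in
# both groups. Case-level aggregation of this pattern reproduces the
# published exclusivity counts (16 resistant-exclusive, 5
# sensitive-exclusive); the pre/post split is consistent with the
# published per-timepoint footnotes (e.g. which genes were exclusive to
# post-treatment samples of resistant cases).
# ---------------------------------------------------------------------------

#: gene -> set of (case_id, timepoint) where a non-synonymous mutation
#: was detected.
EXCLUSIVITY_PRESENCE: dict[str, set[tuple[str, str]]] = {
    # --- 16 genes confined to >1 resistant case ---
    "ADGRV1": {("case2", "post"), ("case3", "post")},
    "AOC1": {("case2", "pre"), ("case2", "post"), ("case3", "post")},
    "ARHGAP5": {("case1", "pre"), ("case3", "post")},
    "CSPG4": {("case1", "pre"), ("case2", "pre"), ("case3", "pre")},
    "KIR2DL1": {("case1", "pre"), ("case2", "post")},
    "KRTAP4-11": {("case2", "pre"), ("case3", "post")},
    "MMP9": {("case1", "pre"), ("case2", "post")},
    "MTMR11": {("case2", "post"), ("case3", "pre"), ("case3", "post")},
    "MUC17": {("case2", "post"), ("case3", "post")},
    "MUC20": {("case2", "post"), ("case3", "post")},
    "OR52N5": {("case1", "post"), ("case2", "pre"), ("case2", "post")},
    "PAK2": {("case2", "post"), ("case3", "post")},
    "PCDHB11": {("case1", "post"), ("case3", "pre"), ("case3", "post")},
    "TMEM14B": {("case1", "pre"), ("case1", "post"), ("case2", "post")},
    "TTN": {("case1", "pre"), ("case2", "post")},
    "USP8": {("case2", "pre"), ("case3", "post")},
    # --- 5 genes confined to both sensitive cases ---
    "CYP2D6": {("case4", "pre"), ("case5", "pre")},
    "DNAH5": {("case4", "pre"), ("case4", "post"), ("case5", "pre")},
    "FAM186A": {("case4", "pre"), ("case5", "post")},
    "MACF1": {("case4", "post"), ("case5", "pre")},
    "NUTM1": {("case4", "pre"), ("case5", "pre")},
    # --- decoys present in both platinum groups ---
    # mutated in all five cases
    "MUC2": {
        ("case1", "pre"), ("case2", "pre"), ("case3", "post"),
        ("case4", "pre"), ("case5", "post"),
    },
    # mutated in 4 of 5 cases
    "DDX11": {("case1", "pre"), ("case2", "post"), ("case3", "pre"), ("case4", "pre")},
    "TP53": {("case1", "pre"), ("case2", "pre"), ("case3", "pre"), ("case4", "pre")},
    "TUBA3D": {
        ("case1", "pre"), ("case1", "post"), ("case2", "pre"), ("case2", "post"),
        ("case3", "pre"), ("case4", "post"),
    },
    # pre-exclusive to resistant cases but later detected in a sensitive case
    "SLC35G5": {
        ("case1", "pre"), ("case1", "post"), ("case2", "pre"), ("case2", "post"),
        ("case5", "post"),
    },
    # emergent in >1 resistant case but mutated pre-treatment in a sensitive case
    "CACNA1S": {("case2", "post"), ("case3", "post"), ("case4", "pre")},
    # emergent in >1 resistant case but mutated pre and post in a sensitive case
    "KIR2DL3": {("case1", "post"), ("case3", "post"), ("case5", "pre"), ("case5", "post")},
}

#: Expected cross-case results on the reconstructed pattern.
RESISTANT_EXCLUSIVE_COUNT = 16
SENSITIVE_EXCLUSIVE_COUNT = 5
#: Pre-timepoint stratum: recurrent genes confined to one group.
PRE_EXCLUSIVE_RESISTANT = frozenset({"CSPG4", "SLC35G5", "TUBA3D"})
PRE_EXCLUSIVE_SENSITIVE = frozenset({"CYP2D6", "DNAH5", "NUTM1"})
#: Post-timepoint stratum: recurrent genes confined to resistant cases.
POST_EXCLUSIVE_RESISTANT = frozenset(
    {"ADGRV1", "AOC1", "CACNA1S", "MTMR11", "MUC17", "MUC20", "OR52N5", "PAK2",
     "PCDHB11", "TMEM14B"}
)
#: Genes emergent (post-only within case) in more than one resistant case...
SHARED_EMERGENT_RESISTANT = frozenset(
    {"ADGRV1", "CACNA1S", "KIR2DL3", "MUC17", "MUC20", "PAK2"}
)
#: ...of which these are never detected in a sensitive case at any timepoint.
EMERGENT_EXCLUSIVE_RESISTANT = frozenset({"ADGRV1", "MUC17", "MUC20", "PAK2"})
#: Stable-within-case genes shared by more than one resistant case.
STABLE_SHARED_RESISTANT = frozenset({"SLC35G5", "TUBA3D"})


def exclusivity_gene_sets() -> dict[str, dict[str, set[str]]]:
    """Presence pattern as case -> timepoint -> gene set."""
    out: dict[str, dict[str, set[str]]] = {
        f"case{i}": {"pre": set(), "post": set()} for i in range(1, 6)
    }
    for gene, cells in EXCLUSIVITY_PRESENCE.items():
        for case_id, timepoint in cells:
            out[case_id][timepoint].add(gene)
    return out


def platinum_groups() -> dict[str, str]:
    return {c.case_id: c.platinum_status for c in reference_cases()}
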