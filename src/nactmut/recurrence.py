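"""Cross-case recurrence, group-exclusivity and multi-site comparisons.

A presence matrix records, per gene and per case, whether a
non-synonymous mutation was detected under a chosen stratum: any
timepoint, pre only, post only, or the within-case stable/emergent
partitions. Exclusivity sets pick out genes recurrently mutated in only
one platinum group; the site comparison assigns each gene of a
multi-sample case to one region of the k-sample Venn diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from nactmut.overlap import round_pct

STRATA = ("any", "pre_only", "post_only", "stable_within_case", "emergent_within_case")


@dataclass
class PresenceMatrix:
    """Gene-by-case boolean presence under one stratum."""

    data: pd.DataFrame  # bool, index=genes, columns=case ids
    stratum: str

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}; expected one of {STRATA}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("presence matrix labels must be unique")
        self.data = self.data.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cases(self) -> list[str]:
        return list(self.data.columns)

    def gene_case_count(self, gene: str) -> int:
        return int(self.data.loc[gene].sum())


@dataclass(frozen=True)
class ExclusivitySets:
    """Recurrent genes confined to one platinum group."""

    resistant_exclusive_recurrent: frozenset[str]
    sensitive_exclusive_recurrent: frozenset[str]
    recurrent_any: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.resistant_exclusive_recurrent & self.sensitive_exclusive_recurrent
        if overlap:
            raise ValueError(f"exclusive sets intersect: {sorted(overlap)}")


def presence_from_gene_sets(
    case_timepoint_genes: Mapping[str, Mapping[str, Iterable[str]]],
    stratum: str = "any",
) -> PresenceMatrix:
    """Build the presence matrix from per-(case, timepoint) gene sets.

    ``case_timepoint_genes`` maps case_id -> {"pre": genes, "post": genes},
    each timepoint already unioned over that case's samples. Strata
    referencing the within-case partition (stable/emergent) require both
    timepoints for every case.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    columns: dict[str, set[str]] = {}
    for case_id, by_tp in case_timepoint_genes.items():
        pre = set(by_tp.get("pre", ()))
        post = set(by_tp.get("post", ()))
        if stratum == "any":
            genes = pre | post
        elif stratum == "pre_only":
            genes = pre
        elif stratum == "post_only":
            genes = post
        else:
            if "pre" not in by_tp or "post" not in by_tp:
                raise ValueError(
                    f"case {case_id}: stratum {stratum!r} requires both timepoints"
                )
            genes = (pre & post) if stratum == "stable_within_case" else (post - pre)
        columns[case_id] = genes

    all_genes = sorted(set().union(*columns.values())) if columns else []
    frame = pd.DataFrame(
        {case: [g in genes for g in all_genes] for case, genes in columns.items()},
        index=all_genes,
    )
    return PresenceMatrix(data=frame, stratum=stratum)


def build_presence(
    variants_by_sample: Mapping[str, Sequence],
    samples: Sequence,
    stratum: str = "any",
    include_indels: bool = False,
) -> PresenceMatrix:
    """Presence matrix straight from per-sample variant calls.

    ``samples`` are SampleRecords carrying case_id/timepoint for every key
    of ``variants_by_sample``.
    """
    from nactmut.classify import nonsynonymous_variants

    meta = {s.sample_id: s for s in samples}
    unknown = set(variants_by_sample) - set(meta)
    if unknown:
        raise ValueError(f"samples missing from manifest: {sorted(unknown)}")
    per_case: dict[str, dict[str, set[str]]] = {}
    for sid, variants in variants_by_sample.items():
        rec = meta[sid]
        genes = {
            v.gene for v in nonsynonymous_variants(variants, include_indels=include_indels)
        }
        per_case.setdefault(rec.case_id, {}).setdefault(rec.timepoint, set()).update(genes)
    return presence_from_gene_sets(per_case, stratum)


def exclusivity(
    matrix: PresenceMatrix,
    groups: Mapping[str, str],
    min_resistant: int = 2,
) -> ExclusivitySets:
    """Genes recurrently mutated in only one platinum group.

    Resistant-exclusive: present in at least ``min_resistant`` resistant
    cases and no sensitive case. Sensitive-exclusive: present in *all*
    sensitive cases and no resistant case (the study had two sensitive
    cases, so "both"; generalized to "all" for larger cohorts).
    """
    unknown = set(matrix.cases) - set(groups)
    if unknown:
        raise ValueError(f"cases without a platinum group label: {sorted(unknown)}")
    resistant = [c for c in matrix.cases if groups[c] == "resistant"]
    sensitive = [c for c in matrix.cases if groups[c] == "sensitive"]
    if not resistant or not sensitive:
        raise ValueError("exclusivity requires both resistant and sensitive cases")

    r_counts = matrix.data[resistant].sum(axis=1)
    s_counts = matrix.data[sensitive].sum(axis=1)
    res_excl = frozenset(
        matrix.data.index[(r_counts >= min_resistant) & (s_counts == 0)]
    )
    sens_excl = frozenset(
        matrix.data.index[(s_counts == len(sensitive)) & (r_counts == 0)]
    )
    totals = matrix.data.sum(axis=1)
    recurrent = {g: int(n) for g, n in totals.items() if n >= 2}
    return ExclusivitySets(
        resistant_exclusive_recurrent=res_excl,
        sensitive_exclusive_recurrent=sens_excl,
        recurrent_any=recurrent,
    )


def recurrent_genes(matrix: PresenceMatrix, min_cases: int = 2) -> dict[str, int]:
    """Genes present in at least ``min_cases`` cases, ordered by case count
    descending then gene symbol."""
    if min_cases < 2:
        raise ValueError("min_cases must be >= 2")
    counts = matrix.data.sum(axis=1)
    hits = [(g, int(n)) for g, n in counts.items() if n >= min_cases]
    hits.sort(key=lambda item: (-item[1], item[0]))
    return dict(hits)


def case_unique_genes(matrix: PresenceMatrix) -> dict[str, tuple[int, int, int]]:
    """Per case: (unique genes, total genes, unique percent).

    A gene is unique to a case when it is present in that case and no
    other case of the matrix.
    """
    counts = matrix.data.sum(axis=1)
    out = {}
    for case in matrix.cases:
        present = matrix.data[case]
        total = int(present.sum())
        unique = int((present & (counts == 1)).sum())
        out[case] = (unique, total, round_pct(unique, total) if total else 0)
    return out


def emergent_cross_reference(
    emergent_matrix: PresenceMatrix,
    any_matrix: PresenceMatrix,
    groups: Mapping[str, str],
    min_resistant: int = 2,
) -> tuple[frozenset[str], frozenset[str]]:
    """Resistant-shared emergent genes, then the strictly exclusive subset.

    First picks genes emergent (post-only within case) in at least
    ``min_resistant`` resistant cases; then removes any gene detected in a
    sensitive case at *any* timepoint, so a gene emergent in resistant
    cases but mutated pre-treatment in a sensitive case does not count as
    exclusive. Returns (shared_emergent, exclusive_emergent).
    """
    resistant = [c for c in emergent_matrix.cases if groups.get(c) == "resistant"]
    sensitive_any = [c for c in any_matrix.cases if groups.get(c) == "sensitive"]
    if not resistant:
        raise ValueError("no resistant cases in emergent matrix")
    r_counts = emergent_matrix.data[resistant].sum(axis=1)
    shared = frozenset(emergent_matrix.data.index[r_counts >= min_resistant])
    if sensitive_any:
        seen_sensitive = set(
            any_matrix.data.index[any_matrix.data[sensitive_any].any(axis=1)]
        )
    else:
        seen_sensitive = set()
    exclusive = frozenset(g for g in shared if g not in seen_sensitive)
    return shared, exclusive


# ---------------------------------------------------------------------------
# Multi-site Venn comparison within one case
# ---------------------------------------------------------------------------


@dataclass
class SiteComparison:
    """Venn partition of one case's gene universe over its k samples."""

    case_id: str
    sample_ids: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[str]]  # sample-id subset -> genes
    named: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= genes
        return frozenset(out)


def site_venn(
    case_id: str,
    gene_sets: Mapping[str, Iterable[str]],
    pre_sample: str | None = None,
    sites: Mapping[str, str] | None = None,
) -> SiteComparison:
    """Assign each of the case's genes to exactly one Venn region.

    ``gene_sets`` maps sample_id -> mutated gene set (2..6 samples). When
    ``pre_sample`` and per-sample ``sites`` are given for the 3-sample
    configuration (one pre, two post from different sites, one of which
    matches the pre site), named categories are derived:

    - ``all_samples``: mutated in every sample.
    - ``both_same_site``: mutated in both samples of the pre-treatment
      site, irrespective of treatment.
    - ``emergent_both_post``: mutated in both post samples but not pre.
    - ``emergent_only_<site>``: mutated in exactly one post sample, not pre.
    """
    sample_ids = tuple(gene_sets)
    k = len(sample_ids)
    if k < 2:
        raise ValueError(f"case {case_id}: site comparison needs >= 2 samples")
    if k > 6:
        raise ValueError(f"case {case_id}: at most 6 samples supported, got {k}")
    sets = {sid: frozenset(genes) for sid, genes in gene_sets.items()}

    membership: dict[str, frozenset[str]] = {}
    universe: set[str] = set()
    for genes in sets.values():
        universe |= genes
    for gene in universe:
        membership[gene] = frozenset(sid for sid in sample_ids if gene in sets[sid])

    regions: dict[frozenset[str], set[str]] = {}
    for gene, subset in membership.items():
        regions.setdefault(subset, set()).add(gene)

    named: dict[str, frozenset[str]] = {}
    named["all_samples"] = frozenset(
        g for g, subset in membership.items() if len(subset) == k
    )
    if pre_sample is not None:
        if pre_sample not in sets:
            raise ValueError(f"pre_sample {pre_sample!r} not among samples")
        posts = [sid for sid in sample_ids if sid != pre_sample]
        named["emergent_both_post"] = frozenset(
            g
            for g, subset in membership.items()
            if pre_sample not in subset and set(posts) <= subset
        )
        for post in posts:
            label = f"emergent_only_{sites[post] if sites else post}"
            named[label] = frozenset(
                g for g, subset in membership.items() if subset == frozenset({post})
            )
        if sites is not None:
            pre_site = sites[pre_sample]
            same_site_posts = [p for p in posts if sites[p] == pre_site]
            if same_site_posts:
                named["both_same_site"] = frozenset(
                    g
                    for g, subset in membership.items()
                    if pre_sample in subset and any(p in subset for p in same_site_posts)
                )
    return SiteComparison(
        case_id=case_id,
        sample_ids=sample_ids,
        regions={subset: frozenset(genes) for subset, genes in regions.items()},
        named=named,
    )
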