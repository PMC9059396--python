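"""Pre/post overlap within a case: shared fractions and gene status.

Two comparison bases are supported: "position" matches mutations on their
normalized (chrom, pos, ref, alt) key; "gene" matches on the mutated gene
symbol. Fractions are asymmetric by design: a pre-treatment sample is
compared against the union of all post-treatment samples from the case
("shared with at least one post sample"), while each post-treatment
sample is compared against the pre-treatment sample(s) only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from nactmut.classify import nonsynonymous_variants
from nactmut.variants import VariantCall, variant_key

GENE_STATUSES = ("stable", "emergent", "lost")


@dataclass(frozen=True)
class SharedFraction:
    """Shared/total counts for one focal sample under one basis."""

    sample_id: str
    basis: str  # "position" or "gene"
    shared: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.shared <= self.total):
            raise ValueError(
                f"{self.sample_id}: shared ({self.shared}) outside [0, {self.total}]"
            )

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def pct(self) -> int:
        """Integer percent, half-up. Undefined (total 0) raises."""
        return round_pct(self.shared, self.total)


def round_pct(shared: int, total: int) -> int:
    """Integer percent 100*shared/total with exact half-up tie-breaking."""
    if total <= 0:
        raise ValueError(f"percentage undefined for total={total}")
    return int(math.floor(Fraction(100 * shared, total) + Fraction(1, 2)))


def _position_keys(variants: Iterable[VariantCall], site_only: bool) -> set:
    return {variant_key(v, site_only=site_only) for v in variants}


def _gene_set(variants: Iterable[VariantCall]) -> set[str]:
    return {v.gene for v in variants}


def shared_fraction(
    focal: Sequence[VariantCall],
    others: Sequence[Sequence[VariantCall]],
    basis: str = "position",
    include_indels: bool = False,
    site_only: bool = False,
) -> SharedFraction:
    """Fraction of the focal sample's non-synonymous mutations (or mutated
    genes) found in at least one of the other samples.

    Variants are restricted to the non-synonymous exonic universe before
    comparison. ``site_only`` relaxes position matching to (chrom, pos).
    """
    if basis not in ("position", "gene"):
        raise ValueError(f"basis must be 'position' or 'gene', got {basis!r}")
    if not others:
        raise ValueError("shared_fraction requires at least one comparison sample")
    focal = list(focal)
    focal_ids = {v.sample_id for v in focal}
    if len(focal_ids) > 1:
        raise ValueError(f"focal variants span multiple samples: {sorted(focal_ids)}")
    sample_id = focal_ids.pop() if focal_ids else ""
    for other in others:
        if sample_id and sample_id in {v.sample_id for v in other}:
            raise ValueError(f"focal sample {sample_id} present among comparison samples")

    focal_ns = nonsynonymous_variants(focal, include_indels=include_indels)
    others_ns = [nonsynonymous_variants(o, include_indels=include_indels) for o in others]

    if basis == "position":
        focal_keys = _position_keys(focal_ns, site_only)
        other_keys: set = set()
        for o in others_ns:
            other_keys |= _position_keys(o, site_only)
    else:
        focal_keys = _gene_set(focal_ns)
        other_keys = set()
        for o in others_ns:
            other_keys |= _gene_set(o)

    return SharedFraction(
        sample_id=sample_id,
        basis=basis,
        shared=len(focal_keys & other_keys),
        total=len(focal_keys),
    )


def case_shared_fractions(
    pre: Mapping[str, Sequence[VariantCall]],
    post: Mapping[str, Sequence[VariantCall]],
    include_indels: bool = False,
    site_only: bool = False,
) -> list[SharedFraction]:
    """All per-sample shared fractions for one case, both bases.

    Pre samples compare against the union of post samples; each post
    sample compares against the (union of) pre sample(s).
    """
    if not pre or not post:
        raise ValueError("case requires at least one pre and one post sample")
    results = []
    post_lists = [list(v) for v in post.values()]
    pre_lists = [list(v) for v in pre.values()]
    for basis in ("position", "gene"):
        for variants in pre_lists:
            results.append(
                shared_fraction(variants, post_lists, basis, include_indels, site_only)
            )
        for variants in post_lists:
            results.append(
                shared_fraction(variants, pre_lists, basis, include_indels, site_only)
            )
    return results


@dataclass
class GeneStatusTable:
    """Per-gene stable/emergent/lost partition for one case.

    Union-over-samples semantics within each timepoint: a gene is
    "stable" if mutated in the pre sample(s) and at least one post
    sample, "emergent" if mutated post only, "lost" if pre only.
    """

    case_id: str
    status: dict[str, str]
    supporting_samples: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def stable(self) -> frozenset[str]:
        return frozenset(g for g, s in self.status.items() if s == "stable")

    @property
    def emergent(self) -> frozenset[str]:
        return frozenset(g for g, s in self.status.items() if s == "emergent")

    @property
    def lost(self) -> frozenset[str]:
        return frozenset(g for g, s in self.status.items() if s == "lost")

    @property
    def pre_universe(self) -> frozenset[str]:
        return self.stable | self.lost

    @property
    def post_universe(self) -> frozenset[str]:
        return self.stable | self.emergent

    @property
    def emergent_fraction(self) -> SharedFraction:
        """Emergent genes over the post-timepoint gene universe."""
        return SharedFraction(
            sample_id=self.case_id,
            basis="gene",
            shared=len(self.emergent),
            total=len(self.post_universe),
        )


def gene_status(
    case_id: str,
    pre: Mapping[str, Sequence[VariantCall]],
    post: Mapping[str, Sequence[VariantCall]],
    include_indels: bool = False,
) -> GeneStatusTable:
    """Partition the case's non-synonymous gene universe by timepoint."""
    if not pre:
        raise ValueError(f"case {case_id}: no pre-treatment samples")
    if not post:
        raise ValueError(f"case {case_id}: no post-treatment samples")

    support: dict[str, set[str]] = {}
    pre_genes: set[str] = set()
    post_genes: set[str] = set()
    for sid, variants in pre.items():
        genes = _gene_set(nonsynonymous_variants(variants, include_indels=include_indels))
        pre_genes |= genes
        for g in genes:
            support.setdefault(g, set()).add(sid)
    for sid, variants in post.items():
        genes = _gene_set(nonsynonymous_variants(variants, include_indels=include_indels))
        post_genes |= genes
        for g in genes:
            support.setdefault(g, set()).add(sid)

    status = {}
    for g in pre_genes | post_genes:
        if g in pre_genes and g in post_genes:
            status[g] = "stable"
        elif g in post_genes:
            status[g] = "emergent"
        else:
            status[g] = "lost"
    return GeneStatusTable(
        case_id=case_id,
        status=status,
        supporting_samples={g: frozenset(s) for g, s in support.items()},
    )
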