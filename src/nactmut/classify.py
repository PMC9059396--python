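"""Per-sample mutation count decomposition.

Defines the "non-synonymous exonic" universe (nonsynonymous SNV, stopgain
or stoploss) used by all pre/post and cross-case comparisons, and the
per-sample count summary whose categories must conserve exactly:
exonic = synonymous + nonsynonymous + stopgain/stoploss + other exonic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from nactmut.variants import VariantCall, variant_key

NONSYNONYMOUS_FUNCTIONS = frozenset({"nonsynonymous_SNV", "stopgain", "stoploss"})


@dataclass(frozen=True)
class MutationCountSummary:
    """One row of the per-sample count table."""

    sample_id: str
    total_somatic: int
    exonic: int
    synonymous_snv: int
    nonsynonymous_snv: int
    stop_gain_loss: int
    other_exonic: int  # indel + unknown exonic categories
    nonsyn_total: int
    nonsyn_gene_count: int

    def __post_init__(self) -> None:
        if self.exonic != (
            self.synonymous_snv + self.nonsynonymous_snv + self.stop_gain_loss + self.other_exonic
        ):
            raise ValueError(f"{self.sample_id}: exonic categories do not conserve")
        if self.nonsyn_total != self.nonsynonymous_snv + self.stop_gain_loss:
            raise ValueError(f"{self.sample_id}: nonsyn_total mismatch")
        # nonsyn_gene_count <= nonsyn_total holds for single-gene annotations
        # but a multi-gene expansion legitimately maps one mutation to
        # several genes, so it is not enforced here
        if self.exonic > self.total_somatic:
            raise ValueError(f"{self.sample_id}: exonic exceeds total")


def is_nonsynonymous(v: VariantCall) -> bool:
    """True iff the call is exonic and alters the protein via an SNV or stop change."""
    return v.region_class == "exonic" and v.exonic_function in NONSYNONYMOUS_FUNCTIONS


def nonsynonymous_variants(
    variants: Iterable[VariantCall], include_indels: bool = False
) -> list[VariantCall]:
    """Filter to the non-synonymous exonic universe.

    ``include_indels`` additionally admits exonic frameshift/nonframeshift
    indels for position-based comparisons (off by default: the summary
    categories enumerate SNV and stop changes only).
    """
    keep = []
    for v in variants:
        if is_nonsynonymous(v):
            keep.append(v)
        elif include_indels and v.region_class == "exonic" and v.exonic_function in (
            "frameshift_indel",
            "nonframeshift_indel",
        ):
            keep.append(v)
    return keep


def dedupe_sample_variants(variants: list[VariantCall]) -> list[VariantCall]:
    """Collapse duplicate normalized keys within one sample.

    Records expanded from multi-gene annotations legitimately share a key
    and are kept (one per gene); other duplicates are assumed caller
    artifacts, collapsed to the first occurrence with a warning.
    """
    seen: dict[tuple, VariantCall] = {}
    out: list[VariantCall] = []
    for v in variants:
        key = variant_key(v) + (v.gene,)
        if key in seen:
            warnings.warn(
                f"sample {v.sample_id}: duplicate variant key {key[:4]} collapsed",
                stacklevel=2,
            )
            continue
        seen[key] = v
        out.append(v)
    return out


def summarize_counts(variants: Iterable[VariantCall]) -> MutationCountSummary:
    """Count decomposition for one sample's variant list.

    "Total somatic" counts distinct normalized variant keys (multi-allelic
    splitting can exceed the source line count; multi-gene expansions do
    not double-count). The distinct-gene denominator is computed over the
    non-synonymous universe.
    """
    variants = list(variants)
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) > 1:
        raise ValueError(f"summarize_counts got mixed sample_ids: {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else ""

    variants = dedupe_sample_variants(variants)
    keys: dict[tuple, list[VariantCall]] = {}
    for v in variants:
        keys.setdefault(variant_key(v), []).append(v)

    exonic = synonymous = nonsyn = stop = other_ex = 0
    nonsyn_genes: set[str] = set()
    for group in keys.values():
        v = group[0]  # one count per distinct key
        if v.region_class != "exonic":
            continue
        exonic += 1
        if v.exonic_function == "synonymous_SNV":
            synonymous += 1
        elif v.exonic_function == "nonsynonymous_SNV":
            nonsyn += 1
        elif v.exonic_function in ("stopgain", "stoploss"):
            stop += 1
        else:
            other_ex += 1
        if v.exonic_function in NONSYNONYMOUS_FUNCTIONS:
            nonsyn_genes.update(g.gene for g in group)

    return MutationCountSummary(
        sample_id=sample_id,
        total_somatic=len(keys),
        exonic=exonic,
        synonymous_snv=synonymous,
        nonsynonymous_snv=nonsyn,
        stop_gain_loss=stop,
        other_exonic=other_ex,
        nonsyn_total=nonsyn + stop,
        nonsyn_gene_count=len(nonsyn_genes),
    )
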