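"""Targeted-panel candidate selection, cross-platform validation, CN flags.

Panel genes satisfy at least one of five criteria: (1) mutated in only
one platinum group; (2) mutated in more than one resistant case; (3)
mutated only in — or at an increased variant-read percentage in —
post-treatment samples of resistant cases; (4) externally flagged as
implicated in platinum response; (5) externally flagged as associated
with progression-free survival in a reference dataset. Criteria 4-5 are
supplied as gene lists; 1-3 are computed from the cohort results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from nactmut.classify import nonsynonymous_variants
from nactmut.overlap import GeneStatusTable
from nactmut.recurrence import PresenceMatrix
from nactmut.variants import CopyNumberRecord, VariantCall, variant_key

DEFAULT_AMP_THRESHOLD = 7.0
DEFAULT_LOSS_THRESHOLD = 1.0
DEFAULT_MIN_VAF_INCREASE = 0.10


@dataclass(frozen=True)
class PanelCriteriaFlags:
    gene: str
    c1_exclusive_group: bool = False
    c2_recurrent_resistant: bool = False
    c3_post_only_or_vaf_increase: bool = False
    c4_literature_platinum: bool = False
    c5_tcga_pfs: bool = False

    @property
    def flags(self) -> tuple[bool, ...]:
        return (
            self.c1_exclusive_group,
            self.c2_recurrent_resistant,
            self.c3_post_only_or_vaf_increase,
            self.c4_literature_platinum,
            self.c5_tcga_pfs,
        )

    @property
    def selected(self) -> bool:
        return any(self.flags)

    @property
    def n_criteria(self) -> int:
        return sum(self.flags)


@dataclass(frozen=True)
class ValidationRecord:
    gene: str
    sample_id: str
    key: tuple
    validated: bool
    exome_vaf: float | None = None
    targeted_vaf: float | None = None
    aa_change: str | None = None
    novel_on_panel: bool = False  # targeted-only call

    def __post_init__(self) -> None:
        for name, vaf in (("exome_vaf", self.exome_vaf), ("targeted_vaf", self.targeted_vaf)):
            if vaf is not None and not (0.0 <= vaf <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {vaf}")


@dataclass(frozen=True)
class CnFlag:
    gene: str
    sample_id: str
    tumor_cn: float
    flag: str  # amplified | neutral | loss


def cn_flag(
    record: CopyNumberRecord,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
) -> CnFlag:
    """Flag gene-level copy number: amplified at >= amp_threshold copies,
    loss at <= loss_threshold (one copy or fewer vs the diploid normal)."""
    if record.tumor_cn < 0:
        raise ValueError(f"negative copy number for {record.gene}")
    if amp_threshold <= loss_threshold:
        raise ValueError("amp_threshold must exceed loss_threshold")
    if record.tumor_cn >= amp_threshold:
        label = "amplified"
    elif record.tumor_cn <= loss_threshold:
        label = "loss"
    else:
        label = "neutral"
    return CnFlag(
        gene=record.gene, sample_id=record.sample_id, tumor_cn=record.tumor_cn, flag=label
    )


def compute_panel_criteria(
    any_matrix: PresenceMatrix,
    groups: Mapping[str, str],
    gene_status_tables: Sequence[GeneStatusTable],
    vaf_by_gene: Mapping[tuple[str, str, str], float] | None = None,
    literature_genes: Iterable[str] = (),
    pfs_genes: Iterable[str] = (),
    min_resistant: int = 2,
    min_vaf_increase: float = DEFAULT_MIN_VAF_INCREASE,
) -> dict[str, PanelCriteriaFlags]:
    """Evaluate the five selection criteria for every gene in the matrix.

    ``vaf_by_gene`` maps (case_id, timepoint, gene) -> max VAF, used for
    the criterion-3 variant-read-increase clause; omit it to fall back to
    the post-only clause alone.
    """
    resistant = [c for c in any_matrix.cases if groups.get(c) == "resistant"]
    sensitive = [c for c in any_matrix.cases if groups.get(c) == "sensitive"]
    status_by_case = {t.case_id: t for t in gene_status_tables}

    r_counts = any_matrix.data[resistant].sum(axis=1) if resistant else 0
    s_counts = any_matrix.data[sensitive].sum(axis=1) if sensitive else 0
    lit = set(literature_genes)
    pfs = set(pfs_genes)

    out: dict[str, PanelCriteriaFlags] = {}
    for gene in any_matrix.genes:
        in_r = int(r_counts[gene]) if resistant else 0
        in_s = int(s_counts[gene]) if sensitive else 0
        c1 = (in_r > 0) != (in_s > 0)  # confined to exactly one group
        c2 = in_r >= min_resistant
        c3 = False
        for case in resistant:
            table = status_by_case.get(case)
            if table is None:
                continue
            if gene in table.emergent:
                c3 = True
                break
            if vaf_by_gene is not None and gene in table.stable:
                pre_v = vaf_by_gene.get((case, "pre", gene))
                post_v = vaf_by_gene.get((case, "post", gene))
                if (
                    pre_v is not None
                    and post_v is not None
                    and post_v - pre_v >= min_vaf_increase
                ):
                    c3 = True
                    break
        out[gene] = PanelCriteriaFlags(
            gene=gene,
            c1_exclusive_group=c1,
            c2_recurrent_resistant=c2,
            c3_post_only_or_vaf_increase=c3,
            c4_literature_platinum=gene in lit,
            c5_tcga_pfs=gene in pfs,
        )
    return out


def select_panel(
    criteria: Mapping[str, PanelCriteriaFlags], target_size: int
) -> list[PanelCriteriaFlags]:
    """Genes meeting >= 1 criterion, ranked by criteria count then symbol,
    truncated to ``target_size``."""
    if target_size < 1:
        raise ValueError(f"target_size must be >= 1, got {target_size}")
    chosen = [f for f in criteria.values() if f.selected]
    chosen.sort(key=lambda f: (-f.n_criteria, f.gene))
    return chosen[:target_size]


def validate_calls(
    exome_calls: Sequence[VariantCall],
    targeted_calls: Sequence[VariantCall],
    panel_genes: Iterable[str],
    include_indels: bool = False,
) -> list[ValidationRecord]:
    """Cross-platform concordance on panel genes, per sample and key.

    Every exome call gets a record with ``validated`` set when the same
    normalized key was called on the targeted platform for the same
    sample; targeted-only calls are reported too, flagged
    ``novel_on_panel`` (never dropped).
    """
    genes = set(panel_genes)
    ex = [
        v
        for v in nonsynonymous_variants(exome_calls, include_indels=include_indels)
        if v.gene in genes
    ]
    tg = [
        v
        for v in nonsynonymous_variants(targeted_calls, include_indels=include_indels)
        if v.gene in genes
    ]
    tg_index = {(v.sample_id, variant_key(v)): v for v in tg}
    ex_index = {(v.sample_id, variant_key(v)): v for v in ex}

    records = []
    for (sid, key), v in sorted(ex_index.items()):
        match = tg_index.get((sid, key))
        records.append(
            ValidationRecord(
                gene=v.gene,
                sample_id=sid,
                key=key,
                validated=match is not None,
                exome_vaf=v.vaf,
                targeted_vaf=match.vaf if match is not None else None,
                aa_change=v.aa_change,
            )
        )
    for (sid, key), v in sorted(tg_index.items()):
        if (sid, key) in ex_index:
            continue
        records.append(
            ValidationRecord(
                gene=v.gene,
                sample_id=sid,
                key=key,
                validated=False,
                exome_vaf=None,
                targeted_vaf=v.vaf,
                aa_change=v.aa_change,
                novel_on_panel=True,
            )
        )
    return records
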