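"""Shared fixtures: programmatic variant builders and reference cohorts.

No binary or on-disk fixtures; everything is constructed at test time.
"""

from __future__ import annotations

import pytest

from nactmut.variants import VariantCall


def make_variant(
    chrom: str = "chr1",
    pos: int = 1,
    ref: str = "A",
    alt: str = "T",
    gene: str = "G1",
    sample_id: str = "s1",
    region_class: str = "exonic",
    exonic_function: str | None = "nonsynonymous_SNV",
    alt_reads: int = 30,
    total_reads: int = 100,
    aa_change: str | None = None,
) -> VariantCall:
    if region_class != "exonic":
        exonic_function = None
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        sample_id=sample_id,
        region_class=region_class,
        exonic_function=exonic_function,
        alt_reads=alt_reads,
        total_reads=total_reads,
        aa_change=aa_change,
    )


def nonsyn_sample(
    sample_id: str,
    positions: list[int],
    genes: list[str] | None = None,
    chrom: str = "chr1",
) -> list[VariantCall]:
    """One non-synonymous SNV per position (gene defaults to one per site)."""
    if genes is None:
        genes = [f"G{p}" for p in positions]
    assert len(genes) == len(positions)
    return [
        make_variant(chrom=chrom, pos=p, gene=g, sample_id=sample_id)
        for p, g in zip(positions, genes)
    ]


def gene_sample(sample_id: str, genes: list[str], start_pos: int = 1) -> list[VariantCall]:
    """One non-synonymous SNV per gene at consecutive positions."""
    return [
        make_variant(pos=start_pos + i, gene=g, sample_id=sample_id)
        for i, g in enumerate(genes)
    ]


@pytest.fixture
def shared_pair_builder():
    """Build (pre, post) variant lists with exact shared/total structure.

    ``position`` basis: focal has ``total`` distinct sites, ``shared`` of
    which also occur in the comparison sample. ``gene`` basis analogous
    with distinct gene symbols.
    """

    def build(total: int, shared: int, basis: str, other_extra: int = 5):
        assert 0 <= shared <= total
        if basis == "position":
            focal = nonsyn_sample("focal", list(range(1, total + 1)))
            other_positions = list(range(1, shared + 1)) + [
                10_000 + i for i in range(other_extra)
            ]
            other = nonsyn_sample("other", other_positions)
        else:
            focal_genes = [f"FG{i:04d}" for i in range(total)]
            other_genes = focal_genes[:shared] + [f"OG{i:04d}" for i in range(other_extra)]
            focal = gene_sample("focal", focal_genes, start_pos=1)
            other = gene_sample("other", other_genes, start_pos=100_000)
        return focal, other

    return build
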