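"""Annotated somatic variant I/O and key normalization.

Reads single-sample VCF 4.x (with ANNOVAR-style INFO annotation keys) or
a MAF-like tab-separated dialect, and writes the tabular reports used by
the downstream comparison modules. Coordinates are 1-based inclusive
everywhere, including the TSV dialect.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

REGION_CLASSES = frozenset(
    {
        "exonic",
        "splicing",
        "intronic",
        "UTR5",
        "UTR3",
        "intergenic",
        "ncRNA",
        "upstream",
        "downstream",
        "other",
    }
)
EXONIC_FUNCTIONS = frozenset(
    {
        "synonymous_SNV",
        "nonsynonymous_SNV",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "nonframeshift_indel",
        "unknown",
    }
)

_ALLELE_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class VariantCall:
    """One annotated somatic mutation observed in one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    region_class: str
    sample_id: str
    exonic_function: str | None = None
    aa_change: str | None = None
    alt_reads: int = 0
    total_reads: int = 0
    multi_gene: bool = False  # expanded from a multi-gene annotation

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")
        if not (0 <= self.alt_reads <= self.total_reads):
            raise ValueError(
                f"alt_reads/total_reads out of range at {self.chrom}:{self.pos}: "
                f"{self.alt_reads}/{self.total_reads}"
            )
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if (self.region_class == "exonic") != (self.exonic_function is not None):
            raise ValueError(
                f"exonic_function must be present iff region_class is exonic "
                f"({self.chrom}:{self.pos}, {self.region_class}, {self.exonic_function})"
            )
        if self.exonic_function is not None and self.exonic_function not in EXONIC_FUNCTIONS:
            raise ValueError(f"unknown exonic_function {self.exonic_function!r}")

    @property
    def vaf(self) -> float | None:
        """Variant allele fraction: alt reads over total reads at the site."""
        if self.total_reads == 0:
            return None
        return self.alt_reads / self.total_reads

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class CopyNumberRecord:
    """Gene-level tumor copy number for one sample (normal expected at 2)."""

    gene: str
    sample_id: str
    tumor_cn: float
    normal_cn: float = 2.0

    def __post_init__(self) -> None:
        if self.tumor_cn < 0:
            raise ValueError(f"tumor_cn must be >= 0, got {self.tumor_cn}")


@dataclass(frozen=True)
class RejectedRecord:
    """Input record dropped during parsing, with the reason."""

    source: str
    locus: str
    reason: str


def normalize_variant(
    chrom: str, pos: int, ref: str, alt: str
) -> tuple[str, int, str, str]:
    """Canonical (chrom, pos, ref, alt) key for position-based matching.

    Alleles are uppercased; shared trailing bases are trimmed first, then
    shared leading bases with the position advanced accordingly. At least
    one base of each allele is always retained. Idempotent.
    """
    ref = ref.strip().upper()
    alt = alt.strip().upper()
    if not ref or not alt:
        raise ValueError(f"empty allele at {chrom}:{pos}")
    for allele in (ref, alt):
        bad = set(allele) - _ALLELE_CHARS
        if bad:
            raise ValueError(
                f"non-ACGTN characters {sorted(bad)} in allele at {chrom}:{pos}"
            )
    # trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix last, advancing the position
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def variant_key(
    v: VariantCall, site_only: bool = False
) -> tuple[str, int, str, str] | tuple[str, int]:
    """Normalized matching key; ``site_only`` relaxes to (chrom, pos)."""
    chrom, pos, ref, alt = normalize_variant(v.chrom, v.pos, v.ref, v.alt)
    if site_only:
        return (chrom, pos)
    return (chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Annotation dialect
# ---------------------------------------------------------------------------

#: Default ANNOVAR-style INFO key map (refGene triplet). Override for other
#: annotation databases (e.g. "Func.knownGene").
DEFAULT_DIALECT: Mapping[str, str] = {
    "region": "Func.refGene",
    "gene": "Gene.refGene",
    "exonic_function": "ExonicFunc.refGene",
    "aa_change": "AAChange.refGene",
}

_REGION_MAP = {
    "exonic": "exonic",
    "splicing": "splicing",
    "exonic;splicing": "exonic",
    "intronic": "intronic",
    "UTR5": "UTR5",
    "UTR3": "UTR3",
    "intergenic": "intergenic",
    "ncRNA_exonic": "ncRNA",
    "ncRNA_intronic": "ncRNA",
    "ncRNA_splicing": "ncRNA",
    "ncRNA": "ncRNA",
    "upstream": "upstream",
    "downstream": "downstream",
    "upstream;downstream": "other",
}

_EXONIC_FUNC_MAP = {
    "synonymous SNV": "synonymous_SNV",
    "synonymous_SNV": "synonymous_SNV",
    "nonsynonymous SNV": "nonsynonymous_SNV",
    "nonsynonymous_SNV": "nonsynonymous_SNV",
    "stopgain": "stopgain",
    "stopgain SNV": "stopgain",
    "stoploss": "stoploss",
    "stoploss SNV": "stoploss",
    "frameshift insertion": "frameshift_indel",
    "frameshift deletion": "frameshift_indel",
    "frameshift substitution": "frameshift_indel",
    "frameshift_indel": "frameshift_indel",
    "nonframeshift insertion": "nonframeshift_indel",
    "nonframeshift deletion": "nonframeshift_indel",
    "nonframeshift substitution": "nonframeshift_indel",
    "nonframeshift_indel": "nonframeshift_indel",
    "unknown": "unknown",
}


def _unescape(value: str) -> str:
    # ANNOVAR writes INFO-reserved characters hex-escaped
    return value.replace(r"\x3b", ";").replace(r"\x3d", "=").replace(r"\x2c", ",")


def _split_genes(raw: str) -> list[str]:
    parts = [g.strip() for g in raw.replace(";", ",").split(",")]
    return [g for g in parts if g and g != "."]


MAF_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "region_class",
    "exonic_function",
    "aa_change",
    "alt_reads",
    "total_reads",
)


def read_variants(
    path: str | Path,
    format: str = "maf_tsv",
    dialect: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> tuple[list[VariantCall], list[RejectedRecord]]:
    """Read annotated somatic calls; returns (retained, rejected).

    ``format`` is ``"vcf"`` (single-sample VCF 4.x with annotation INFO
    keys per ``dialect``) or ``"maf_tsv"`` (the tab-separated dialect
    written by :func:`write_variants_tsv`). Records with an unusable
    annotation (no gene symbol, exonic without an exonic function) are
    routed to the reject list with a reason rather than raised.

    Multi-allelic VCF records are split per alt allele; multi-gene
    annotations expand to one record per gene, flagged ``multi_gene``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"variant file not found: {path}")
    if format == "vcf":
        retained, rejected = _read_vcf(path, dialect or DEFAULT_DIALECT, sample_id)
    elif format == "maf_tsv":
        retained, rejected = _read_maf_tsv(path, sample_id)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'vcf' or 'maf_tsv')")
    logger.info(
        "%s: read %d records, retained %d, rejected %d",
        path.name,
        len(retained) + len(rejected),
        len(retained),
        len(rejected),
    )
    return retained, rejected


def _read_vcf(
    path: Path, dialect: Mapping[str, str], sample_id: str | None
) -> tuple[list[VariantCall], list[RejectedRecord]]:
    for role in ("region", "gene", "exonic_function"):
        if role not in dialect:
            raise KeyError(f"annotation dialect missing required role {role!r}")
    retained: list[VariantCall] = []
    rejected: list[RejectedRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if sample_id is None:
            if len(vcf_samples) != 1:
                raise ValueError(
                    f"{path}: pass sample_id explicitly for multi-sample VCFs"
                )
            sample_id = vcf_samples[0]
        for rec in vcf:
            locus = f"{rec.chrom}:{rec.pos}"
            info = rec.info
            raw_region = info.get(dialect["region"])
            raw_gene = info.get(dialect["gene"])
            raw_exfunc = info.get(dialect["exonic_function"])
            raw_aa = info.get(dialect.get("aa_change", ""), None)
            region = _normalize_info_scalar(raw_region)
            gene_field = _normalize_info_scalar(raw_gene)
            exfunc = _normalize_info_scalar(raw_exfunc)
            aa = _normalize_info_scalar(raw_aa)
            alt_depths, total = _depths_from_record(rec, vcf_samples)
            for i, alt in enumerate(rec.alts or ()):
                base = dict(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    sample_id=sample_id,
                    alt_reads=alt_depths[i] if i < len(alt_depths) else 0,
                    total_reads=total,
                )
                _classify_and_append(
                    base, region, gene_field, exfunc, aa, path.name, locus, retained, rejected
                )
    return retained, rejected


def _normalize_info_scalar(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
        if value is None:
            return None
    text = _unescape(str(value)).strip()
    return text or None


def _depths_from_record(rec, vcf_samples: Sequence[str]) -> tuple[list[int], int]:
    """Per-alt depths and total depth from FORMAT AD (fall back to INFO DP)."""
    if vcf_samples:
        fmt = rec.samples[vcf_samples[0]]
        ad = fmt.get("AD")
        if ad is not None and ad[0] is not None:
            ad = [int(x) for x in ad]
            return ad[1:], sum(ad)
    dp = rec.info.get("DP")
    return [], int(dp) if dp is not None else 0


def _classify_and_append(
    base: dict,
    region: str | None,
    gene_field: str | None,
    exfunc: str | None,
    aa: str | None,
    source: str,
    locus: str,
    retained: list[VariantCall],
    rejected: list[RejectedRecord],
) -> None:
    if region is None:
        rejected.append(RejectedRecord(source, locus, "missing region annotation"))
        return
    region_class = _REGION_MAP.get(region, "other")
    exonic_function = None
    if region_class == "exonic":
        if exfunc is None or exfunc == ".":
            rejected.append(
                RejectedRecord(source, locus, "exonic record lacks exonic function")
            )
            return
        exonic_function = _EXONIC_FUNC_MAP.get(exfunc)
        if exonic_function is None:
            rejected.append(
                RejectedRecord(source, locus, f"unrecognized exonic function {exfunc!r}")
            )
            return
    genes = _split_genes(gene_field) if gene_field else []
    if not genes:
        rejected.append(RejectedRecord(source, locus, "no gene symbol"))
        return
    multi = len(genes) > 1
    for gene in genes:
        try:
            retained.append(
                VariantCall(
                    gene=gene,
                    region_class=region_class,
                    exonic_function=exonic_function,
                    aa_change=aa,
                    multi_gene=multi,
                    **base,
                )
            )
        except ValueError as exc:
            rejected.append(RejectedRecord(source, locus, str(exc)))
            return


def _read_maf_tsv(
    path: Path, sample_id: str | None
) -> tuple[list[VariantCall], list[RejectedRecord]]:
    retained: list[VariantCall] = []
    rejected: list[RejectedRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        missing = set(MAF_COLUMNS[:7]) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: malformed header, missing columns {sorted(missing)}")
        for row in reader:
            locus = f"{row.get('chrom')}:{row.get('pos')}"
            if sample_id is not None and row["sample_id"] != sample_id:
                continue
            exfunc = row.get("exonic_function") or None
            if exfunc in (".", "NA"):
                exfunc = None
            aa = row.get("aa_change") or None
            if aa in (".", "NA"):
                aa = None
            genes = _split_genes(row["gene"])
            if not genes:
                rejected.append(RejectedRecord(path.name, locus, "no gene symbol"))
                continue
            multi = len(genes) > 1
            for gene in genes:
                try:
                    retained.append(
                        VariantCall(
                            chrom=row["chrom"],
                            pos=int(row["pos"]),
                            ref=row["ref"],
                            alt=row["alt"],
                            gene=gene,
                            region_class=row["region_class"],
                            exonic_function=exfunc,
                            aa_change=aa,
                            alt_reads=int(row.get("alt_reads") or 0),
                            total_reads=int(row.get("total_reads") or 0),
                            sample_id=row["sample_id"],
                            multi_gene=multi,
                        )
                    )
                except (ValueError, KeyError) as exc:
                    rejected.append(RejectedRecord(path.name, locus, str(exc)))
                    break
    return retained, rejected


def write_variants_tsv(variants: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls in the MAF-like TSV dialect, deterministically ordered."""
    rows = sorted(
        variants, key=lambda v: (v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.gene)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MAF_COLUMNS)
        for v in rows:
            writer.writerow(
                [
                    v.sample_id,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene,
                    v.region_class,
                    v.exonic_function or "",
                    v.aa_change or "",
                    v.alt_reads,
                    v.total_reads,
                ]
            )


def read_copy_numbers(path: str | Path) -> list[CopyNumberRecord]:
    """Read a gene-level copy-number TSV (gene, sample_id, tumor_cn[, normal_cn])."""
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "sample_id", "tumor_cn"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ValueError(f"{path}: CN table must have columns {sorted(required)}")
        for row in reader:
            records.append(
                CopyNumberRecord(
                    gene=row["gene"].strip(),
                    sample_id=row["sample_id"],
                    tumor_cn=float(row["tumor_cn"]),
                    normal_cn=float(row.get("normal_cn") or 2.0),
                )
            )
    return records


def write_table(rows: Iterable[Mapping[str, object]], columns: Sequence[str], path: str | Path) -> None:
    """Write a generic TSV report with a fixed column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([row.get(c, "") for c in columns])
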