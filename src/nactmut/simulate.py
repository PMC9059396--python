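"""Clonal-evolution synthetic cohort generator with exact ground truth.

Each simulated case carries a truncal mutation set present in every
tumor cell plus a small number of subclones with private mutations. The
pre-treatment sample mixes the clones at configured fractions; the
chemotherapy bottleneck reweights them (resistant cases skew toward one
pre-existing minor clone), and a treatment-emergent clone with private
mutations appears only post-treatment. Observed allele fractions are
purity- and copy-number-aware, and detection is depth-limited: alt reads
are drawn binomially at the configured coverage and calls below the
detection thresholds drop out.

The ground truth records the full clone algebra, and
:func:`truth_statistics` recomputes every downstream summary (counts,
shared fractions, gene status, exclusivity) by direct set enumeration,
independent of the pipeline modules, to serve as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np

from nactmut.cohort import CaseRecord, SampleRecord, classify_platinum_status, write_manifest
from nactmut.variants import CopyNumberRecord, VariantCall, write_variants_tsv, write_table

_NONSYN = ("nonsynonymous_SNV", "stopgain", "stoploss")
_BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; a single seed determines all output."""

    n_resistant: int = 3
    n_sensitive: int = 2
    truncal_mutations: int = 40
    subclones_per_case: int = 3
    subclonal_mut_mean: float = 12.0
    subclonal_mut_dispersion: float = 5.0  # negative-binomial shape
    #: pre-treatment cell fractions: base clone (truncal only) + subclones
    pre_clone_fractions: tuple[float, ...] = (0.55, 0.25, 0.15, 0.05)
    #: per-clone bottleneck survival weights (aligned with fractions);
    #: resistant cases skew toward the pre-existing minor clone and lose one
    #: chemo-sensitive subclone outright
    resistant_bottleneck_weights: tuple[float, ...] = (0.1, 0.0, 0.2, 3.0)
    sensitive_bottleneck_weights: tuple[float, ...] = (1.0, 0.2, 1.0, 1.0)
    post_private_mut_mean: float = 10.0
    post_private_fraction: float = 0.25  # cell fraction of the emergent clone
    purity: float = 0.8
    exome_depth: int = 100  # tumor exome coverage
    panel_depth: int = 5000  # targeted-panel tumor coverage
    min_alt_reads: int = 3
    min_vaf: float = 0.02
    exonic_fraction: float = 0.30
    nonsynonymous_fraction: float = 0.70  # of exonic: protein-altering SNVs
    stop_fraction: float = 0.05  # of exonic: stopgain/stoploss
    #: 0-based case index receiving two post-treatment sites (None: all single-site)
    multisite_case: int | None = None
    site_private_mut_mean: float = 6.0
    site_perturbation: float = 0.10
    n_genes: int = 500
    gene_length: int = 1500
    #: copy-number categories exercised per (gene, sample)
    cn_values: tuple[int, ...] = (1, 2, 3, 7, 9)
    cn_probs: tuple[float, ...] = (0.05, 0.80, 0.10, 0.03, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pre_clone_fractions) != self.subclones_per_case + 1:
            raise ValueError(
                "pre_clone_fractions must have subclones_per_case + 1 entries"
            )
        if not math.isclose(sum(self.pre_clone_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("pre_clone_fractions must sum to 1")
        if any(not 0 <= f <= 1 for f in self.pre_clone_fractions):
            raise ValueError("clone fractions must lie in [0, 1]")
        for name in ("purity", "post_private_fraction", "min_vaf", "exonic_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.exome_depth <= 0 or self.panel_depth <= 0:
            raise ValueError("sequencing depths must be positive")
        if len(self.cn_values) != len(self.cn_probs):
            raise ValueError("cn_values and cn_probs must align")


@dataclass(frozen=True)
class TrueMutation:
    """One simulated somatic mutation (identity and annotation)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    region_class: str
    exonic_function: str | None
    aa_change: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_nonsyn(self) -> bool:
        return self.region_class == "exonic" and self.exonic_function in _NONSYN


@dataclass
class CaseTruth:
    """Clone algebra for one case: who carries what, at which fraction."""

    case_id: str
    group: str  # resistant | sensitive
    clone_mutations: dict[str, tuple[TrueMutation, ...]]  # clone -> private set
    sample_clone_fractions: dict[str, dict[str, float]]  # sample -> clone -> fraction

    def sample_mutations(self, sample_id: str) -> set[TrueMutation]:
        """Mutations truly present: carried by any clone with fraction > 0.
        The truncal set rides along in every clone."""
        fractions = self.sample_clone_fractions[sample_id]
        present: set[TrueMutation] = set()
        if any(f > 0 for f in fractions.values()):
            present.update(self.clone_mutations["truncal"])
        for clone, frac in fractions.items():
            if clone != "truncal" and frac > 0:
                present.update(self.clone_mutations[clone])
        return present

    def mutation_ccf(self, sample_id: str, mut: TrueMutation) -> float:
        """Cancer-cell fraction: summed fractions of clones carrying it."""
        fractions = self.sample_clone_fractions[sample_id]
        if mut in self.clone_mutations["truncal"]:
            return sum(fractions.values())
        return sum(
            frac
            for clone, frac in fractions.items()
            if clone != "truncal" and mut in self.clone_mutations[clone]
        )


@dataclass
class GroundTruth:
    """Exact truth for a simulated cohort."""

    cases: dict[str, CaseTruth]
    samples: dict[str, SampleRecord] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    config: SyntheticConfig
    cases: list[CaseRecord]
    samples: list[SampleRecord]
    variants: dict[str, list[VariantCall]]
    copy_numbers: list[CopyNumberRecord]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


class _Genome:
    """Synthetic exome: per-gene intervals, positions drawn w/o replacement."""

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.used: dict[int, set[int]] = {}

    def draw_mutation(self) -> TrueMutation:
        cfg = self.config
        gi = int(self.rng.integers(cfg.n_genes))
        chrom = f"chr{gi % 22 + 1}"
        start = (gi // 22) * (cfg.gene_length + 500) + 1
        used = self.used.setdefault(gi, set())
        if len(used) >= cfg.gene_length:
            raise RuntimeError(f"gene interval {gi} exhausted; increase gene_length")
        while True:
            pos = start + int(self.rng.integers(cfg.gene_length))
            if pos not in used:
                used.add(pos)
                break
        ref = _BASES[int(self.rng.integers(4))]
        alt = _BASES[int(self.rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(self.rng.integers(4))]
        region, exfunc = self._draw_class()
        aa = None
        if exfunc in _NONSYN:
            aa = f"p.X{pos % 997 + 1}Y"
        return TrueMutation(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=f"GENE{gi:04d}",
            region_class=region,
            exonic_function=exfunc,
            aa_change=aa,
        )

    def _draw_class(self) -> tuple[str, str | None]:
        cfg = self.config
        if self.rng.random() < cfg.exonic_fraction:
            u = self.rng.random()
            if u < cfg.nonsynonymous_fraction:
                return "exonic", "nonsynonymous_SNV"
            if u < cfg.nonsynonymous_fraction + cfg.stop_fraction:
                return "exonic", "stopgain" if self.rng.random() < 0.8 else "stoploss"
            return "exonic", "synonymous_SNV"
        region = ["intronic", "intergenic", "UTR3", "UTR5", "ncRNA"][
            int(self.rng.integers(5))
        ]
        return region, None


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    # negative binomial parameterized by mean and shape
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_cohort(config: SyntheticConfig) -> SimulatedCohort:
    """Generate a reproducible cohort with paired pre/post samples.

    Same config (including seed) always produces identical output.
    """
    rng = np.random.default_rng(config.seed)
    genome = _Genome(config, rng)

    cases: list[CaseRecord] = []
    samples: list[SampleRecord] = []
    variants: dict[str, list[VariantCall]] = {}
    copy_numbers: list[CopyNumberRecord] = []
    truth_cases: dict[str, CaseTruth] = {}

    n_cases = config.n_resistant + config.n_sensitive
    for ci in range(n_cases):
        group = "resistant" if ci < config.n_resistant else "sensitive"
        case_id = f"SIM{ci + 1}"
        if group == "resistant":
            ttr = round(3.0 + 2.5 * rng.random(), 1)
            weights = config.resistant_bottleneck_weights
        else:
            ttr = round(12.0 + 12.0 * rng.random(), 1)
            weights = config.sensitive_bottleneck_weights
        cases.append(
            CaseRecord(
                case_id=case_id,
                stage="III",
                nact_cycles=3,
                total_cycles=6,
                time_to_recurrence=ttr,
                time_to_death_or_fu=ttr + round(10 + 10 * rng.random(), 1),
                vital_status="DOD" if group == "resistant" else "AWD",
                platinum_status=classify_platinum_status(ttr),
            )
        )

        # clone architecture
        clone_mutations: dict[str, tuple[TrueMutation, ...]] = {
            "truncal": tuple(genome.draw_mutation() for _ in range(config.truncal_mutations)),
            "base": (),
        }
        clone_ids = ["base"]
        for si in range(config.subclones_per_case):
            cid = f"sub{si + 1}"
            n = _draw_count(rng, config.subclonal_mut_mean, config.subclonal_mut_dispersion)
            clone_mutations[cid] = tuple(genome.draw_mutation() for _ in range(n))
            clone_ids.append(cid)
        n_priv = _draw_count(rng, config.post_private_mut_mean, config.subclonal_mut_dispersion)
        clone_mutations["post_private"] = tuple(
            genome.draw_mutation() for _ in range(n_priv)
        )

        pre_fracs = dict(zip(clone_ids, config.pre_clone_fractions))
        pre_fracs["post_private"] = 0.0

        post_raw = {
            cid: pre_fracs[cid] * w for cid, w in zip(clone_ids, weights)
        }
        total = sum(post_raw.values())
        scale = (1.0 - config.post_private_fraction) / total if total > 0 else 0.0
        post_fracs = {cid: f * scale for cid, f in post_raw.items()}
        post_fracs["post_private"] = config.post_private_fraction

        sample_fracs: dict[str, dict[str, float]] = {}
        pre_sid = f"{case_id}-1"
        sample_fracs[pre_sid] = pre_fracs
        case_samples = [
            SampleRecord(
                sample_id=pre_sid, case_id=case_id, timepoint="pre", site="omentum",
                tumor_cellularity=config.purity,
            )
        ]
        n_post_sites = 2 if config.multisite_case == ci else 1
        for pi in range(n_post_sites):
            sid = f"{case_id}-{pi + 2}"
            site = "omentum" if pi == 0 else "ovary"
            fracs = dict(post_fracs)
            if n_post_sites > 1:
                # site-specific perturbation of clone fractions + a private late clone
                clone_key = f"site_private_{site}"
                n_site = _draw_count(
                    rng, config.site_private_mut_mean, config.subclonal_mut_dispersion
                )
                clone_mutations[clone_key] = tuple(
                    genome.draw_mutation() for _ in range(n_site)
                )
                noise = {
                    cid: max(f * (1 + config.site_perturbation * (rng.random() - 0.5)), 0.0)
                    for cid, f in fracs.items()
                }
                site_frac = 0.1 if n_site else 0.0
                z = sum(noise.values())
                fracs = {cid: f / z * (1 - site_frac) for cid, f in noise.items()}
                fracs[clone_key] = site_frac
            # every sample tracks a fraction for every clone of the case
            for cid in clone_mutations:
                fracs.setdefault(cid, 0.0)
            sample_fracs[sid] = fracs
            case_samples.append(
                SampleRecord(
                    sample_id=sid, case_id=case_id, timepoint="post", site=site,
                    tumor_cellularity=config.purity,
                )
            )
        # every sample carries an (possibly zero) fraction for every clone
        for fracs in sample_fracs.values():
            for clone_key in clone_mutations:
                fracs.setdefault(clone_key, 0.0)

        truth_cases[case_id] = CaseTruth(
            case_id=case_id,
            group=group,
            clone_mutations=clone_mutations,
            sample_clone_fractions=sample_fracs,
        )
        samples.extend(case_samples)

        # copy number per mutated gene per sample, exercising the flag thresholds
        case_genes = sorted(
            {m.gene for muts in clone_mutations.values() for m in muts}
        )
        cn_lookup: dict[tuple[str, str], int] = {}
        for s in case_samples:
            draws = rng.choice(config.cn_values, size=len(case_genes), p=config.cn_probs)
            for gene, cn in zip(case_genes, draws):
                cn_lookup[(s.sample_id, gene)] = int(cn)
                copy_numbers.append(
                    CopyNumberRecord(gene=gene, sample_id=s.sample_id, tumor_cn=float(cn))
                )

        # observed calls under depth-limited detection
        ct = truth_cases[case_id]
        for s in case_samples:
            calls: list[VariantCall] = []
            for mut in sorted(ct.sample_mutations(s.sample_id), key=lambda m: m.key):
                ccf = ct.mutation_ccf(s.sample_id, mut)
                if ccf <= 0:
                    continue
                cn = cn_lookup.get((s.sample_id, mut.gene), 2)
                evaf = expected_vaf(config.purity, ccf, cn)
                depth = config.exome_depth
                alt_reads = int(rng.binomial(depth, min(evaf, 1.0)))
                if alt_reads < config.min_alt_reads:
                    continue
                if depth and alt_reads / depth < config.min_vaf:
                    continue
                calls.append(
                    VariantCall(
                        chrom=mut.chrom,
                        pos=mut.pos,
                        ref=mut.ref,
                        alt=mut.alt,
                        gene=mut.gene,
                        region_class=mut.region_class,
                        exonic_function=mut.exonic_function,
                        aa_change=mut.aa_change,
                        alt_reads=alt_reads,
                        total_reads=depth,
                        sample_id=s.sample_id,
                    )
                )
            variants[s.sample_id] = calls

    truth = GroundTruth(cases=truth_cases, samples={s.sample_id: s for s in samples})
    return SimulatedCohort(
        config=config,
        cases=cases,
        samples=samples,
        variants=variants,
        copy_numbers=copy_numbers,
        truth=truth,
    )


def expected_vaf(purity: float, ccf: float, tumor_cn: float, multiplicity: int = 1) -> float:
    """Expected allele fraction of a mutation in a bulk tumor sample.

    purity * ccf * multiplicity mutated copies over the copy-number-
    adjusted average ploidy at the locus (normal contamination is diploid).
    """
    denom = purity * tumor_cn + (1.0 - purity) * 2.0
    if denom <= 0:
        return 0.0
    return purity * ccf * multiplicity / denom


def noiseless(config: SyntheticConfig) -> SyntheticConfig:
    """Detection-free variant of a config: every true mutation is observed."""
    return replace(config, min_alt_reads=0, min_vaf=0.0)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """Write variant TSVs, manifest and CN table (text formats only)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(cohort.cases, cohort.samples, out / "manifest.yaml")
    for sid in sorted(cohort.variants):
        write_variants_tsv(cohort.variants[sid], out / f"{sid}.variants.tsv")
    write_table(
        (
            {"gene": r.gene, "sample_id": r.sample_id, "tumor_cn": r.tumor_cn,
             "normal_cn": r.normal_cn}
            for r in sorted(cohort.copy_numbers, key=lambda r: (r.sample_id, r.gene))
        ),
        ("gene", "sample_id", "tumor_cn", "normal_cn"),
        out / "copy_numbers.tsv",
    )


# ---------------------------------------------------------------------------
# Independent oracle: direct set enumeration over the clone algebra.
# Deliberately avoids the pipeline comparison modules.
# ---------------------------------------------------------------------------


def _pct(shared: int, total: int) -> int | None:
    if total == 0:
        return None
    return int(math.floor(Fraction(100 * shared, total) + Fraction(1, 2)))


def truth_statistics(truth: GroundTruth) -> dict:
    """Recompute every cohort summary straight from the clone assignments.

    Returns a dict with per-sample counts and shared fractions, per-case
    stable/emergent/lost gene partitions, and cross-case exclusivity —
    all computed with plain set operations on the ground truth.
    """
    per_sample_counts: dict[str, dict[str, int]] = {}
    per_sample_shared: dict[str, dict] = {}
    per_case: dict[str, dict] = {}

    for case_id, ct in truth.cases.items():
        sample_ids = list(ct.sample_clone_fractions)
        pre_ids = [s for s in sample_ids if truth.samples[s].timepoint == "pre"]
        post_ids = [s for s in sample_ids if truth.samples[s].timepoint == "post"]
        muts = {sid: ct.sample_mutations(sid) for sid in sample_ids}

        for sid in sample_ids:
            ms = muts[sid]
            exonic = [m for m in ms if m.region_class == "exonic"]
            nonsyn = [m for m in ms if m.is_nonsyn]
            per_sample_counts[sid] = {
                "total_somatic": len(ms),
                "exonic": len(exonic),
                "synonymous_snv": sum(
                    1 for m in exonic if m.exonic_function == "synonymous_SNV"
                ),
                "nonsynonymous_snv": sum(
                    1 for m in exonic if m.exonic_function == "nonsynonymous_SNV"
                ),
                "stop_gain_loss": sum(
                    1 for m in exonic if m.exonic_function in ("stopgain", "stoploss")
                ),
                "nonsyn_total": len(nonsyn),
                "nonsyn_gene_count": len({m.gene for m in nonsyn}),
            }

        nonsyn_keys = {
            sid: {m.key for m in muts[sid] if m.is_nonsyn} for sid in sample_ids
        }
        nonsyn_genes = {
            sid: {m.gene for m in muts[sid] if m.is_nonsyn} for sid in sample_ids
        }

        post_key_union: set = set().union(*(nonsyn_keys[s] for s in post_ids)) if post_ids else set()
        post_gene_union: set = set().union(*(nonsyn_genes[s] for s in post_ids)) if post_ids else set()
        pre_key_union: set = set().union(*(nonsyn_keys[s] for s in pre_ids)) if pre_ids else set()
        pre_gene_union: set = set().union(*(nonsyn_genes[s] for s in pre_ids)) if pre_ids else set()

        for sid in pre_ids:
            ks, gs = nonsyn_keys[sid], nonsyn_genes[sid]
            per_sample_shared[sid] = {
                "position": (len(ks & post_key_union), len(ks)),
                "gene": (len(gs & post_gene_union), len(gs)),
                "position_pct": _pct(len(ks & post_key_union), len(ks)),
                "gene_pct": _pct(len(gs & post_gene_union), len(gs)),
            }
        for sid in post_ids:
            ks, gs = nonsyn_keys[sid], nonsyn_genes[sid]
            per_sample_shared[sid] = {
                "position": (len(ks & pre_key_union), len(ks)),
                "gene": (len(gs & pre_gene_union), len(gs)),
                "position_pct": _pct(len(ks & pre_key_union), len(ks)),
                "gene_pct": _pct(len(gs & pre_gene_union), len(gs)),
            }

        per_case[case_id] = {
            "group": ct.group,
            "stable": frozenset(pre_gene_union & post_gene_union),
            "emergent": frozenset(post_gene_union - pre_gene_union),
            "lost": frozenset(pre_gene_union - post_gene_union),
            "pre_genes": frozenset(pre_gene_union),
            "post_genes": frozenset(post_gene_union),
            "any_genes": frozenset(pre_gene_union | post_gene_union),
        }

    resistant = [c for c, d in per_case.items() if d["group"] == "resistant"]
    sensitive = [c for c, d in per_case.items() if d["group"] == "sensitive"]
    all_genes: set[str] = set()
    for d in per_case.values():
        all_genes |= d["any_genes"]
    resistant_exclusive = frozenset(
        g
        for g in all_genes
        if sum(g in per_case[c]["any_genes"] for c in resistant) >= 2
        and all(g not in per_case[c]["any_genes"] for c in sensitive)
    )
    sensitive_exclusive = frozenset(
        g
        for g in all_genes
        if sensitive
        and all(g in per_case[c]["any_genes"] for c in sensitive)
        and all(g not in per_case[c]["any_genes"] for c in resistant)
    )

    return {
        "per_sample_counts": per_sample_counts,
        "per_sample_shared": per_sample_shared,
        "per_case": per_case,
        "resistant_exclusive": resistant_exclusive,
        "sensitive_exclusive": sensitive_exclusive,
    }
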