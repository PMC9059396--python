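# nactmut

Toolkit for comparing somatic mutation profiles in paired tumor samples
taken before and after neoadjuvant chemotherapy (NACT), as in
retrospective high-grade serous ovarian carcinoma cohorts with
platinum-resistant and platinum-sensitive cases.

It covers the full summary-level analysis of such a cohort:

- **cohort model** (`nactmut.cohort`) — case/sample metadata, platinum
  status from time to recurrence (resistant strictly under 6 months),
  CA-125 percent response, per-group outcome means.
- **variant I/O** (`nactmut.variants`) — reads annotated somatic calls
  from single-sample VCF 4.x with ANNOVAR-style INFO keys (configurable
  dialect) or a MAF-like TSV; allele normalization (uppercase, shared
  suffix then prefix trimming); multi-allelic splitting and multi-gene
  expansion; gene-level copy-number tables; deterministic TSV reports.
- **functional classification** (`nactmut.classify`) — per-sample count
  decomposition (total / exonic / synonymous / non-synonymous / stop
  gain-loss) and the non-synonymous exonic universe (nonsynonymous SNV,
  stopgain, stoploss) used by all comparisons.
- **overlap analysis** (`nactmut.overlap`) — pre/post shared fractions on
  a position basis (normalized chrom,pos,ref,alt key) or gene basis,
  with half-up integer percentages; per-case stable / emergent / lost
  gene partitions.
- **recurrence analysis** (`nactmut.recurrence`) — gene-by-case presence
  matrices under five strata (any, pre-only, post-only, stable-within-
  case, emergent-within-case), recurrently mutated genes, resistant- or
  sensitive-exclusive gene sets, emergent-set cross-referencing, and
  within-case multi-site Venn comparisons.
- **panel validation** (`nactmut.panel`) — five-criterion targeted-panel
  candidate selection, exome vs targeted-platform concordance records,
  and copy-number flags (amplified at >= 7 copies, loss at <= 1).
- **synthetic cohort** (`nactmut.simulate`) — clonal-evolution cohort
  generator: truncal + subclonal mutations, a treatment bottleneck that
  enriches a pre-existing minor clone in resistant cases, treatment- and
  site-private clones, purity/copy-number-aware expected allele
  fractions, binomial read sampling at configured depth, and detection
  thresholds. Ground truth is exact, and `truth_statistics` recomputes
  all summaries by independent set enumeration for oracle testing.
- **reference data** (`nactmut.refdata`) — summary numbers from a
  published five-case cohort (3 resistant, 2 sensitive; 11 exome
  samples) used by the tests and acceptance checks.

## Command line

```sh
# generate a synthetic cohort (deterministic per seed)
nactmut simulate --seed 7 --multisite-case 2 --out scratch/sim

# individual stages
nactmut summarize  --manifest scratch/sim/manifest.yaml --variants-dir scratch/sim --out scratch/results
nactmut overlap    --manifest scratch/sim/manifest.yaml --variants-dir scratch/sim --out scratch/results
nactmut recurrence --manifest scratch/sim/manifest.yaml --variants-dir scratch/sim --out scratch/results
nactmut sites      --manifest scratch/sim/manifest.yaml --variants-dir scratch/sim --case SIM3 --out scratch/results
nactmut panel      --manifest scratch/sim/manifest.yaml --variants-dir scratch/sim \
                   --cn-table scratch/sim/copy_numbers.tsv --out scratch/results

# or everything at once
nactmut all --manifest scratch/sim/manifest.yaml --variants-dir scratch/sim \
            --cn-table scratch/sim/copy_numbers.tsv --out scratch/results
```

Outputs are tab-separated with deterministic row order: `summary.tsv`,
`overlap.tsv`, `genestatus.tsv`, `presence_<stratum>.tsv`,
`exclusivity.tsv`, `recurrent.tsv`, `case_unique.tsv`, `venn.tsv`,
`panel.tsv`, `cnflags.tsv`.

### Cohort manifest

YAML with two sections; field names are fixed:

```yaml
cases:
  - case_id: case1
    stage: IIIa
    nact_cycles: 5
    total_cycles: 9
    ca125_pre: 81
    ca125_pct_decrease: 84
    residual_disease: none       # none | <=1cm | >1cm
    time_to_recurrence: 4.6      # months
    time_to_death_or_fu: 21.4    # months
    vital_status: DOD            # DOD | AWD (AWD = censored)
    platinum_status: resistant   # resistant | sensitive
samples:
  - sample_id: "1-1"
    case_id: case1
    timepoint: pre               # pre | post
    site: omentum
    platform: exome              # exome | targeted
    tumor_cellularity: 0.8
```

Variant TSV columns: `sample_id chrom pos ref alt gene region_class
exonic_function aa_change alt_reads total_reads` (1-based inclusive
coordinates). Copy-number TSV: `gene sample_id tumor_cn [normal_cn]`.

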