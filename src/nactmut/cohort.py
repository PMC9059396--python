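"""Case/sample metadata model and derived clinical quantities.

A cohort is a set of cases (one patient each) with paired tumor samples
taken before ("pre") and after ("post") neoadjuvant chemotherapy.
Platinum status is derived from time to recurrence; CA-125 biochemical
response is the percentage decrease from the pre-treatment level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import yaml

from nactmut._rounding import mean_1dp, round_half_up

PLATINUM_CUTOFF_MONTHS = 6.0

PlatinumStatus = Literal["resistant", "sensitive"]
Timepoint = Literal["pre", "post"]


@dataclass(frozen=True)
class CaseRecord:
    """One patient: staging, treatment, response and outcome metadata."""

    case_id: str
    stage: str = ""
    nact_cycles: int = 0
    total_cycles: int = 0
    ca125_pre: float | None = None
    ca125_pct_decrease: float | None = None
    residual_disease: str = ""  # one of "none", "<=1cm", ">1cm"
    time_to_recurrence: float | None = None
    time_to_death_or_fu: float | None = None
    vital_status: str = ""  # "DOD" dead of disease, "AWD" alive with disease
    platinum_status: PlatinumStatus | None = None

    def __post_init__(self) -> None:
        if self.total_cycles and self.nact_cycles > self.total_cycles:
            raise ValueError(
                f"case {self.case_id}: nact_cycles ({self.nact_cycles}) exceeds "
                f"total_cycles ({self.total_cycles})"
            )
        if self.time_to_recurrence is not None and self.time_to_recurrence < 0:
            raise ValueError(f"case {self.case_id}: negative time_to_recurrence")

    @property
    def censored(self) -> bool:
        """Alive-with-disease cases are censored for time-to-death."""
        return self.vital_status == "AWD"


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced tumor sample with its timepoint and tissue site."""

    sample_id: str
    case_id: str
    timepoint: Timepoint
    site: str = ""
    platform: str = "exome"  # "exome" or "targeted"
    tumor_cellularity: float = 0.8

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"sample {self.sample_id}: timepoint must be 'pre' or 'post'")
        if not (0.0 < self.tumor_cellularity <= 1.0):
            raise ValueError(f"sample {self.sample_id}: tumor_cellularity must be in (0, 1]")


def classify_platinum_status(
    time_to_recurrence: float, cutoff: float = PLATINUM_CUTOFF_MONTHS
) -> PlatinumStatus:
    """Classify a case from its time to recurrence in months.

    Resistant means recurrence strictly within ``cutoff`` months of
    first-line platinum chemotherapy; recurrence at the cutoff or later
    is sensitive.
    """
    if time_to_recurrence < 0:
        raise ValueError(f"time_to_recurrence must be >= 0, got {time_to_recurrence}")
    return "resistant" if time_to_recurrence < cutoff else "sensitive"


def ca125_response(pre_level: float, post_level: float) -> int:
    """Percentage decrease in CA-125 from pre- to post-treatment.

    Returns the nearest-integer percent decrease, 100 * (pre - post) / pre.
    A rise in CA-125 gives a negative value.
    """
    if pre_level <= 0:
        raise ValueError(f"pre_level must be > 0, got {pre_level}")
    if post_level < 0:
        raise ValueError(f"post_level must be >= 0, got {post_level}")
    pct = 100.0 * (pre_level - post_level) / pre_level
    return int(round_half_up(pct))


def cohort_summary(cases: Iterable[CaseRecord]) -> dict[str, dict[str, float]]:
    """Per-platinum-group means of time to recurrence and death/follow-up.

    Means are reported at one-decimal precision (half-up). Every group
    present in the cohort must have at least one case with the relevant
    time recorded.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("cohort_summary requires at least one case")
    out: dict[str, dict[str, float]] = {}
    for group in ("resistant", "sensitive"):
        members = [c for c in cases if c.platinum_status == group]
        if not members:
            continue
        ttr = [c.time_to_recurrence for c in members if c.time_to_recurrence is not None]
        ttd = [c.time_to_death_or_fu for c in members if c.time_to_death_or_fu is not None]
        if not ttr:
            raise ValueError(f"group '{group}' has no time_to_recurrence values")
        entry = {"n": float(len(members)), "mean_time_to_recurrence": mean_1dp(ttr)}
        if ttd:
            entry["mean_time_to_death_or_fu"] = mean_1dp(ttd)
        out[group] = entry
    if not out:
        raise ValueError("no case carries a platinum_status label")
    return out


# ---------------------------------------------------------------------------
# Manifest I/O
#
# The manifest is a YAML document:
#
#   cases:
#     - case_id: case1
#       stage: IIIa
#       ...
#   samples:
#     - sample_id: s1-1
#       case_id: case1
#       timepoint: pre
#       ...
# ---------------------------------------------------------------------------

_CASE_FIELDS = (
    "case_id stage nact_cycles total_cycles ca125_pre ca125_pct_decrease "
    "residual_disease time_to_recurrence time_to_death_or_fu vital_status "
    "platinum_status"
).split()
_SAMPLE_FIELDS = "sample_id case_id timepoint site platform tumor_cellularity".split()


def read_manifest(path: str | Path) -> tuple[list[CaseRecord], list[SampleRecord]]:
    """Load a cohort manifest; validates uniqueness and cross-references."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "cases" not in doc or "samples" not in doc:
        raise ValueError(f"manifest {path} must contain 'cases' and 'samples' sections")
    cases = [CaseRecord(**{k: v for k, v in row.items() if k in _CASE_FIELDS}) for row in doc["cases"]]
    samples = [
        SampleRecord(**{k: v for k, v in row.items() if k in _SAMPLE_FIELDS})
        for row in doc["samples"]
    ]
    case_ids = [c.case_id for c in cases]
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("duplicate case_id in manifest")
    sample_ids = [s.sample_id for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in manifest")
    known = set(case_ids)
    for s in samples:
        if s.case_id not in known:
            raise ValueError(f"sample {s.sample_id} references unknown case {s.case_id}")
    return cases, samples


def write_manifest(
    cases: Iterable[CaseRecord], samples: Iterable[SampleRecord], path: str | Path
) -> None:
    doc = {
        "cases": [
            {k: getattr(c, k) for k in _CASE_FIELDS if getattr(c, k) not in (None, "")}
            for c in cases
        ],
        "samples": [{k: getattr(s, k) for k in _SAMPLE_FIELDS} for s in samples],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
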