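"""The four-criterion rare-CNV filter.

A call is rare iff it
  (1) exceeds ``min_size_kb`` (strict >),
  (2) is supported by at least ``min_markers`` probes,
  (3) is NOT >= ``max_common_coverage`` covered by the union of same-dosage
      database records whose population frequency >= ``max_common_frequency``,
  (4) is absent from every control cohort (no same-dosage control call with
      50% reciprocal overlap).

Criterion (3) reads the published disjunction of rareness conditions as a
conjunction of commonness: a call is common only if it is both heavily
covered AND the covering records are themselves common in the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

from rarecnv.genome_model import (
    CnvCall,
    GenomicInterval,
    MarkerGrid,
    count_markers,
    coverage_fraction,
    overlap_bp,
)

REASON_CODES = (
    "fails_size",
    "fails_markers",
    "common_in_database",
    "seen_in_controls",
)


@dataclass(frozen=True)
class RareFilterParams:
    min_size_kb: float = 50.0
    min_markers: int = 25
    max_common_frequency: float = 0.001  # 1 per mille
    max_common_coverage: float = 0.50
    require_absent_from_controls: bool = True
    reciprocal_overlap: float = 0.50

    def __post_init__(self) -> None:
        if self.min_size_kb <= 0 or self.min_markers <= 0:
            raise ValueError("size and marker thresholds must be > 0")
        if not 0 < self.max_common_coverage <= 1:
            raise ValueError("coverage threshold must be in (0, 1]")
        if not 0 < self.max_common_frequency < 1:
            raise ValueError("frequency threshold must be in (0, 1)")


@dataclass(frozen=True)
class CommonCnvRecord:
    """A population CNV with dosage sign and carrier frequency."""

    interval: GenomicInterval
    dosage: str
    frequency: float

    def __post_init__(self) -> None:
        if self.dosage not in ("gain", "loss"):
            raise ValueError(f"dosage must be gain|loss, got {self.dosage!r}")
        if not 0 <= self.frequency <= 1:
            raise ValueError("frequency must be in [0, 1]")


@dataclass(frozen=True)
class FilterDecision:
    call: CnvCall
    reasons: frozenset

    def __post_init__(self) -> None:
        unknown = set(self.reasons) - set(REASON_CODES)
        if unknown:
            raise ValueError(f"unknown reason codes {unknown}")

    @property
    def rare(self) -> bool:
        return not self.reasons


def is_common_vs_database(
    call: CnvCall,
    db: Iterable[CommonCnvRecord],
    params: RareFilterParams = RareFilterParams(),
) -> bool:
    """True iff the call is >= 50% covered by the union of same-dosage
    records at population frequency >= 1 per mille (default thresholds)."""
    refs = [
        r.interval
        for r in db
        if r.dosage == call.dosage and r.frequency >= params.max_common_frequency
    ]
    if not refs:
        return False
    frac = coverage_fraction(call.interval, refs)
    return frac >= params.max_common_coverage


def reciprocal_overlap_ge(
    a: GenomicInterval, b: GenomicInterval, threshold: float
) -> bool:
    """True iff the intersection covers >= threshold of BOTH intervals."""
    ov = overlap_bp(a, b)
    if ov == 0:
        return False
    return ov >= threshold * a.length_bp and ov >= threshold * b.length_bp


def seen_in_controls(
    call: CnvCall,
    cohorts: Iterable[Sequence[CnvCall]],
    params: RareFilterParams = RareFilterParams(),
) -> bool:
    """True iff any control call of matching dosage has 50% reciprocal
    overlap with the query."""
    for cohort in cohorts:
        for ctrl in cohort:
            if ctrl.dosage != call.dosage:
                continue
            if reciprocal_overlap_ge(
                call.interval, ctrl.interval, params.reciprocal_overlap
            ):
                return True
    return False


def evaluate_call(
    call: CnvCall,
    db: Sequence[CommonCnvRecord],
    cohorts: Sequence[Sequence[CnvCall]],
    grid: MarkerGrid | None = None,
    params: RareFilterParams = RareFilterParams(),
) -> FilterDecision:
    reasons = set()
    if call.interval.length_kb <= params.min_size_kb:
        reasons.add("fails_size")
    n_markers = call.n_markers
    if n_markers is None:
        if grid is None:
            raise ValueError(
                f"call {call.sample_id} {call.interval} has no marker count "
                "and no marker grid was supplied"
            )
        n_markers = count_markers(call.interval, grid)
    if n_markers < params.min_markers:
        reasons.add("fails_markers")
    if is_common_vs_database(call, db, params):
        reasons.add("common_in_database")
    if params.require_absent_from_controls and seen_in_controls(
        call, cohorts, params
    ):
        reasons.add("seen_in_controls")
    return FilterDecision(call=call, reasons=frozenset(reasons))


def apply_rare_filter(
    calls: Sequence[CnvCall],
    db: Sequence[CommonCnvRecord] = (),
    cohorts: Sequence[Sequence[CnvCall]] = (),
    grid: MarkerGrid | None = None,
    params: RareFilterParams = RareFilterParams(),
) -> List[FilterDecision]:
    """One decision per call, in stable input order."""
    return [evaluate_call(c, db, cohorts, grid, params) for c in calls]


def rare_calls(decisions: Iterable[FilterDecision]) -> List[CnvCall]:
    return [d.call for d in decisions if d.rare]
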