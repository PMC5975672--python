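"""Five-criterion rare-variant exome filter.

Survivors satisfy all of:
  (1) located in an exonic or splicing region,
  (2) not synonymous (functional consequence),
  (3) population frequency < ``max_pop_freq`` in BOTH public databases
      (missing frequency treated as rare by default),
  (4) absent from both in-house control sets,
  (5) at least ``min_deleterious_calls`` predictor calls are deleterious.

The filter is a pure conjunction; the audit trail records the first failed
criterion for each reject.  Zygosity is carried for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        "nonsynonymous",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "nonframeshift_indel",
        "splice_site",
    }
)
NONFUNCTIONAL_CONSEQUENCES = frozenset({"synonymous"})
CONSEQUENCES = FUNCTIONAL_CONSEQUENCES | NONFUNCTIONAL_CONSEQUENCES

REGION_CLASSES = ("exonic", "splicing", "other")
CRITERIA = (
    "region",
    "functional",
    "population_frequency",
    "inhouse",
    "predictors",
)


@dataclass(frozen=True)
class WesVariant:
    gene: str
    region_class: str
    consequence: str
    freq_1000g: Optional[float] = None
    freq_exac: Optional[float] = None
    in_inhouse_controls: bool = False
    in_nonhtx_patients: bool = False
    predictor_calls: Mapping[str, str] = field(default_factory=dict)
    zygosity: str = "het"
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"region_class {self.region_class!r} not in {REGION_CLASSES}"
            )
        for f in (self.freq_1000g, self.freq_exac):
            if f is not None and not 0 <= f <= 1:
                raise ValueError(f"frequency {f} outside [0, 1]")
        for tool, call in self.predictor_calls.items():
            if call not in ("deleterious", "tolerated", "missing"):
                raise ValueError(
                    f"predictor call {call!r} from {tool!r}: expected "
                    "deleterious|tolerated|missing"
                )

    @property
    def n_deleterious(self) -> int:
        return sum(
            1 for c in self.predictor_calls.values() if c == "deleterious"
        )


@dataclass(frozen=True)
class VariantFilterParams:
    max_pop_freq: float = 0.001  # 0.1%
    min_deleterious_calls: int = 1
    missing_freq_is_rare: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.max_pop_freq < 1:
            raise ValueError("max_pop_freq must be in (0, 1)")
        if self.min_deleterious_calls < 1:
            raise ValueError("min_deleterious_calls must be >= 1")


def is_functional(v: WesVariant) -> bool:
    """True for consequences in the functional-mutation vocabulary."""
    if v.consequence not in CONSEQUENCES:
        raise ValueError(
            f"unknown consequence {v.consequence!r}; accepted: "
            f"{sorted(CONSEQUENCES)}"
        )
    return v.consequence in FUNCTIONAL_CONSEQUENCES


def _freq_rare(freq: Optional[float], params: VariantFilterParams) -> bool:
    if freq is None:
        return params.missing_freq_is_rare
    return freq < params.max_pop_freq


def first_failed_criterion(
    v: WesVariant, params: VariantFilterParams = VariantFilterParams()
) -> Optional[str]:
    """The first violated criterion in printed order, or None for survivors."""
    if v.region_class not in ("exonic", "splicing"):
        return "region"
    if not is_functional(v):
        return "functional"
    if not (_freq_rare(v.freq_1000g, params) and _freq_rare(v.freq_exac, params)):
        return "population_frequency"
    if v.in_inhouse_controls or v.in_nonhtx_patients:
        return "inhouse"
    if v.n_deleterious < params.min_deleterious_calls:
        return "predictors"
    return None


def apply_variant_filter(
    variants: Sequence[WesVariant],
    params: VariantFilterParams = VariantFilterParams(),
) -> Tuple[List[WesVariant], List[Tuple[WesVariant, str]]]:
    """Returns (survivors, rejects-with-first-failed-criterion)."""
    survivors: List[WesVariant] = []
    rejects: List[Tuple[WesVariant, str]] = []
    for v in variants:
        failed = first_failed_criterion(v, params)
        if failed is None:
            survivors.append(v)
        else:
            rejects.append((v, failed))
    return survivors, rejects
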