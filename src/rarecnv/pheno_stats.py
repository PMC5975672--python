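"""Contingency statistics for laterality assays and cohort summaries.

Phenotype counts are scored against a control group by collapsing to a 2x2
abnormal/normal table (the first category of each scheme is normal) and
testing with the Yates continuity-corrected chi-squared test, falling back
to Fisher's exact test whenever any expected cell is below 5.  Significance
stars follow the 0.05 / 0.01 / 0.001 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

#: Category schemes; the first category is the normal phenotype.
SCHEMES: Dict[str, Tuple[str, ...]] = {
    "looping": ("d_loop", "s_loop", "no_loop"),
    "expression": ("left", "right", "bilateral", "absent"),
}

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeCounts:
    group: str
    scheme: str
    counts: Mapping[str, int]
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise StatsError(f"unknown scheme {self.scheme!r}")
        cats = SCHEMES[self.scheme]
        unknown = set(self.counts) - set(cats)
        if unknown:
            raise StatsError(f"categories {unknown} not in scheme {self.scheme}")
        if any(c < 0 for c in self.counts.values()):
            raise StatsError("counts must be non-negative")
        object.__setattr__(
            self, "counts", {c: int(self.counts.get(c, 0)) for c in cats}
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_abnormal(self) -> int:
        normal = SCHEMES[self.scheme][0]
        return self.total - self.counts[normal]


@dataclass(frozen=True)
class CountTable2x2:
    """Rows: (treated, control); columns: (abnormal, normal)."""

    treated_abnormal: int
    treated_normal: int
    control_abnormal: int
    control_normal: int

    def __post_init__(self) -> None:
        if min(self.cells.ravel()) < 0:
            raise StatsError("cell counts must be non-negative")

    @property
    def cells(self) -> np.ndarray:
        return np.array(
            [
                [self.treated_abnormal, self.treated_normal],
                [self.control_abnormal, self.control_normal],
            ],
            dtype=np.int64,
        )

    @property
    def n(self) -> int:
        return int(self.cells.sum())


@dataclass(frozen=True)
class TestResult:
    test_used: str  # chi2_yates | fisher
    p_value: float
    statistic: Optional[float] = None

    @property
    def stars(self) -> str:
        for threshold, label in STAR_THRESHOLDS:
            if self.p_value < threshold:
                return label
        return "ns"


def pool_replicates(groups: Iterable[PhenotypeCounts]) -> PhenotypeCounts:
    """Sum per-replicate counts of one group into a single record."""
    groups = list(groups)
    if not groups:
        raise StatsError("no counts to pool")
    scheme = groups[0].scheme
    name = groups[0].group
    if any(g.scheme != scheme for g in groups):
        raise StatsError("cannot pool across schemes")
    if any(g.group != name for g in groups):
        raise StatsError("cannot pool across groups")
    pooled = {
        c: sum(g.counts[c] for g in groups) for c in SCHEMES[scheme]
    }
    return PhenotypeCounts(group=name, scheme=scheme, counts=pooled, replicate=0)


def collapse_to_2x2(
    treated: PhenotypeCounts, control: PhenotypeCounts
) -> CountTable2x2:
    """Abnormal = sum of all non-first categories of the shared scheme."""
    if treated.scheme != control.scheme:
        raise StatsError(
            f"scheme mismatch: {treated.scheme} vs {control.scheme}"
        )
    normal = SCHEMES[treated.scheme][0]
    return CountTable2x2(
        treated_abnormal=treated.n_abnormal,
        treated_normal=treated.counts[normal],
        control_abnormal=control.n_abnormal,
        control_normal=control.counts[normal],
    )


def fisher_exact_2x2(t: CountTable2x2) -> TestResult:
    """Two-sided Fisher's exact test (point-probability method)."""
    if t.n == 0:
        raise StatsError("all-zero table")
    res = stats.fisher_exact(t.cells, alternative="two-sided")
    return TestResult(test_used="fisher", p_value=float(res.pvalue))


def chi2_yates_2x2(t: CountTable2x2) -> TestResult:
    """Continuity-corrected chi-squared statistic with 1 df.

    statistic = N * (max(|ad - bc| - N/2, 0))^2 / (r1 * r2 * c1 * c2)
    """
    a, b = t.treated_abnormal, t.treated_normal
    c, d = t.control_abnormal, t.control_normal
    n = t.n
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise StatsError("chi-squared test requires all margins > 0")
    delta = max(abs(a * d - b * c) - n / 2.0, 0.0)
    statistic = n * delta * delta / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(test_used="chi2_yates", p_value=p, statistic=statistic)


def expected_cells(t: CountTable2x2) -> np.ndarray:
    cells = t.cells
    return np.outer(cells.sum(axis=1), cells.sum(axis=0)) / cells.sum()


def run_test_2x2(t: CountTable2x2) -> TestResult:
    """Fisher when any expected cell < 5, otherwise Yates chi-squared."""
    if t.n == 0 or min(t.cells.sum(axis=0)) == 0 or min(t.cells.sum(axis=1)) == 0:
        return fisher_exact_2x2(t)
    if (expected_cells(t) < 5).any():
        return fisher_exact_2x2(t)
    return chi2_yates_2x2(t)


def compare_groups(
    treated: PhenotypeCounts | Sequence[PhenotypeCounts],
    control: PhenotypeCounts | Sequence[PhenotypeCounts],
    pool: bool = True,
) -> TestResult:
    """Collapse (optionally pooling replicates) and run the selected test."""
    if not isinstance(treated, PhenotypeCounts):
        treated = pool_replicates(treated) if pool else treated[0]
    if not isinstance(control, PhenotypeCounts):
        control = pool_replicates(control) if pool else control[0]
    return run_test_2x2(collapse_to_2x2(treated, control))


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """Half-up rounded percentage, the convention of printed cohort tables."""
    if denominator <= 0:
        raise StatsError("denominator must be > 0")
    if count > denominator:
        raise StatsError(f"count {count} exceeds denominator {denominator}")
    if count < 0:
        raise StatsError("count must be >= 0")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(count) * 100 / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def summarize_cohort(
    records: Mapping[str, int], denominator: int
) -> Dict[str, Tuple[int, float]]:
    """Label -> (count, percent of denominator to 1 decimal)."""
    return {
        label: (count, percent(count, denominator))
        for label, count in records.items()
    }


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """Optional FDR adjustment (off by default in all report paths)."""
    return list(stats.false_discovery_control(p_values, method="bh"))
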