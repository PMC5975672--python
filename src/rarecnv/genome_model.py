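"""Core coordinate conventions and interval algebra.

Coordinates are stored as printed in their source tables (1-based,
hg19-style).  Segment length is defined as ``end - start`` (no +1), and
marker counting uses the half-open ``[start, end)`` convention so that the
two definitions agree.  Chromosome labels are normalized at construction
("chr1" and "1" compare equal).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple


class IntervalError(ValueError):
    """Raised for malformed genomic intervals or calls."""


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label: strip whitespace and any 'chr' prefix.

    >>> normalize_chrom("chr1")
    '1'
    >>> normalize_chrom(" X ")
    'X'
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if not c:
        raise IntervalError("chromosome label must be non-empty")
    return c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located segment with ``end >= start``; length is ``end - start``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end < self.start:
            raise IntervalError(
                f"end < start for interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise IntervalError("coordinates must be non-negative")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def dosage_of(copy_number: int) -> str:
    """Map a copy number to its dosage sign ('loss' below 2, 'gain' above)."""
    if copy_number == 2:
        raise IntervalError("copy number 2 is diploid, not a CNV")
    if copy_number < 0:
        raise IntervalError("copy number must be >= 0")
    return "loss" if copy_number < 2 else "gain"


@dataclass(frozen=True)
class CnvCall:
    """A copy-number call: interval + copy number + marker support + sample."""

    interval: GenomicInterval
    copy_number: int
    sample_id: str
    n_markers: int | None = None

    def __post_init__(self) -> None:
        dosage_of(self.copy_number)  # validates
        if self.n_markers is not None and self.n_markers < 0:
            raise IntervalError("n_markers must be >= 0")

    @property
    def dosage(self) -> str:
        return dosage_of(self.copy_number)


@dataclass
class MarkerGrid:
    """Per-chromosome sorted probe positions (bp)."""

    positions: Dict[str, List[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: Dict[str, List[int]] = {}
        for chrom, pos in self.positions.items():
            pos = sorted(int(p) for p in pos)
            for a, b in zip(pos, pos[1:]):
                if a == b:
                    raise IntervalError(
                        f"duplicate probe position {a} on chromosome {chrom}"
                    )
            norm[normalize_chrom(chrom)] = pos
        self.positions = norm

    @property
    def n_probes(self) -> int:
        return sum(len(p) for p in self.positions.values())


def length_bp(iv: GenomicInterval) -> int:
    """Segment length in bp under the ``end - start`` convention."""
    return iv.length_bp


def length_kb(iv: GenomicInterval) -> float:
    """Segment length in kbp (bp / 1000), reported to 3 decimals downstream."""
    return iv.length_kb


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of two intervals; 0 if disjoint or on
    different chromosomes.  Symmetric in its arguments."""
    if a.chrom != b.chrom:
        return 0
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0, hi - lo)


def _merge(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of (start, end) pairs as a sorted list of disjoint pairs."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            prev_s, prev_e = merged[-1]
            merged[-1] = (prev_s, max(prev_e, e))
        else:
            merged.append((s, e))
    return merged


def coverage_fraction(
    query: GenomicInterval, refs: Iterable[GenomicInterval]
) -> float:
    """Fraction of ``query`` covered by the union of ``refs`` (same chromosome).

    Raises for zero-length queries, where the fraction is undefined.
    """
    if query.length_bp == 0:
        raise IntervalError("coverage fraction undefined for zero-length query")
    clipped = []
    for r in refs:
        if r.chrom != query.chrom:
            continue
        s = max(r.start, query.start)
        e = min(r.end, query.end)
        if e > s:
            clipped.append((s, e))
    covered = sum(e - s for s, e in _merge(clipped))
    return covered / query.length_bp


def count_markers(iv: GenomicInterval, grid: MarkerGrid) -> int:
    """Number of probe positions p with ``start <= p < end``."""
    pos = grid.positions.get(iv.chrom)
    if not pos:
        return 0
    lo = bisect.bisect_left(pos, iv.start)
    hi = bisect.bisect_left(pos, iv.end)
    return hi - lo


def genomic_sort_key(chrom: str) -> Tuple[int, str]:
    """Order chromosomes numerically where possible (1..22, X, Y, MT, rest)."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (special.get(c.upper(), 26), c)
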