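"""Classify CNV calls against gene models and enumerate altered genes.

Classes:
  genic_del    loss overlapping >= 1 coding exon of any gene
  genic_dup    gain fully containing >= 1 gene span
  internal_dup gain overlapping >= 1 coding exon without containing a gene
  noncoding    anything else

"Full duplication" is tested against the gene span (transcription unit),
not coding exons, so non-coding RNA genes count.  genic_dup takes
precedence over internal_dup when a gain contains one gene and partially
covers another.  Strand is carried but ignored: dosage events are
strand-agnostic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

from rarecnv.genome_model import (
    CnvCall,
    GenomicInterval,
    IntervalError,
    overlap_bp,
)

IMPACT_CLASSES = ("genic_del", "genic_dup", "internal_dup", "noncoding")


@dataclass(frozen=True)
class GeneModel:
    """Gene span plus sorted, non-overlapping coding exon intervals."""

    symbol: str
    span: GenomicInterval
    strand: str = "+"
    coding_exons: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted(self.coding_exons, key=lambda e: (e.start, e.end)))
        for e in exons:
            if e.chrom != self.span.chrom:
                raise ValueError(f"exon of {self.symbol} on wrong chromosome")
            if e.start < self.span.start or e.end > self.span.end:
                raise ValueError(f"exon of {self.symbol} outside gene span")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping coding exons in {self.symbol}")
        object.__setattr__(self, "coding_exons", exons)


@dataclass(frozen=True)
class GenicImpact:
    call: CnvCall
    impact_class: str
    genes_altered: tuple

    def __post_init__(self) -> None:
        if self.impact_class not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact_class!r}")


def _by_chrom(genes: Iterable[GeneModel]) -> Dict[str, List[GeneModel]]:
    out: Dict[str, List[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.span.chrom, []).append(g)
    for lst in out.values():
        lst.sort(key=lambda g: (g.span.start, g.span.end, g.symbol))
    return out


def genes_altered(call: CnvCall, genes: Iterable[GeneModel]) -> List[str]:
    """Symbols of all genes whose span overlaps the call, in genomic order."""
    iv = call.interval
    hits = [
        g
        for g in _by_chrom(genes).get(iv.chrom, [])
        if overlap_bp(iv, g.span) > 0
    ]
    return [g.symbol for g in hits]


def _hits_coding_exon(iv: GenomicInterval, gene: GeneModel) -> bool:
    return any(overlap_bp(iv, e) > 0 for e in gene.coding_exons)


def _contains(iv: GenomicInterval, span: GenomicInterval) -> bool:
    return (
        iv.chrom == span.chrom and iv.start <= span.start and span.end <= iv.end
    )


def classify_cnv(call: CnvCall, genes: Iterable[GeneModel]) -> GenicImpact:
    """Assign the impact class of a single call (total and exclusive)."""
    iv = call.interval
    chrom_genes = _by_chrom(genes).get(iv.chrom, [])
    overlapping = [g for g in chrom_genes if overlap_bp(iv, g.span) > 0]
    symbols = tuple(g.symbol for g in overlapping)

    if call.dosage == "loss":
        if any(_hits_coding_exon(iv, g) for g in overlapping):
            cls = "genic_del"
        else:
            cls = "noncoding"
    else:
        if any(_contains(iv, g.span) for g in overlapping):
            cls = "genic_dup"
        elif any(_hits_coding_exon(iv, g) for g in overlapping):
            cls = "internal_dup"
        else:
            cls = "noncoding"
    return GenicImpact(call=call, impact_class=cls, genes_altered=symbols)


def classify_all(
    calls: Sequence[CnvCall], genes: Iterable[GeneModel]
) -> List[GenicImpact]:
    gene_list = list(genes)
    return [classify_cnv(c, gene_list) for c in calls]


def tabulate_classes(impacts: Iterable[GenicImpact | str]) -> Dict[str, int]:
    """Histogram of impact classes; accepts impacts or bare class labels."""
    counts = Counter()
    for item in impacts:
        label = item if isinstance(item, str) else item.impact_class
        if label not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {label!r}")
        counts[label] += 1
    return {cls: counts.get(cls, 0) for cls in IMPACT_CLASSES}
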