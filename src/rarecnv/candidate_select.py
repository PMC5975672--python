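"""Candidate-gene prioritization within rare CNVs.

Genes altered by a rare CNV become candidates when they belong to at least
one curated set: ciliary proteome/function, a laterality signaling pathway
(Notch, Nodal, Hedgehog, Wnt, TGF-beta), or the E3 ubiquitin ligase family.
The criteria are a union; every matching criterion is recorded.  A separate
screen intersects altered genes with the known laterality-gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from rarecnv.genic_impact import GenicImpact

PATHWAY_TAGS = ("Notch", "Nodal", "Hedgehog", "Wnt", "TGF-beta")

#: Laterality genes with previously reported mutations, screened to exclude
#: known causes before any call is labelled novel.
DEFAULT_KNOWN_GENES = frozenset(
    {
        "ZIC3",
        "CFC1",
        "NKX2.5",
        "GDF1",
        "NODAL",
        "LEFTY1",
        "LEFTY2",
        "ACVR2B",
        "DNAH5",
        "DNAH11",
        "DNAI1",
        "FOXH1",
        "CRELD1",
        "GALNT11",
    }
)


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class CuratedGeneSets:
    """Configuration gene sets; symbols are uppercase-normalized on load."""

    cilia_genes: Set[str] = field(default_factory=set)
    lr_pathway_genes: Dict[str, str] = field(default_factory=dict)  # symbol -> pathway
    e3_ligase_genes: Set[str] = field(default_factory=set)
    known_htx_genes: Set[str] = field(default_factory=lambda: set(DEFAULT_KNOWN_GENES))
    aliases: Dict[str, str] = field(default_factory=dict)  # alias -> canonical

    def __post_init__(self) -> None:
        self.cilia_genes = {normalize_symbol(s) for s in self.cilia_genes}
        self.lr_pathway_genes = {
            normalize_symbol(s): p for s, p in self.lr_pathway_genes.items()
        }
        self.e3_ligase_genes = {normalize_symbol(s) for s in self.e3_ligase_genes}
        self.known_htx_genes = {normalize_symbol(s) for s in self.known_htx_genes}
        self.aliases = {
            normalize_symbol(a): normalize_symbol(c)
            for a, c in self.aliases.items()
        }
        bad = set(self.lr_pathway_genes.values()) - set(PATHWAY_TAGS)
        if bad:
            raise ValueError(f"unknown pathway tags {bad}; expected {PATHWAY_TAGS}")

    def canonical(self, symbol: str) -> str:
        s = normalize_symbol(symbol)
        return self.aliases.get(s, s)

    def criteria_for(self, symbol: str) -> Tuple[str, ...]:
        """All prioritization criteria hit by a symbol, in fixed order."""
        s = self.canonical(symbol)
        hits: List[str] = []
        if s in self.cilia_genes:
            hits.append("cilia")
        if s in self.lr_pathway_genes:
            hits.append(f"pathway:{self.lr_pathway_genes[s]}")
        if s in self.e3_ligase_genes:
            hits.append("e3_ligase")
        return tuple(hits)


@dataclass(frozen=True)
class CandidateGene:
    symbol: str
    criteria_hit: Tuple[str, ...]
    source_cnv: GenicImpact
    patient_id: str

    def __post_init__(self) -> None:
        if not self.criteria_hit:
            raise ValueError("candidate must hit at least one criterion")


def screen_known_genes(
    impacts: Iterable[GenicImpact], sets: CuratedGeneSets
) -> Dict[str, List[GenicImpact]]:
    """Known laterality genes found among altered genes, with provenance."""
    found: Dict[str, List[GenicImpact]] = {}
    for imp in impacts:
        for sym in imp.genes_altered:
            canon = sets.canonical(sym)
            if canon in sets.known_htx_genes:
                found.setdefault(canon, []).append(imp)
    return found


def select_candidates(
    impacts: Sequence[GenicImpact], sets: CuratedGeneSets
) -> List[CandidateGene]:
    """Candidates among genes altered by rare CNVs, ordered by (patient,
    CNV position, gene position within the CNV)."""
    ordered = sorted(
        impacts,
        key=lambda i: (
            str(i.call.sample_id),
            i.call.interval.chrom,
            i.call.interval.start,
        ),
    )
    out: List[CandidateGene] = []
    for imp in ordered:
        for sym in imp.genes_altered:  # already in genomic order
            criteria = sets.criteria_for(sym)
            if criteria:
                out.append(
                    CandidateGene(
                        symbol=sets.canonical(sym),
                        criteria_hit=criteria,
                        source_cnv=imp,
                        patient_id=str(imp.call.sample_id),
                    )
                )
    return out


def summarize_candidates(candidates: Sequence[CandidateGene]) -> Dict[str, int]:
    """Counts the text reports: distinct genes, source CNVs, patients."""
    segments = {
        (c.patient_id, c.source_cnv.call.interval) for c in candidates
    }
    return {
        "n_candidate_genes": len({c.symbol for c in candidates}),
        "n_cnv_segments": len(segments),
        "n_patients": len({c.patient_id for c in candidates}),
    }
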