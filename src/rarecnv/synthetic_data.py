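"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of a :class:`SimConfig`, so a seed fully
determines its output.  CNV call sets come with ground-truth labels: spike-in
rare calls are labelled ``rare`` and each decoy violates exactly one filter
criterion, so reason codes are individually testable downstream.

Marker counts travel on the calls themselves (as in array segmentation
exports); the under-markered decoy is realised by its reported count, not by
thinning the probe grid underneath it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from rarecnv.cnv_rarity import CommonCnvRecord
from rarecnv.genic_impact import GeneModel
from rarecnv.genome_model import (
    CnvCall,
    GenomicInterval,
    MarkerGrid,
    count_markers,
)
from rarecnv.pheno_stats import SCHEMES, PhenotypeCounts
from rarecnv.wes_filter import (
    CONSEQUENCES,
    FUNCTIONAL_CONSEQUENCES,
    WesVariant,
)

TRUTH_LABELS = (
    "rare",
    "fails_size",
    "fails_markers",
    "common_in_database",
    "seen_in_controls",
)

PREDICTOR_TOOLS = ("sift", "polyphen2", "mutation_taster")


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    marker_spacing_bp: int = 1_000
    n_genes: int = 40
    exons_per_gene: Tuple[int, int] = (2, 20)
    n_common_cnvs: int = 8
    common_freq_range: Tuple[float, float] = (0.01, 0.05)
    n_samples: int = 6
    spike_in_rare_cnvs: List[Tuple[GenomicInterval, int, str]] = field(
        default_factory=list
    )  # (interval, copy_number, sample_id)
    n_decoys_per_kind: int = 1
    n_variants: int = 50
    planted_qualifying_variants: int = 4
    phenotype_scheme: str = "looping"
    phenotype_probs: Dict[str, Sequence[float]] = field(default_factory=dict)
    n_embryos_per_group: int = 80
    n_replicates: int = 3
    carrier_frequency: bool = True  # database frequencies are carrier fractions

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "marker_spacing_bp",
            "n_genes",
            "n_common_cnvs",
            "n_samples",
            "n_variants",
            "planted_qualifying_variants",
            "n_embryos_per_group",
            "n_replicates",
            "n_decoys_per_kind",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.exons_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("exons_per_gene range must satisfy 1 <= lo <= hi")
        n_cats = len(SCHEMES[self.phenotype_scheme])
        for group, probs in self.phenotype_probs.items():
            if len(probs) != n_cats:
                raise ValueError(
                    f"group {group}: expected {n_cats} category probabilities"
                )
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"group {group}: probabilities must sum to 1")

    @property
    def chromosomes(self) -> List[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]


@dataclass
class CnvTruth:
    """A generated call plus the label the rarity filter should recover."""

    call: CnvCall
    label: str

    def __post_init__(self) -> None:
        if self.label not in TRUTH_LABELS:
            raise ValueError(f"unknown truth label {self.label!r}")


@dataclass
class CnvBundle:
    calls: List[CnvCall]
    common_db: List[CommonCnvRecord]
    control_cohorts: List[List[CnvCall]]
    truth: List[CnvTruth]


def gen_genome(cfg: SimConfig) -> Tuple[MarkerGrid, List[GeneModel]]:
    """Probe grid with exponential gaps plus non-overlapping gene models."""
    rng = np.random.default_rng([cfg.seed, 1])
    positions: Dict[str, List[int]] = {}
    for chrom in cfg.chromosomes:
        n_expect = cfg.chrom_length_bp // cfg.marker_spacing_bp
        gaps = rng.exponential(cfg.marker_spacing_bp, size=int(n_expect * 1.5) + 10)
        gaps = np.maximum(1, np.round(gaps)).astype(np.int64)
        pos = np.cumsum(gaps)
        positions[chrom] = pos[pos < cfg.chrom_length_bp].tolist()
    grid = MarkerGrid(positions=positions)

    genes: List[GeneModel] = []
    if cfg.n_genes:
        per_chrom = _split_evenly(cfg.n_genes, cfg.n_chromosomes)
        for chrom, n in zip(cfg.chromosomes, per_chrom):
            if n == 0:
                continue
            slot = cfg.chrom_length_bp // n
            if slot < 4_000:
                raise ValueError(
                    f"cannot pack {n} genes into {cfg.chrom_length_bp} bp on "
                    f"chromosome {chrom}"
                )
            for i in range(n):
                lo = i * slot
                span_len = int(rng.integers(slot // 4, slot // 2))
                start = int(rng.integers(lo + 1, lo + slot - span_len))
                end = start + span_len
                n_exons = int(
                    rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1)
                )
                exons = _draw_exons(rng, chrom, start, end, n_exons)
                genes.append(
                    GeneModel(
                        symbol=f"G{chrom}_{i:03d}",
                        span=GenomicInterval(chrom, start, end),
                        strand="+" if rng.random() < 0.5 else "-",
                        coding_exons=tuple(exons),
                    )
                )
    return grid, genes


def _split_evenly(total: int, parts: int) -> List[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _draw_exons(
    rng: np.random.Generator, chrom: str, start: int, end: int, n_exons: int
) -> List[GenomicInterval]:
    span = end - start
    # partition the span into 2*n_exons+1 blocks; odd blocks become exons
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons, replace=False))
    exons = []
    for k in range(n_exons):
        s = start + int(cuts[2 * k])
        e = start + int(cuts[2 * k + 1])
        if e > s:
            exons.append(GenomicInterval(chrom, s, e))
    if not exons:  # degenerate draw; force a single mid-span exon
        mid = start + span // 2
        exons = [GenomicInterval(chrom, mid, min(mid + 10, end))]
    return exons


def _call(
    grid: MarkerGrid,
    iv: GenomicInterval,
    copy_number: int,
    sample_id: str,
    n_markers: Optional[int] = None,
) -> CnvCall:
    if n_markers is None:
        n_markers = count_markers(iv, grid)
    return CnvCall(
        interval=iv,
        copy_number=copy_number,
        sample_id=sample_id,
        n_markers=n_markers,
    )


def gen_cnv_callset(cfg: SimConfig, grid: MarkerGrid) -> CnvBundle:
    """Common background CNVs, spike-in rare calls, and per-criterion decoys.

    Layout: each chromosome is divided into fixed slots; commons and decoys
    occupy slots that do not intersect any spike-in, so every generated call
    violates exactly the criterion its label names (margins well clear of the
    thresholds).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    spike_ivs = [iv for iv, _, _ in cfg.spike_in_rare_cnvs]
    for iv in spike_ivs:
        if iv.chrom not in cfg.chromosomes or iv.end > cfg.chrom_length_bp:
            raise ValueError(f"spike-in {iv} outside the simulated genome")

    slot_w = 400_000
    free_slots: List[GenomicInterval] = []
    for chrom in cfg.chromosomes:
        for s in range(0, cfg.chrom_length_bp - slot_w, slot_w):
            slot = GenomicInterval(chrom, s + 50_000, s + slot_w - 50_000)
            if all(
                iv.chrom != slot.chrom or iv.end <= slot.start or slot.end <= iv.start
                for iv in spike_ivs
            ):
                free_slots.append(slot)
    n_needed = cfg.n_common_cnvs + 4 * cfg.n_decoys_per_kind
    if n_needed > len(free_slots):
        raise ValueError("genome too small for requested commons and decoys")
    chosen = rng.choice(len(free_slots), size=n_needed, replace=False)
    slots = [free_slots[i] for i in chosen]

    samples = [f"S{i+1:02d}" for i in range(cfg.n_samples)]
    calls: List[CnvCall] = []
    truth: List[CnvTruth] = []
    common_db: List[CommonCnvRecord] = []

    # spike-ins, verbatim
    for iv, cn, sample_id in cfg.spike_in_rare_cnvs:
        c = _call(grid, iv, cn, sample_id)
        calls.append(c)
        truth.append(CnvTruth(call=c, label="rare"))

    lo_f, hi_f = cfg.common_freq_range
    common_slots = slots[: cfg.n_common_cnvs]
    decoy_slots = slots[cfg.n_common_cnvs :]

    # background common CNVs, mirrored into the database and carried by a sample
    for k, slot in enumerate(common_slots):
        size = int(rng.integers(80_000, 250_000))
        start = int(rng.integers(slot.start, slot.end - size))
        iv = GenomicInterval(slot.chrom, start, start + size)
        cn = int(rng.choice([1, 3]))
        freq = float(rng.uniform(max(lo_f, 0.0011), max(hi_f, 0.0012)))
        dosage = "loss" if cn < 2 else "gain"
        common_db.append(
            CommonCnvRecord(interval=iv, dosage=dosage, frequency=freq)
        )
        carrier = samples[k % len(samples)] if samples else "S01"
        c = _call(grid, iv, cn, carrier)
        calls.append(c)
        truth.append(CnvTruth(call=c, label="common_in_database"))

    control_cohorts: List[List[CnvCall]] = [[], []]
    it = iter(decoy_slots)
    for _ in range(cfg.n_decoys_per_kind):
        # fails_size: 45 kb, plenty of markers, nothing in db or controls
        slot = next(it)
        iv = GenomicInterval(slot.chrom, slot.start, slot.start + 45_000)
        c = _call(grid, iv, 1, samples[0] if samples else "S01")
        calls.append(c)
        truth.append(CnvTruth(call=c, label="fails_size"))

        # fails_markers: 120 kb but only 10 reported markers
        slot = next(it)
        iv = GenomicInterval(slot.chrom, slot.start, slot.start + 120_000)
        c = _call(grid, iv, 3, samples[0] if samples else "S01", n_markers=10)
        calls.append(c)
        truth.append(CnvTruth(call=c, label="fails_markers"))

        # common_in_database: fully inside a high-frequency same-dosage record
        slot = next(it)
        iv = GenomicInterval(slot.chrom, slot.start + 10_000, slot.start + 110_000)
        rec_iv = GenomicInterval(slot.chrom, slot.start, slot.start + 150_000)
        common_db.append(
            CommonCnvRecord(interval=rec_iv, dosage="gain", frequency=0.02)
        )
        c = _call(grid, iv, 3, samples[0] if samples else "S01")
        calls.append(c)
        truth.append(CnvTruth(call=c, label="common_in_database"))

        # seen_in_controls: identical call present in a control cohort
        slot = next(it)
        iv = GenomicInterval(slot.chrom, slot.start, slot.start + 100_000)
        c = _call(grid, iv, 1, samples[0] if samples else "S01")
        calls.append(c)
        truth.append(CnvTruth(call=c, label="seen_in_controls"))
        control_cohorts[0].append(_call(grid, iv, 1, "CTRL01"))

    return CnvBundle(
        calls=calls,
        common_db=common_db,
        control_cohorts=control_cohorts,
        truth=truth,
    )


def gen_wes_variants(cfg: SimConfig) -> Tuple[List[WesVariant], List[bool]]:
    """Annotated variant table with exactly ``planted_qualifying_variants``
    records passing the five-criterion filter; returns (variants, truth)."""
    rng = np.random.default_rng([cfg.seed, 3])
    if cfg.planted_qualifying_variants > cfg.n_variants:
        raise ValueError("cannot plant more qualifying variants than variants")
    variants: List[WesVariant] = []
    truth: List[bool] = []
    n_plant = cfg.planted_qualifying_variants
    consequences = sorted(CONSEQUENCES)
    functional = sorted(FUNCTIONAL_CONSEQUENCES)

    for i in range(cfg.n_variants):
        gene = f"G{int(rng.integers(0, max(cfg.n_genes, 1))):03d}"
        if i < n_plant:
            v = WesVariant(
                gene=gene,
                region_class=str(rng.choice(["exonic", "splicing"])),
                consequence=str(rng.choice(functional)),
                freq_1000g=None if rng.random() < 0.3 else float(rng.uniform(0, 0.0009)),
                freq_exac=None if rng.random() < 0.3 else float(rng.uniform(0, 0.0009)),
                in_inhouse_controls=False,
                in_nonhtx_patients=False,
                predictor_calls=_draw_predictors(rng, min_deleterious=1),
                zygosity="het",
                variant_id=f"V{i:04d}",
            )
            qualifies = True
        else:
            v = _random_variant(rng, gene, f"V{i:04d}")
            v = _spoil_if_qualifying(rng, v)
            qualifies = False
        variants.append(v)
        truth.append(qualifies)

    order = rng.permutation(cfg.n_variants)
    variants = [variants[j] for j in order]
    truth = [truth[j] for j in order]
    return variants, truth


def _draw_predictors(
    rng: np.random.Generator, min_deleterious: int = 0
) -> Dict[str, str]:
    calls = {
        tool: str(rng.choice(["deleterious", "tolerated", "missing"]))
        for tool in PREDICTOR_TOOLS
    }
    if sum(c == "deleterious" for c in calls.values()) < min_deleterious:
        calls[PREDICTOR_TOOLS[int(rng.integers(len(PREDICTOR_TOOLS)))]] = "deleterious"
    return calls


def _random_variant(rng: np.random.Generator, gene: str, vid: str) -> WesVariant:
    def freq() -> Optional[float]:
        r = rng.random()
        if r < 0.2:
            return None
        if r < 0.5:
            return float(rng.uniform(0, 0.0009))
        return float(rng.uniform(0.001, 0.2))

    return WesVariant(
        gene=gene,
        region_class=str(rng.choice(["exonic", "splicing", "other"])),
        consequence=str(rng.choice(sorted(CONSEQUENCES))),
        freq_1000g=freq(),
        freq_exac=freq(),
        in_inhouse_controls=bool(rng.random() < 0.2),
        in_nonhtx_patients=bool(rng.random() < 0.2),
        predictor_calls=_draw_predictors(rng),
        zygosity=str(rng.choice(["het", "hom"])),
        variant_id=vid,
    )


def _spoil_if_qualifying(rng: np.random.Generator, v: WesVariant) -> WesVariant:
    from dataclasses import replace

    from rarecnv.wes_filter import first_failed_criterion

    if first_failed_criterion(v) is None:
        spoiler = int(rng.integers(4))
        if spoiler == 0:
            v = replace(v, region_class="other")
        elif spoiler == 1:
            v = replace(v, consequence="synonymous")
        elif spoiler == 2:
            v = replace(v, freq_exac=float(rng.uniform(0.01, 0.2)))
        else:
            v = replace(v, in_inhouse_controls=True)
    return v


def gen_phenotype_counts(cfg: SimConfig) -> List[PhenotypeCounts]:
    """Multinomial category counts per group per replicate."""
    rng = np.random.default_rng([cfg.seed, 4])
    cats = SCHEMES[cfg.phenotype_scheme]
    out: List[PhenotypeCounts] = []
    for group in sorted(cfg.phenotype_probs):
        probs = cfg.phenotype_probs[group]
        for rep in range(1, cfg.n_replicates + 1):
            draw = rng.multinomial(cfg.n_embryos_per_group, probs)
            out.append(
                PhenotypeCounts(
                    group=group,
                    scheme=cfg.phenotype_scheme,
                    counts=dict(zip(cats, map(int, draw))),
                    replicate=rep,
                )
            )
    return out
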