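"""Readers/writers for the on-disk formats, bundled fixtures, and the
pipeline orchestrator.

The canonical CNV exchange format is a BED-derived TSV (header row:
``sample_id  chrom  start  end  copy_number  n_markers``) holding printed
1-based coordinates; thousands separators are tolerated on read and never
written.  Gene models travel as GFF3 (gene + CDS features); GFF3's 1-based
inclusive exon coordinates are converted to the internal end-exclusive
convention at parse time.  Readers reject malformed rows with line numbers
rather than silently coercing.
"""

from __future__ import annotations

import hashlib
import json
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from rarecnv.candidate_select import (
    CandidateGene,
    CuratedGeneSets,
    screen_known_genes,
    select_candidates,
    summarize_candidates,
)
from rarecnv.cnv_rarity import (
    CommonCnvRecord,
    FilterDecision,
    RareFilterParams,
    apply_rare_filter,
)
from rarecnv.genic_impact import (
    GeneModel,
    GenicImpact,
    classify_all,
    tabulate_classes,
)
from rarecnv.genome_model import (
    CnvCall,
    GenomicInterval,
    IntervalError,
    MarkerGrid,
    genomic_sort_key,
)
from rarecnv.pheno_stats import SCHEMES, PhenotypeCounts, compare_groups, percent
from rarecnv.wes_filter import (
    VariantFilterParams,
    WesVariant,
    apply_variant_filter,
)

CNV_COLUMNS = ("sample_id", "chrom", "start", "end", "copy_number", "n_markers")
DB_COLUMNS = ("chrom", "start", "end", "dosage", "frequency")
VARIANT_COLUMNS = (
    "variant_id",
    "gene",
    "region_class",
    "consequence",
    "freq_1000g",
    "freq_exac",
    "in_inhouse_controls",
    "in_nonhtx_patients",
    "predictor_calls",
    "zygosity",
)
COUNT_COLUMNS = ("group", "scheme", "replicate", "category", "count")


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(str(text).replace(",", "").strip())
    except ValueError:
        raise FormatError(f"line {lineno}: bad {what} {text!r}") from None


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# CNV calls


def read_cnv_tsv(path: str | Path) -> List[CnvCall]:
    df = _read_tsv(path, CNV_COLUMNS)
    calls: List[CnvCall] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        start = _parse_int(row["start"], "start", lineno)
        end = _parse_int(row["end"], "end", lineno)
        cn = _parse_int(row["copy_number"], "copy_number", lineno)
        nm = str(row["n_markers"]).strip()
        n_markers = _parse_int(nm, "n_markers", lineno) if nm else None
        try:
            iv = GenomicInterval(row["chrom"], start, end)
            call = CnvCall(
                interval=iv,
                copy_number=cn,
                sample_id=str(row["sample_id"]).strip(),
                n_markers=n_markers,
            )
        except (IntervalError, ValueError) as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from None
        calls.append(call)
    return calls


def write_cnv_tsv(path: str | Path, calls: Iterable[CnvCall]) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "copy_number": c.copy_number,
            "n_markers": "" if c.n_markers is None else c.n_markers,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=list(CNV_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_bed(path: str | Path, calls: Iterable[CnvCall]) -> None:
    """BED4 export (0-based half-open) for genome-browser use."""
    with open(path, "w") as fh:
        for c in calls:
            name = f"{c.sample_id}_cn{c.copy_number}"
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start - 1}"
                f"\t{c.interval.end - 1}\t{name}\n"
            )


# ---------------------------------------------------------------------------
# Common-CNV database


def read_common_db_tsv(path: str | Path) -> List[CommonCnvRecord]:
    df = _read_tsv(path, DB_COLUMNS)
    records: List[CommonCnvRecord] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2
        try:
            records.append(
                CommonCnvRecord(
                    interval=GenomicInterval(
                        row["chrom"],
                        _parse_int(row["start"], "start", lineno),
                        _parse_int(row["end"], "end", lineno),
                    ),
                    dosage=str(row["dosage"]).strip(),
                    frequency=float(row["frequency"]),
                )
            )
        except (IntervalError, ValueError) as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from None
    return records


def write_common_db_tsv(
    path: str | Path, records: Iterable[CommonCnvRecord]
) -> None:
    rows = [
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "dosage": r.dosage,
            "frequency": repr(r.frequency),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(DB_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Marker grid


def read_marker_grid_tsv(path: str | Path) -> MarkerGrid:
    df = _read_tsv(path, ("chrom", "position"))
    positions: Dict[str, List[int]] = {}
    for idx, row in df.iterrows():
        positions.setdefault(str(row["chrom"]), []).append(
            _parse_int(row["position"], "position", int(idx) + 2)
        )
    return MarkerGrid(positions=positions)


def write_marker_grid_tsv(path: str | Path, grid: MarkerGrid) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\n")
        for chrom in sorted(grid.positions, key=genomic_sort_key):
            for p in grid.positions[chrom]:
                fh.write(f"{chrom}\t{p}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)


def read_gene_models_gff3(path: str | Path) -> List[GeneModel]:
    """Parse gene + CDS features into gene models via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        symbol = gene.attributes.get("Name", gene.attributes.get("ID", ["?"]))[0]
        # GFF3 is 1-based inclusive: [start, end] -> internal [start, end+1)
        # stored under printed 1-based starts, i.e. end_internal = end + 1.
        span = GenomicInterval(gene.seqid, gene.start, gene.end + 1)
        exons = []
        for cds in db.children(gene, featuretype="CDS", order_by="start"):
            exons.append(GenomicInterval(cds.seqid, cds.start, cds.end + 1))
        try:
            genes.append(
                GeneModel(
                    symbol=symbol,
                    span=span,
                    strand=gene.strand if gene.strand in "+-" else "+",
                    coding_exons=tuple(exons),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: gene {symbol}: {exc}") from None
    genes.sort(key=lambda g: (genomic_sort_key(g.span.chrom), g.span.start))
    return genes


def write_gene_models_gff3(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            gid = f"gene{i:05d}"
            fh.write(
                f"{g.span.chrom}\tsim\tgene\t{g.span.start}\t{g.span.end - 1}"
                f"\t.\t{g.strand}\t.\tID={gid};Name={g.symbol}\n"
            )
            fh.write(
                f"{g.span.chrom}\tsim\tmRNA\t{g.span.start}\t{g.span.end - 1}"
                f"\t.\t{g.strand}\t.\tID={gid}.t1;Parent={gid}\n"
            )
            for j, e in enumerate(g.coding_exons):
                fh.write(
                    f"{e.chrom}\tsim\tCDS\t{e.start}\t{e.end - 1}\t.\t"
                    f"{g.strand}\t0\tID={gid}.cds{j};Parent={gid}.t1\n"
                )


# ---------------------------------------------------------------------------
# Gene sets


def read_gene_sets_tsv(
    sets_path: str | Path, aliases_path: str | Path | None = None
) -> CuratedGeneSets:
    df = _read_tsv(sets_path, ("symbol", "tag"))
    cilia, e3, known = set(), set(), set()
    pathway: Dict[str, str] = {}
    for idx, row in df.iterrows():
        sym, tag = str(row["symbol"]).strip(), str(row["tag"]).strip()
        if tag == "cilia":
            cilia.add(sym)
        elif tag.startswith("pathway:"):
            pathway[sym] = tag.split(":", 1)[1]
        elif tag == "e3_ligase":
            e3.add(sym)
        elif tag == "known_htx":
            known.add(sym)
        else:
            raise FormatError(f"{sets_path} line {int(idx) + 2}: unknown tag {tag!r}")
    aliases: Dict[str, str] = {}
    if aliases_path is not None:
        adf = _read_tsv(aliases_path, ("alias", "canonical"))
        aliases = dict(zip(adf["alias"], adf["canonical"]))
    return CuratedGeneSets(
        cilia_genes=cilia,
        lr_pathway_genes=pathway,
        e3_ligase_genes=e3,
        known_htx_genes=known or set(),
        aliases=aliases,
    )


# ---------------------------------------------------------------------------
# WES variants


def _parse_predictors(cell: str) -> Dict[str, str]:
    calls: Dict[str, str] = {}
    cell = cell.strip()
    if not cell:
        return calls
    for item in cell.split(";"):
        tool, _, verdict = item.partition("=")
        calls[tool.strip()] = verdict.strip()
    return calls


def read_variants_tsv(path: str | Path) -> List[WesVariant]:
    df = _read_tsv(path, VARIANT_COLUMNS)
    variants: List[WesVariant] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2

        def opt_float(cell: str) -> Optional[float]:
            cell = str(cell).strip()
            return None if cell in ("", "NA", ".") else float(cell)

        try:
            variants.append(
                WesVariant(
                    gene=str(row["gene"]).strip(),
                    region_class=str(row["region_class"]).strip(),
                    consequence=str(row["consequence"]).strip(),
                    freq_1000g=opt_float(row["freq_1000g"]),
                    freq_exac=opt_float(row["freq_exac"]),
                    in_inhouse_controls=str(row["in_inhouse_controls"]).strip()
                    in ("1", "true", "True"),
                    in_nonhtx_patients=str(row["in_nonhtx_patients"]).strip()
                    in ("1", "true", "True"),
                    predictor_calls=_parse_predictors(str(row["predictor_calls"])),
                    zygosity=str(row["zygosity"]).strip() or "het",
                    variant_id=str(row["variant_id"]).strip(),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from None
    return variants


def write_variants_tsv(path: str | Path, variants: Iterable[WesVariant]) -> None:
    def fmt_freq(f: Optional[float]) -> str:
        return "" if f is None else repr(f)

    rows = [
        {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "region_class": v.region_class,
            "consequence": v.consequence,
            "freq_1000g": fmt_freq(v.freq_1000g),
            "freq_exac": fmt_freq(v.freq_exac),
            "in_inhouse_controls": int(v.in_inhouse_controls),
            "in_nonhtx_patients": int(v.in_nonhtx_patients),
            "predictor_calls": ";".join(
                f"{tool}={call}" for tool, call in sorted(v.predictor_calls.items())
            ),
            "zygosity": v.zygosity,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Phenotype counts


def read_counts_tsv(path: str | Path) -> List[PhenotypeCounts]:
    df = _read_tsv(path, COUNT_COLUMNS)
    grouped: Dict[Tuple[str, str, int], Dict[str, int]] = {}
    for idx, row in df.iterrows():
        lineno = int(idx) + 2
        key = (
            str(row["group"]),
            str(row["scheme"]),
            _parse_int(row["replicate"], "replicate", lineno),
        )
        grouped.setdefault(key, {})[str(row["category"])] = _parse_int(
            row["count"], "count", lineno
        )
    return [
        PhenotypeCounts(group=g, scheme=s, counts=c, replicate=r)
        for (g, s, r), c in sorted(grouped.items())
    ]


def write_counts_tsv(path: str | Path, counts: Iterable[PhenotypeCounts]) -> None:
    rows = []
    for pc in counts:
        for cat in SCHEMES[pc.scheme]:
            rows.append(
                {
                    "group": pc.group,
                    "scheme": pc.scheme,
                    "replicate": pc.replicate,
                    "category": cat,
                    "count": pc.counts[cat],
                }
            )
    pd.DataFrame(rows, columns=list(COUNT_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Bundled fixtures (the published result tables, verbatim)


@dataclass(frozen=True)
class ResultRecord:
    """One row of the curated rare-CNV result table."""

    patient_id: str
    cytoband: str
    call: CnvCall
    type_label: str
    size_kbp: float
    genes: Tuple[str, ...]


def _fixture_path(name: str) -> Path:
    return Path(resources.files("rarecnv.fixtures") / name)


def load_result_table(path: str | Path | None = None) -> List[ResultRecord]:
    """The 19-row curated rare-CNV table; each row is validated so that the
    printed size equals (end - start) / 1000 to 3 decimals."""
    path = _fixture_path("rare_cnv_results.tsv") if path is None else Path(path)
    df = _read_tsv(
        path,
        (
            "patient_id",
            "cytoband",
            "chrom",
            "start",
            "end",
            "type",
            "size_kbp",
            "copy_number",
            "genes",
        ),
    )
    records: List[ResultRecord] = []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2
        start = _parse_int(row["start"], "start", lineno)
        end = _parse_int(row["end"], "end", lineno)
        size = float(row["size_kbp"])
        computed = round((end - start) / 1000.0, 3)
        if abs(computed - size) > 5e-4:
            raise FormatError(
                f"{path} line {lineno}: size {size} != computed {computed}"
            )
        call = CnvCall(
            interval=GenomicInterval(row["chrom"], start, end),
            copy_number=_parse_int(row["copy_number"], "copy_number", lineno),
            sample_id=str(row["patient_id"]).strip(),
        )
        records.append(
            ResultRecord(
                patient_id=str(row["patient_id"]).strip(),
                cytoband=str(row["cytoband"]).strip(),
                call=call,
                type_label=str(row["type"]).strip(),
                size_kbp=size,
                genes=tuple(
                    g.strip() for g in str(row["genes"]).split(";") if g.strip()
                ),
            )
        )
    return records


def result_table_impacts(
    records: Sequence[ResultRecord] | None = None,
) -> List[GenicImpact]:
    """Impacts built from the table's printed type labels and gene lists."""
    if records is None:
        records = load_result_table()
    return [
        GenicImpact(
            call=r.call, impact_class=r.type_label, genes_altered=tuple(r.genes)
        )
        for r in records
    ]


def load_curated_gene_sets() -> CuratedGeneSets:
    return read_gene_sets_tsv(
        _fixture_path("gene_sets.tsv"), _fixture_path("gene_aliases.tsv")
    )


def carrier_rate(
    records: Sequence[ResultRecord], denominator: int
) -> Tuple[int, float]:
    """(unique carriers, percent of cohort to 1 decimal, half-up)."""
    carriers = len({r.patient_id for r in records})
    return carriers, percent(carriers, denominator)


# ---------------------------------------------------------------------------
# Pipeline orchestration


@dataclass
class PipelineConfig:
    calls_path: str
    out_dir: str
    common_db_path: Optional[str] = None
    control_paths: List[str] = field(default_factory=list)
    markers_path: Optional[str] = None
    gene_models_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    gene_aliases_path: Optional[str] = None
    variants_path: Optional[str] = None
    counts_path: Optional[str] = None
    control_group: Optional[str] = None
    cohort_denominator: Optional[int] = None
    rare_params: RareFilterParams = field(default_factory=RareFilterParams)
    variant_params: VariantFilterParams = field(default_factory=VariantFilterParams)
    seed: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_decisions_tsv(
    path: str | Path, decisions: Iterable[FilterDecision]
) -> None:
    rows = [
        {
            "sample_id": d.call.sample_id,
            "chrom": d.call.interval.chrom,
            "start": d.call.interval.start,
            "end": d.call.interval.end,
            "copy_number": d.call.copy_number,
            "rare": int(d.rare),
            "reasons": ";".join(sorted(d.reasons)),
        }
        for d in decisions
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "start",
            "end",
            "copy_number",
            "rare",
            "reasons",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_impacts_tsv(path: str | Path, impacts: Iterable[GenicImpact]) -> None:
    rows = [
        {
            "sample_id": i.call.sample_id,
            "chrom": i.call.interval.chrom,
            "start": i.call.interval.start,
            "end": i.call.interval.end,
            "type": i.impact_class,
            "size_kbp": f"{i.call.interval.length_kb:.3f}",
            "genes": ";".join(i.genes_altered),
        }
        for i in impacts
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "type", "size_kbp", "genes"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_candidates_tsv(
    path: str | Path, candidates: Iterable[CandidateGene]
) -> None:
    rows = [
        {
            "patient_id": c.patient_id,
            "chrom": c.source_cnv.call.interval.chrom,
            "start": c.source_cnv.call.interval.start,
            "end": c.source_cnv.call.interval.end,
            "size_kbp": f"{c.source_cnv.call.interval.length_kb:.3f}",
            "copy_number": c.source_cnv.call.copy_number,
            "gene": c.symbol,
            "criteria": ";".join(c.criteria_hit),
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "chrom",
            "start",
            "end",
            "size_kbp",
            "copy_number",
            "gene",
            "criteria",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """filter -> classify -> prioritize -> (optional) variant filter -> stats.

    Writes decisions.tsv, impacts.tsv, class_tally.json, candidates.tsv,
    optional variant and stats reports, and a run manifest with parameters
    and input digests.  Returns the in-memory bundle.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    calls = read_cnv_tsv(cfg.calls_path)
    db = read_common_db_tsv(cfg.common_db_path) if cfg.common_db_path else []
    cohorts = [read_cnv_tsv(p) for p in cfg.control_paths]
    grid = read_marker_grid_tsv(cfg.markers_path) if cfg.markers_path else None

    decisions = apply_rare_filter(calls, db, cohorts, grid, cfg.rare_params)
    write_decisions_tsv(out / "decisions.tsv", decisions)
    rare = [d.call for d in decisions if d.rare]
    write_cnv_tsv(out / "rare_calls.tsv", rare)
    write_bed(out / "rare_calls.bed", rare)

    bundle: Dict[str, object] = {
        "decisions": decisions,
        "n_calls": len(calls),
        "n_rare": len(rare),
    }

    impacts: List[GenicImpact] = []
    if cfg.gene_models_path:
        genes = read_gene_models_gff3(cfg.gene_models_path)
        impacts = classify_all(rare, genes)
        write_impacts_tsv(out / "impacts.tsv", impacts)
        tally = tabulate_classes(impacts)
        (out / "class_tally.json").write_text(json.dumps(tally, indent=2) + "\n")
        bundle["impacts"] = impacts
        bundle["class_tally"] = tally

    if cfg.gene_sets_path and impacts:
        sets = read_gene_sets_tsv(cfg.gene_sets_path, cfg.gene_aliases_path)
        known = screen_known_genes(impacts, sets)
        candidates = select_candidates(impacts, sets)
        write_candidates_tsv(out / "candidates.tsv", candidates)
        bundle["known_gene_hits"] = sorted(known)
        bundle["candidates"] = candidates
        bundle["candidate_summary"] = summarize_candidates(candidates)

    if cfg.cohort_denominator:
        carriers = len({c.sample_id for c in rare})
        bundle["carrier_rate_percent"] = percent(carriers, cfg.cohort_denominator)
        bundle["n_carriers"] = carriers

    if cfg.variants_path:
        variants = read_variants_tsv(cfg.variants_path)
        survivors, rejects = apply_variant_filter(variants, cfg.variant_params)
        write_variants_tsv(out / "qualifying_variants.tsv", survivors)
        audit = pd.DataFrame(
            [
                {"variant_id": v.variant_id, "first_failed": crit}
                for v, crit in rejects
            ],
            columns=["variant_id", "first_failed"],
        )
        audit.to_csv(out / "variant_audit.tsv", sep="\t", index=False,
                     lineterminator="\n")
        bundle["n_variants"] = len(variants)
        bundle["qualifying_variants"] = survivors

    if cfg.counts_path and cfg.control_group:
        counts = read_counts_tsv(cfg.counts_path)
        by_group: Dict[str, List[PhenotypeCounts]] = {}
        for pc in counts:
            by_group.setdefault(pc.group, []).append(pc)
        if cfg.control_group not in by_group:
            raise FormatError(
                f"control group {cfg.control_group!r} absent from counts"
            )
        control = by_group[cfg.control_group]
        stats_rows = []
        for group in sorted(by_group):
            if group == cfg.control_group:
                continue
            res = compare_groups(by_group[group], control)
            stats_rows.append(
                {
                    "group": group,
                    "test": res.test_used,
                    "statistic": ""
                    if res.statistic is None
                    else f"{res.statistic:.6g}",
                    "p_value": f"{res.p_value:.6g}",
                    "stars": res.stars,
                }
            )
        pd.DataFrame(
            stats_rows, columns=["group", "test", "statistic", "p_value", "stars"]
        ).to_csv(out / "stats.tsv", sep="\t", index=False, lineterminator="\n")
        bundle["stats"] = stats_rows

    manifest = {
        "seed": cfg.seed,
        "rare_params": vars(cfg.rare_params),
        "variant_params": vars(cfg.variant_params),
        "cohort_denominator": cfg.cohort_denominator,
        "inputs": {
            str(p): _sha256(p)
            for p in filter(
                None,
                [
                    cfg.calls_path,
                    cfg.common_db_path,
                    *cfg.control_paths,
                    cfg.markers_path,
                    cfg.gene_models_path,
                    cfg.gene_sets_path,
                    cfg.gene_aliases_path,
                    cfg.variants_path,
                    cfg.counts_path,
                ],
            )
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle
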