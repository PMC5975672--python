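# rarecnv

A toolkit for discovering rare copy-number variants (CNVs) in a patient
cohort and prioritizing candidate laterality genes:

- **Interval algebra** (`rarecnv.genome_model`): printed 1-based coordinates
  with length defined as `end − start`, overlap, union-coverage fractions,
  and half-open marker counting against a probe grid.
- **Rarity filter** (`rarecnv.cnv_rarity`): the four-criterion filter —
  size > 50 kb, ≥ 25 markers, not ≥ 50% covered by same-dosage common-CNV
  database records at ≥ 1‰ frequency, and absent from control cohorts
  (50% reciprocal overlap). Every decision carries reason codes.
- **Genic impact** (`rarecnv.genic_impact`): classifies each CNV as a genic
  deletion (loss hitting ≥ 1 coding exon), full-gene duplication (gain
  containing ≥ 1 gene span), internal duplication, or noncoding, and
  enumerates altered genes in genomic order.
- **Candidate selection** (`rarecnv.candidate_select`): prioritizes genes in
  rare CNVs by curated sets (cilia, laterality signaling pathways, E3
  ubiquitin ligases) and screens for known laterality genes.
- **Exome filter** (`rarecnv.wes_filter`): five-criterion rare functional
  variant filter with a per-variant audit trail.
- **Phenotype statistics** (`rarecnv.pheno_stats`): collapses embryo
  phenotype counts to 2×2 tables, Yates-corrected chi-squared or Fisher's
  exact test (auto-selected by expected cell counts), significance stars,
  and half-up percentage summaries.
- **Synthetic data** (`rarecnv.synthetic_data`): seeded generators for every
  input — probe grids, gene models, call sets with ground-truth labels
  (spike-in rare calls plus decoys that each violate exactly one filter
  criterion), annotated variants with planted qualifying records, and
  multinomial phenotype counts.
- **IO and orchestration** (`rarecnv.io_report`): TSV/GFF3/BED readers and
  writers with row-level validation, bundled curated result-table fixtures,
  and a full pipeline runner with a manifest of parameters and input digests.

## CLI

```bash
rarecnv simulate --seed 7 --out-dir sim/           # synthetic input set
rarecnv filter-cnv --calls sim/calls.tsv --common-db sim/common_db.tsv \
    --controls sim/controls_0.tsv,sim/controls_1.tsv \
    --markers sim/markers.tsv --out decisions.tsv
rarecnv classify --calls rare.tsv --genes sim/genes.gff3 --out impacts.tsv
rarecnv prioritize --impacts impacts.tsv --out candidates.tsv
rarecnv filter-variants --variants sim/variants.tsv --out qualifying.tsv
rarecnv stats --counts sim/counts.tsv --control control --out stats.tsv
rarecnv run --config pipeline.json                 # full pipeline
rarecnv report                                     # bundled result-table summary
```

`rarecnv run` takes a JSON config mirroring `PipelineConfig` (paths to
calls, common database, control cohorts, marker grid, gene models, gene
sets, variants, counts, plus threshold overrides and the cohort
denominator).

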