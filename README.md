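# tissueresp

Multi-tissue transcriptome responsiveness analysis for paired-condition
(treated vs. control) bulk RNA-seq designs with one pooled sample per
tissue and condition.

The pipeline:

1. **quantify** — flatten transcript models into per-gene integrated exon
   sets (interval union) and compute RPKM from supplied read counts and
   library sizes.
2. **filter + score** — drop genes below RPKM/read-count thresholds in
   either condition, then compute each gene's per-tissue response score
   `SR = log2(RPKM_treated / RPKM_control)` and the composite Euclidean
   norm of its SR vector across tissues.
3. **responder calls** — twofold responders (|SR| ≥ 1, inclusive),
   multi-tissue responders (|SR| ≥ 1 in ≥ 4 tissues), and
   tissue-specific responders (dominant single-tissue |SR|).
4. **tissue comparison** — two-sided Fisher's exact tests of responder
   proportions between tissues.
5. **enrichment** — gene → GO annotation via an ortholog → Entrez → GO
   join chain, hypergeometric upper-tail over-representation tests, and
   Benjamini–Hochberg FDR adjustment.
6. **clustering** — average-linkage hierarchical clustering of the top-N
   genes by composite norm (uncentered-correlation distance by default)
   with Cluster-3.0-compatible CDT/GTR output readable by Java TreeView.
7. **simulate** — a negative-binomial count simulator with planted
   multi-tissue and tissue-specific effects and a planted GO category, so
   the entire pipeline is testable without external downloads.

## CLI

```sh
# generate a synthetic study (GTF, counts, totals, annotation maps, truth)
tissueresp simulate --seed 1 --out study/

# RPKM quantification
tissueresp quantify --gtf study/models.gtf --counts study/counts.tsv \
    --totals study/totals.tsv --out rpkm.tsv

# filtering + SR/composite-norm table
tissueresp score --gtf study/models.gtf --counts study/counts.tsv \
    --totals study/totals.tsv --min-rpkm 1 --min-reads 5 --out sr.tsv

# per-tissue twofold counts and Fisher tests vs. a focal tissue
tissueresp compare --gtf study/models.gtf --counts study/counts.tsv \
    --totals study/totals.tsv --focal-tissue intestine --out comparison.tsv

# GO over-representation for one tissue's up- or down-responders
tissueresp enrich --sr-table sr.tsv --direction up --tissue intestine \
    --ortho study/orthologs.tsv --gene2ensembl study/gene2ensembl.tsv \
    --gene2go study/gene2go.tsv --out enrichment.tsv

# hierarchical clustering of the top 400 genes by composite norm
tissueresp cluster --sr-table sr.tsv --top 400 --metric uncentered-correlation \
    --cut 5 --out-prefix clusters

# the whole pipeline from a YAML config (keys mirror PipelineConfig)
tissueresp run --config pipeline.yaml --seed 1
```

`tissueresp run` writes every intermediate TSV plus `manifest.json`
(package version, config, seed, per-stage gene counts) into the configured
output directory.

## File formats

- **Gene models**: GTF exon features with `gene_id`/`transcript_id`
  attributes; 1-based inclusive coordinates.
- **Counts**: TSV with `gene_id` plus one column per sample named
  `<tissue>_<SF|GC>`; companion TSV `sample` / `total_mapped_reads`.
- **SR table**: TSV with `gene_id`, one SR column per tissue, and the
  composite norm column `TSR`.
- **Annotation maps**: ortholog TSV (`species_gene_id`, `human_gene_id`),
  gene2ensembl-style TSV (`tax_id`, `entrez_id`, `ensembl_gene_id`), and
  gene2go-style TSV (`tax_id`, `entrez_id`, `go_id`, `evidence`,
  `qualifier`, `term_label`).
- **Clustering**: `.cdt`/`.gtr` files in the Eisen Cluster/TreeView
  dialect.

Readers accept en-dash/minus-sign variants in numeric fields; writers emit
ASCII hyphen-minus.
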