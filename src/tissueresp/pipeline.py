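"""End-to-end pipeline: quantify -> filter -> score -> responders ->
tissue comparison -> enrichment -> clustering.

Each stage writes its table under ``out_dir`` and contributes an entry to
the run manifest (config, seed, per-stage gene counts, stage status), which
is written even on failure so partial runs are diagnosable.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as tio
from .clustering import average_linkage_tree, cut_tree, sr_distance_matrix, write_cdt_gtr
from .config import PipelineConfig
from .enrichment import build_annotation_map, hypergeometric_enrichment, significant_terms
from .errors import PipelineStageError, TissuerespError
from .quantify import quantify_samples
from .responsiveness import (
    FilterConfig,
    SRTable,
    build_sr_table,
    filter_genes,
    fisher_tissue_comparison,
    multi_tissue_responders,
    tissue_specific_responders,
    rank_top_n,
    twofold_counts,
)

logger = logging.getLogger("tissueresp")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, **info):
        manifest["stages"][stage] = {"status": "ok", **info}
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineStageError(stage, str(exc)) from exc

    t0 = time.time()

    # --- quantify
    stage = "quantify"
    try:
        models = tio.read_gtf(cfg.gtf)
        samples = tio.read_counts_table(cfg.counts, cfg.totals)
        expr = quantify_samples(models, samples)
        missing = [t for t in cfg.tissues if t not in expr.tissues]
        if missing:
            raise TissuerespError(f"configured tissue(s) absent: {missing}")
        tio.write_rpkm_table(expr.rpkm, out / "rpkm.tsv")
    except Exception as exc:  # noqa: BLE001 - manifest must record any failure
        fail(stage, exc)
    record(stage, n_genes=len(expr.genes), n_samples=len(expr.samples),
           seconds=round(time.time() - t0, 2))
    logger.info("quantify: %d genes x %d samples", len(expr.genes),
                len(expr.samples))

    # --- per-tissue filtering + twofold counts + Fisher comparisons
    stage = "compare"
    try:
        fc = FilterConfig(cfg.min_rpkm, cfg.min_reads, "per-tissue")
        per_tissue = {
            t: filter_genes(expr, fc, tissue=t) for t in cfg.tissues
        }
        rows = []
        for t in cfg.tissues:
            srt_t = build_sr_table(expr, per_tissue[t], tissues=[t])
            counts_t = twofold_counts(srt_t).loc[t]
            rows.append({
                "tissue": t,
                "up": int(counts_t["up"]),
                "down": int(counts_t["down"]),
                "total": int(counts_t["total"]),
            })
        cmp_df = pd.DataFrame(rows)
        focal = cmp_df.set_index("tissue").loc[cfg.focal_tissue]
        for direction in ("up", "down"):
            cmp_df[f"p_{direction}_vs_{cfg.focal_tissue}"] = [
                fisher_tissue_comparison(
                    int(r[direction]), int(r["total"]),
                    int(focal[direction]), int(focal["total"]),
                )
                for _, r in cmp_df.iterrows()
            ]
        cmp_df["p"] = cmp_df[[f"p_up_vs_{cfg.focal_tissue}",
                              f"p_down_vs_{cfg.focal_tissue}"]].min(axis=1)
        tio.write_fisher_table(cmp_df, out / "tissue_comparison.tsv")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)
    record(stage, per_tissue_pass={t: len(s) for t, s in per_tissue.items()})

    # --- all-tissue filter + SR/TSR
    stage = "score"
    try:
        fc_all = FilterConfig(cfg.min_rpkm, cfg.min_reads, "all-tissues")
        kept = filter_genes(expr, fc_all, tissues=cfg.tissues)
        srt = build_sr_table(expr, kept, tissues=list(cfg.tissues))
        tio.write_sr_table(srt, out / "sr_table.tsv")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)
    record(stage, n_input=len(expr.genes), n_pass_all_tissues=len(kept))

    # --- responder calls
    stage = "responders"
    try:
        calls = multi_tissue_responders(
            srt, sr_threshold=cfg.sr_threshold, min_tissues=cfg.min_tissues
        ) + tissue_specific_responders(
            srt, cfg.focal_tissue,
            min_focal_sr=cfg.min_focal_sr,
            dominance_ratio=cfg.dominance_ratio,
        )
        tio.write_responder_calls(calls, out / "responder_calls.tsv")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)
    record(stage, n_scored=len(srt.genes), n_calls=len(calls))

    # --- enrichment per direction in the focal tissue
    stage = "enrich"
    enrich_summary = {}
    try:
        if cfg.orthologs and cfg.gene2ensembl and cfg.gene2go:
            ann = build_annotation_map(
                cfg.orthologs, cfg.gene2ensembl, cfg.gene2go
            )
            background = per_tissue[cfg.focal_tissue]
            srt_focal = build_sr_table(expr, background,
                                       tissues=[cfg.focal_tissue])
            col = srt_focal.sr[cfg.focal_tissue]
            all_results = []
            for direction, mask in (
                ("up", col >= cfg.sr_threshold),
                ("down", col <= -cfg.sr_threshold),
            ):
                study = set(col.index[mask])
                res = hypergeometric_enrichment(
                    study, background, ann, direction=direction,
                    restrict_to_annotated=(cfg.background == "annotated"),
                )
                all_results.extend(significant_terms(res, cfg.p_cut, cfg.q_cut))
                enrich_summary[direction] = {
                    "study": len(study), "tested": len(res),
                }
            tio.write_enrichment_table(all_results, out / "enrichment.tsv")
        else:
            enrich_summary["skipped"] = "no annotation files configured"
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)
    record(stage, **enrich_summary)

    # --- clustering of top genes by composite norm
    stage = "cluster"
    try:
        top = rank_top_n(srt, n=min(cfg.top_n, len(srt.genes)))
        sub = SRTable(sr=srt.sr.loc[top])
        if cfg.mean_center_rows:
            sub = SRTable(
                sr=sub.sr.sub(sub.sr.mean(axis=1), axis=0), tsr=sub.tsr
            )
        dist = sr_distance_matrix(sub, top, metric=cfg.metric)
        tree = average_linkage_tree(dist, genes=top)
        labels = cut_tree(tree, k=min(cfg.k_clusters, len(top)))
        write_cdt_gtr(sub, tree, out / "clusters.cdt", out / "clusters.gtr")
        with open(out / "cluster_labels.tsv", "w") as fh:
            fh.write("gene_id\tcluster\n")
            for g in tree.ordered_genes:
                fh.write(f"{g}\t{labels[g]}\n")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)
    record(stage, n_clustered=len(top), k=min(cfg.k_clusters, len(top)),
           seconds_total=round(time.time() - t0, 2))

    return manifest
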