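"""Synthetic multi-tissue paired-condition study generator.

Produces everything the analysis pipeline consumes — gene models (GTF),
count and library-size tables, and the three annotation-mapping files —
together with the planted ground truth, so every downstream stage can be
exercised and validated without external data.

Counts are negative-binomial with mean
``baseline_rpkm * 2^effect * (length/1e3) * (library_size/1e6)``;
one pooled sample per (tissue, condition), no replicates. A configurable
fraction of genes is given deliberately low expression so the RPKM/read
filters have something to remove, and one GO category is planted among the
focal tissue's upregulated tissue-specific genes for enrichment testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .enrichment import AnnotationMap
from .errors import ConfigError
from .quantify import GeneModel, SampleCounts, Transcript, flatten_gene_model
from .responsiveness import ResponderCall

DEFAULT_TISSUES = ("brain", "eye", "ovary", "testis", "liver", "intestine")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic study; all randomness flows from ``seed``."""

    n_genes: int = 2000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    baseline_log_mean: float = 5.0   # log2 RPKM of a typical gene
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.01
    library_size: int = 10_000_000
    n_multi_tissue: int = 20
    n_tissue_specific: int = 40
    focal_tissue: str = "intestine"
    tissue_specific_up_fraction: float = 0.75
    multi_effect_range: tuple[float, float] = (1.5, 3.0)
    specific_effect_range: tuple[float, float] = (2.5, 4.0)
    low_expr_fraction: float = 0.10
    no_ortholog_fraction: float = 0.05
    planted_go_id: str = "GO:0099001"
    planted_go_overlap_fraction: float = 0.5
    n_go_categories: int = 40
    go_category_size_range: tuple[int, int] = (10, 60)
    seed: int = 0

    def __post_init__(self):
        if self.n_multi_tissue + self.n_tissue_specific > self.n_genes:
            raise ConfigError(
                "more planted genes than genes: "
                f"{self.n_multi_tissue} + {self.n_tissue_specific} > "
                f"{self.n_genes}"
            )
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.baseline_log_sd <= 0:
            raise ConfigError("baseline_log_sd must be > 0")
        if self.library_size <= 0:
            raise ConfigError("library_size must be > 0")
        if self.focal_tissue not in self.tissues:
            raise ConfigError(
                f"focal_tissue {self.focal_tissue!r} not in tissues"
            )
        if not 0 <= self.planted_go_overlap_fraction <= 1:
            raise ConfigError("planted_go_overlap_fraction must be in [0,1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth covering every generated gene exactly once."""

    effects: pd.DataFrame              # genes x tissues, planted log2 effects
    classes: pd.Series                 # gene -> multi-tissue | tissue-specific | low-expression | null
    go_memberships: dict[str, frozenset[str]]
    planted_go_id: str
    focal_tissue: str

    def genes_of_class(self, cls: str) -> set[str]:
        return set(self.classes.index[self.classes == cls])


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    models: dict[str, GeneModel]
    samples: list[SampleCounts]
    truth: SyntheticTruth
    annotation: AnnotationMap = None
    paths: dict[str, Path] = field(default_factory=dict)


def _make_gene_model(gene_id: str, rng: np.random.Generator) -> GeneModel:
    chrom = f"chr{int(rng.integers(1, 25))}"
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(1_000, 1_000_000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(100, 801))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(60, 500))
    transcripts = [Transcript(f"{gene_id}.t1", chrom, strand, tuple(exons))]
    if n_exons > 1 and rng.random() < 0.5:
        # second isoform: drop one internal exon, keep the rest
        drop = int(rng.integers(0, n_exons))
        sub = tuple(e for i, e in enumerate(exons) if i != drop)
        transcripts.append(Transcript(f"{gene_id}.t2", chrom, strand, sub))
    return flatten_gene_model(gene_id, transcripts)


def simulate_study(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticStudy:
    """Generate one synthetic study; identical config -> identical output.

    When ``out_dir`` is given, writes ``models.gtf``, ``counts.tsv``,
    ``totals.tsv``, ``orthologs.tsv``, ``gene2ensembl.tsv``,
    ``gene2go.tsv`` and ``truth.tsv`` there and records their paths.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    tissues = list(cfg.tissues)

    models = {g: _make_gene_model(g, rng) for g in genes}
    lengths = np.array([models[g].length_bp for g in genes], dtype=float)

    # --- baseline expression; a slice of genes is deliberately near-silent
    baseline = 2.0 ** rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                 cfg.n_genes)
    n_low = int(round(cfg.low_expr_fraction * cfg.n_genes))
    n_planted = cfg.n_multi_tissue + cfg.n_tissue_specific
    if n_planted + n_low > cfg.n_genes:
        raise ConfigError("low-expression fraction overlaps planted genes")
    low_idx = np.arange(cfg.n_genes - n_low, cfg.n_genes)
    baseline[low_idx] = rng.uniform(0.02, 0.6, n_low)

    # --- planted effects
    effects = np.zeros((cfg.n_genes, len(tissues)))
    classes = np.array(["null"] * cfg.n_genes, dtype=object)
    classes[low_idx] = "low-expression"

    mt_idx = np.arange(cfg.n_multi_tissue)
    classes[mt_idx] = "multi-tissue"
    lo, hi = cfg.multi_effect_range
    for i in mt_idx:
        n_hit = int(rng.integers(4, len(tissues) + 1))
        hit = rng.choice(len(tissues), size=n_hit, replace=False)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effects[i, hit] = sign * rng.uniform(lo, hi, n_hit)

    ts_idx = np.arange(cfg.n_multi_tissue, n_planted)
    classes[ts_idx] = "tissue-specific"
    focal_col = tissues.index(cfg.focal_tissue)
    lo, hi = cfg.specific_effect_range
    n_up = int(round(cfg.tissue_specific_up_fraction * cfg.n_tissue_specific))
    for rank, i in enumerate(ts_idx):
        sign = 1.0 if rank < n_up else -1.0
        effects[i, focal_col] = sign * rng.uniform(lo, hi)
        # faint off-target wobble, well under any calling threshold
        others = [c for c in range(len(tissues)) if c != focal_col]
        effects[i, others] = rng.normal(0.0, 0.05, len(others))

    # --- counts: NB around rpkm * length/1e3 * depth/1e6, SF shifted by 2^effect
    depth_factor = cfg.library_size / 1e6
    size = 1.0 / cfg.nb_dispersion
    samples: list[SampleCounts] = []
    for t_i, tissue in enumerate(tissues):
        mu_gc = baseline * (lengths / 1e3) * depth_factor
        mu_sf = mu_gc * 2.0 ** effects[:, t_i]
        for cond, mu in (("SF", mu_sf), ("GC", mu_gc)):
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p)
            samples.append(
                SampleCounts(
                    sample_id=(tissue, cond),
                    gene_counts=dict(zip(genes, (int(c) for c in counts))),
                    total_mapped_reads=cfg.library_size,
                )
            )

    # --- annotation chain: gene -> human id -> entrez -> GO
    has_ortholog = rng.random(cfg.n_genes) >= cfg.no_ortholog_fraction
    ortho_rows, g2e_rows = [], []
    for i, g in enumerate(genes):
        if not has_ortholog[i]:
            continue
        human = f"HSAG{i:07d}"
        ortho_rows.append((g, human))
        g2e_rows.append((9606, 100000 + i, human))

    annotated_idx = np.flatnonzero(has_ortholog)
    go_memberships: dict[str, set[str]] = {}
    cat_lo, cat_hi = cfg.go_category_size_range
    for c in range(cfg.n_go_categories):
        go_id = f"GO:{1000000 + c:07d}"
        n_members = int(rng.integers(cat_lo, cat_hi + 1))
        members = rng.choice(annotated_idx, size=min(n_members, annotated_idx.size),
                             replace=False)
        go_memberships[go_id] = {genes[j] for j in members}

    # planted category: a chosen fraction of the focal tissue's upregulated
    # tissue-specific genes, padded with background genes of similar count
    up_specific = [genes[i] for rank, i in enumerate(ts_idx)
                   if rank < n_up and has_ortholog[i]]
    n_overlap = int(round(cfg.planted_go_overlap_fraction * len(up_specific)))
    planted_members = set(up_specific[:n_overlap])
    null_pool = [genes[j] for j in annotated_idx
                 if classes[j] == "null" and genes[j] not in planted_members]
    n_pad = max(len(planted_members), 5)
    pad = rng.choice(len(null_pool), size=min(n_pad, len(null_pool)),
                     replace=False)
    planted_members.update(null_pool[j] for j in pad)
    go_memberships[cfg.planted_go_id] = planted_members

    gene_index = {g: i for i, g in enumerate(genes)}
    g2go_rows = []
    for go_id in sorted(go_memberships):
        for g in sorted(go_memberships[go_id]):
            g2go_rows.append(
                (9606, 100000 + gene_index[g], go_id, "IEA", "-",
                 f"synthetic category {go_id}")
            )

    truth = SyntheticTruth(
        effects=pd.DataFrame(effects, index=pd.Index(genes, name="gene_id"),
                             columns=tissues),
        classes=pd.Series(classes, index=genes, name="class"),
        go_memberships={k: frozenset(v) for k, v in go_memberships.items()},
        planted_go_id=cfg.planted_go_id,
        focal_tissue=cfg.focal_tissue,
    )
    go_by_entrez: dict[int, set[str]] = {}
    for _, eid, go_id, _, _, _ in g2go_rows:
        go_by_entrez.setdefault(eid, set()).add(go_id)
    annotation = AnnotationMap(
        ortholog_map={g: frozenset({h}) for g, h in ortho_rows},
        entrez_map={ens: frozenset({eid}) for _, eid, ens in g2e_rows},
        go_map={k: frozenset(v) for k, v in go_by_entrez.items()},
        term_labels={go_id: f"synthetic category {go_id}"
                     for go_id in go_memberships},
    )
    study = SyntheticStudy(config=cfg, models=models, samples=samples,
                           truth=truth, annotation=annotation)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": out / "models.gtf",
            "counts": out / "counts.tsv",
            "totals": out / "totals.tsv",
            "orthologs": out / "orthologs.tsv",
            "gene2ensembl": out / "gene2ensembl.tsv",
            "gene2go": out / "gene2go.tsv",
            "truth": out / "truth.tsv",
        }
        tio.write_gtf(models, paths["gtf"])
        tio.write_counts_table(samples, paths["counts"], paths["totals"])
        with open(paths["orthologs"], "w") as fh:
            fh.write("#species_gene_id\thuman_gene_id\n")
            for g, h in ortho_rows:
                fh.write(f"{g}\t{h}\n")
        with open(paths["gene2ensembl"], "w") as fh:
            fh.write("#tax_id\tGeneID\tEnsembl_gene_identifier\n")
            for tax, eid, ens in g2e_rows:
                fh.write(f"{tax}\t{eid}\t{ens}\n")
        with open(paths["gene2go"], "w") as fh:
            fh.write("#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\n")
            for row in g2go_rows:
                fh.write("\t".join(map(str, row)) + "\n")
        truth_df = truth.effects.copy()
        truth_df.insert(0, "class", truth.classes)
        truth_df["seed"] = cfg.seed
        truth_df.to_csv(paths["truth"], sep="\t")
        study.paths = paths

    return study


def evaluate_recovery(
    truth: SyntheticTruth,
    calls: Sequence[ResponderCall],
    eligible_genes: set[str] | None = None,
) -> dict[str, dict[str, float | None]]:
    """Precision/recall per planted responder class.

    Genes failing the expression filters (absent from ``eligible_genes``)
    are excluded from the truth denominator. Precision with zero calls is
    reported as None (not applicable).
    """
    out: dict[str, dict[str, float | None]] = {}
    for cls in ("multi-tissue", "tissue-specific"):
        truth_pos = truth.genes_of_class(cls)
        if eligible_genes is not None:
            truth_pos &= eligible_genes
        called = {c.gene_id for c in calls if c.call_class == cls}
        tp = len(called & truth_pos)
        out[cls] = {
            "precision": tp / len(called) if called else None,
            "recall": tp / len(truth_pos) if truth_pos else None,
            "tp": tp,
            "n_called": len(called),
            "n_truth": len(truth_pos),
        }
    return out
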