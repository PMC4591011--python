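"""Response scoring across tissues.

For each tissue with a treated (SF) and control (GC) sample, a gene's
response score SR is log2(RPKM_SF / RPKM_GC); the composite responsiveness
of a gene over all tissues is the Euclidean norm of its SR vector (reported
as ||TSR||, printed as ||Z|| in tabular output). Genes are filtered on
minimum RPKM and read count in both conditions before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FilterDomainError, IncompleteDesignError, InvalidTableError
from .quantify import ExpressionTable

Scope = Literal["per-tissue", "all-tissues"]


@dataclass(frozen=True)
class FilterConfig:
    """Expression filter thresholds; both are inclusive lower bounds."""

    min_rpkm: float = 1.0
    min_reads: int = 5
    scope: Scope = "all-tissues"

    def __post_init__(self):
        if self.min_rpkm < 0:
            raise ValueError(f"min_rpkm must be >= 0, got {self.min_rpkm}")
        if self.min_reads < 0:
            raise ValueError(f"min_reads must be >= 0, got {self.min_reads}")
        if self.scope not in ("per-tissue", "all-tissues"):
            raise ValueError(f"unknown scope: {self.scope!r}")


@dataclass
class SRTable:
    """Per-gene SR per tissue plus the composite norm.

    ``sr`` is genes x tissues; ``tsr`` is the Euclidean norm of each row.
    """

    sr: pd.DataFrame
    tsr: pd.Series = field(default=None)

    def __post_init__(self):
        if self.tsr is None:
            self.tsr = pd.Series(
                np.linalg.norm(self.sr.to_numpy(), axis=1),
                index=self.sr.index,
                name="TSR",
            )

    @property
    def genes(self) -> list[str]:
        return list(self.sr.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.sr.columns)


@dataclass(frozen=True)
class ResponderCall:
    gene_id: str
    call_class: Literal[
        "twofold-up", "twofold-down", "multi-tissue", "tissue-specific"
    ]
    tissues: tuple[str, ...]
    direction: Literal["up", "down", "mixed"]


def _passes(expr: ExpressionTable, tissue: str, cfg: FilterConfig) -> pd.Series:
    """Boolean mask: gene passes RPKM and read thresholds in SF and GC."""
    sf, gc = expr.sample_pair(tissue)
    return (
        (expr.rpkm[sf] >= cfg.min_rpkm)
        & (expr.rpkm[gc] >= cfg.min_rpkm)
        & (expr.counts[sf] >= cfg.min_reads)
        & (expr.counts[gc] >= cfg.min_reads)
    )


def filter_genes(
    expr: ExpressionTable,
    cfg: FilterConfig,
    tissue: str | None = None,
    tissues: Sequence[str] | None = None,
) -> set[str]:
    """Genes passing the expression filter.

    ``per-tissue`` scope requires a ``tissue`` and returns genes passing in
    both its SF and GC samples; ``all-tissues`` scope returns genes passing
    in every tissue (``tissues`` defaults to all tissues in the table).
    Thresholds are inclusive.
    """
    if cfg.scope == "per-tissue":
        if tissue is None:
            raise IncompleteDesignError(
                "per-tissue filtering requires a tissue name"
            )
        mask = _passes(expr, tissue, cfg)
    else:
        scoped = list(tissues) if tissues is not None else expr.tissues
        if not scoped:
            raise IncompleteDesignError("no tissues to filter on")
        mask = pd.Series(True, index=expr.counts.index)
        for t in scoped:
            mask &= _passes(expr, t, cfg)
    return set(mask.index[mask])


def space_responsiveness(rpkm_sf: float, rpkm_gc: float) -> float:
    """log2 ratio of treated over control RPKM; antisymmetric under swap."""
    if rpkm_sf <= 0 or rpkm_gc <= 0:
        raise FilterDomainError(
            "SR requires positive RPKM in both conditions; "
            "apply filter_genes first"
        )
    return math.log2(rpkm_sf / rpkm_gc)


def total_space_responsiveness(sr_vector: Sequence[float]) -> float:
    """Euclidean norm of a gene's per-tissue SR vector."""
    v = np.asarray(sr_vector, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("sr_vector must be a non-empty 1-D sequence")
    if np.isnan(v).any():
        raise ValueError("sr_vector contains missing values")
    return float(np.linalg.norm(v))


def build_sr_table(
    expr: ExpressionTable,
    genes: Sequence[str] | set[str],
    tissues: Sequence[str] | None = None,
) -> SRTable:
    """SR matrix and composite norm for a filtered gene set."""
    tissues = list(tissues) if tissues is not None else expr.tissues
    genes = sorted(genes)
    sr = pd.DataFrame(index=pd.Index(genes, name="gene_id"), columns=tissues,
                      dtype=float)
    for t in tissues:
        sf, gc = expr.sample_pair(t)
        num = expr.rpkm.loc[genes, sf].to_numpy(dtype=float)
        den = expr.rpkm.loc[genes, gc].to_numpy(dtype=float)
        if (num <= 0).any() or (den <= 0).any():
            raise FilterDomainError(
                f"non-positive RPKM in tissue '{t}' among selected genes; "
                "apply filter_genes first"
            )
        sr[t] = np.log2(num / den)
    return SRTable(sr=sr)


def classify_twofold(sr: float) -> Literal["up", "down", "none"]:
    """Twofold responder direction for one SR value (inclusive at |SR|=1)."""
    if sr >= 1.0:
        return "up"
    if sr <= -1.0:
        return "down"
    return "none"


def twofold_counts(srt: SRTable) -> pd.DataFrame:
    """Per-tissue up/down/total twofold-responder counts."""
    rows = {}
    for t in srt.tissues:
        col = srt.sr[t]
        rows[t] = {
            "up": int((col >= 1.0).sum()),
            "down": int((col <= -1.0).sum()),
            "total": int(col.notna().sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tissue"
    return out


def multi_tissue_responders(
    srt: SRTable, sr_threshold: float = 1.0, min_tissues: int = 4
) -> list[ResponderCall]:
    """Genes with |SR| >= threshold in at least ``min_tissues`` tissues.

    Direction is up/down when every qualifying tissue agrees in sign,
    otherwise mixed.
    """
    calls = []
    abs_sr = srt.sr.abs()
    for gene in srt.genes:
        qual = abs_sr.loc[gene] >= sr_threshold
        if int(qual.sum()) < min_tissues:
            continue
        signs = np.sign(srt.sr.loc[gene][qual])
        if (signs > 0).all():
            direction = "up"
        elif (signs < 0).all():
            direction = "down"
        else:
            direction = "mixed"
        calls.append(
            ResponderCall(
                gene_id=gene,
                call_class="multi-tissue",
                tissues=tuple(srt.sr.columns[qual]),
                direction=direction,
            )
        )
    return calls


def tissue_specific_responders(
    srt: SRTable,
    focal_tissue: str,
    min_focal_sr: float = 2.0,
    dominance_ratio: float = 2.0,
) -> list[ResponderCall]:
    """Genes responding dominantly in one tissue.

    A gene is called when |SR| in the focal tissue is at least
    ``min_focal_sr``, is the largest absolute SR, and is at least
    ``dominance_ratio`` times the second-largest absolute SR.
    """
    if focal_tissue not in srt.tissues:
        raise KeyError(f"unknown tissue: {focal_tissue!r}")
    calls = []
    abs_sr = srt.sr.abs()
    others = [t for t in srt.tissues if t != focal_tissue]
    for gene in srt.genes:
        focal = abs_sr.at[gene, focal_tissue]
        if focal < min_focal_sr:
            continue
        second = abs_sr.loc[gene, others].max() if others else 0.0
        if focal <= second or focal < dominance_ratio * second:
            continue
        direction = "up" if srt.sr.at[gene, focal_tissue] > 0 else "down"
        calls.append(
            ResponderCall(
                gene_id=gene,
                call_class="tissue-specific",
                tissues=(focal_tissue,),
                direction=direction,
            )
        )
    return calls


def rank_top_n(srt: SRTable, n: int = 400) -> list[str]:
    """Top-n genes by composite norm, descending; ties break by gene id."""
    if n > len(srt.genes):
        raise ValueError(
            f"n={n} exceeds the number of genes ({len(srt.genes)})"
        )
    order = sorted(srt.genes, key=lambda g: (-srt.tsr[g], g))
    return order[:n]


def fisher_tissue_comparison(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> float:
    """Two-sided Fisher's exact p for two responder proportions.

    Tests the 2x2 table [[count_a, total_a - count_a],
    [count_b, total_b - count_b]] by summing probabilities of tables at
    most as probable as the observed one.
    """
    for name, c, t in (("a", count_a, total_a), ("b", count_b, total_b)):
        if c < 0 or t < 0 or c > t:
            raise InvalidTableError(
                f"group {name}: need 0 <= count <= total, got "
                f"count={c}, total={t}"
            )
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
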