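"""Gene-model flattening and RPKM quantification.

A gene model is the interval union ("integrated exons") of the exons of all
of the gene's transcripts; its total exonic length is the RPKM length
denominator. Counts are supplied pre-assigned to genes; the library size
(total mapped reads) is an input per sample and is never inferred by summing
gene counts, because multi-mapping and intergenic reads make that sum wrong.

Coordinates are 1-based with inclusive ends throughout (the GTF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IncompleteDesignError,
    InconsistentModelError,
    InvalidDenominatorError,
    MalformedIntervalError,
    UnknownGeneError,
)

Interval = tuple[int, int]


class Transcript(NamedTuple):
    """One transcript: an id plus its exon intervals on one chrom/strand."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]


@dataclass(frozen=True)
class GeneModel:
    """A gene's integrated exon set, derived from its transcripts.

    ``integrated_exons`` are pairwise disjoint, sorted by start, and their
    union contains every transcript exon. ``length_bp`` is the sum of the
    integrated interval lengths (inclusive coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]
    integrated_exons: tuple[Interval, ...]
    length_bp: int


@dataclass(frozen=True)
class SampleCounts:
    """Per-gene read counts for one (tissue, condition) sample."""

    sample_id: tuple[str, str]  # (tissue, "SF" | "GC")
    gene_counts: Mapping[str, int]
    total_mapped_reads: int

    @property
    def label(self) -> str:
        return f"{self.sample_id[0]}_{self.sample_id[1]}"


@dataclass
class ExpressionTable:
    """Counts and RPKM for every (gene, sample) cell.

    Columns are sample labels ``<tissue>_<SF|GC>``; rows are gene ids.
    ``total_mapped_reads`` is indexed by sample label.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    total_mapped_reads: pd.Series
    gene_lengths: pd.Series = field(default=None)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for col in self.counts.columns:
            tissue = col.rsplit("_", 1)[0]
            if tissue not in seen:
                seen.append(tissue)
        return seen

    def sample_pair(self, tissue: str) -> tuple[str, str]:
        """Return the (SF, GC) column labels for a tissue or raise."""
        sf, gc = f"{tissue}_SF", f"{tissue}_GC"
        missing = [s for s in (sf, gc) if s not in self.counts.columns]
        if missing:
            raise IncompleteDesignError(
                f"tissue '{tissue}' is missing sample(s): {', '.join(missing)}"
            )
        return sf, gc


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Union of 1-based inclusive intervals, sorted and disjoint.

    Adjacent-but-not-overlapping intervals ([1,5],[6,9]) are merged, since
    their union covers contiguous bases.
    """
    ivs = sorted(intervals)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def flatten_gene_model(
    gene_id: str, transcripts: Sequence[Transcript]
) -> GeneModel:
    """Flatten a gene's transcripts into its integrated exon set.

    When exons of different transcripts overlap or share a boundary, the
    union keeps the longer extent; arbitrary overlaps merge. Raises
    :class:`MalformedIntervalError` for an exon with start > end and
    :class:`InconsistentModelError` when transcripts disagree on chromosome
    or strand.
    """
    if not transcripts:
        raise InconsistentModelError(f"gene '{gene_id}' has no transcripts")
    chroms = {t.chrom for t in transcripts}
    strands = {t.strand for t in transcripts}
    if len(chroms) > 1:
        raise InconsistentModelError(
            f"gene '{gene_id}' has transcripts on multiple chromosomes: "
            f"{sorted(chroms)}"
        )
    if len(strands) > 1:
        raise InconsistentModelError(
            f"gene '{gene_id}' has transcripts on multiple strands: "
            f"{sorted(strands)}"
        )
    all_exons: list[Interval] = []
    for t in transcripts:
        for start, end in t.exons:
            if start > end:
                raise MalformedIntervalError(
                    f"gene '{gene_id}' transcript '{t.transcript_id}': "
                    f"exon [{start}, {end}] has start > end"
                )
            all_exons.append((int(start), int(end)))
    integrated = merge_intervals(all_exons)
    length = sum(e - s + 1 for s, e in integrated)
    return GeneModel(
        gene_id=gene_id,
        chrom=chroms.pop(),
        strand=strands.pop(),
        transcripts=tuple(transcripts),
        integrated_exons=integrated,
        length_bp=length,
    )


def compute_rpkm(count: float, length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of exon per million mapped reads.

    ``count / ((length_bp / 1e3) * (total_mapped_reads / 1e6))``.
    """
    if length_bp <= 0:
        raise InvalidDenominatorError(f"length_bp must be > 0, got {length_bp}")
    if total_mapped_reads <= 0:
        raise InvalidDenominatorError(
            f"total_mapped_reads must be > 0, got {total_mapped_reads}"
        )
    if count < 0:
        raise InvalidDenominatorError(f"count must be >= 0, got {count}")
    return count / ((length_bp / 1e3) * (total_mapped_reads / 1e6))


def quantify_samples(
    models: Mapping[str, GeneModel] | Iterable[GeneModel],
    samples: Sequence[SampleCounts],
) -> ExpressionTable:
    """Build the counts + RPKM table for a set of samples.

    Genes absent from a sample's count map get count 0 and RPKM 0. A gene
    counted in any sample but missing from ``models`` raises
    :class:`UnknownGeneError` listing the offending ids.
    """
    if not isinstance(models, Mapping):
        models = {m.gene_id: m for m in models}
    unknown: set[str] = set()
    for s in samples:
        unknown.update(g for g in s.gene_counts if g not in models)
    if unknown:
        raise UnknownGeneError(unknown)

    genes = sorted(models)
    labels = [s.label for s in samples]
    counts = pd.DataFrame(0, index=genes, columns=labels, dtype=np.int64)
    for s in samples:
        if s.gene_counts:
            col = pd.Series(s.gene_counts, dtype=np.int64)
            counts.loc[col.index, s.label] = col
    totals = pd.Series(
        {s.label: int(s.total_mapped_reads) for s in samples}, dtype=np.int64
    )
    lengths = pd.Series({g: models[g].length_bp for g in genes}, dtype=np.int64)
    if (lengths <= 0).any():
        raise InvalidDenominatorError("gene model with non-positive length")
    if (totals <= 0).any():
        raise InvalidDenominatorError("sample with non-positive library size")

    rpkm = counts / np.outer(lengths / 1e3, totals / 1e6)
    counts.index.name = rpkm.index.name = "gene_id"
    return ExpressionTable(
        counts=counts,
        rpkm=rpkm,
        total_mapped_reads=totals,
        gene_lengths=lengths,
    )
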