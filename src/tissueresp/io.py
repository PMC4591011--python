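"""Readers and writers for every file dialect the pipeline touches.

All tabular files are plain TSV. Numbers are serialized with ASCII
hyphen-minus; readers additionally accept typeset en-dash and true minus
signs. Intermediate tables are written at full precision so that
write-then-read is the identity; two-decimal rounding (half away from zero)
is applied only at report boundaries.
"""

from __future__ import annotations

import io as _io
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import TissuerespError
from .quantify import ExpressionTable, GeneModel, SampleCounts, Transcript, flatten_gene_model
from .responsiveness import ResponderCall, SRTable

logger = logging.getLogger("tissueresp")

_MINUS_VARIANTS = str.maketrans({"–": "-", "−": "-", "—": "-"})


class TableParseError(TissuerespError):
    """Malformed tabular record; message names row and column."""


class DuplicateRecordError(TissuerespError):
    """Duplicate gene_id in a table keyed by gene."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention; repr-stable)."""
    if math.isnan(x):
        return x
    scale = 10**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def _read_tsv(path) -> pd.DataFrame:
    """TSV -> DataFrame, normalizing unicode minus variants first."""
    text = Path(path).read_text().translate(_MINUS_VARIANTS)
    return pd.read_csv(_io.StringIO(text), sep="\t")


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

def read_gtf(path) -> dict[str, GeneModel]:
    """Parse exon features of a GTF into flattened gene models.

    Only ``exon`` features are used; ``gene_id`` and ``transcript_id``
    attributes are required. Coordinates are kept 1-based inclusive.
    """
    per_gene: dict[str, dict[str, dict]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise TableParseError(f"{path}:{line_no}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            attr_map = {}
            for item in attrs.rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, value = item.partition(" ")
                attr_map[key] = value.strip().strip('"')
            try:
                gene_id = attr_map["gene_id"]
                tx_id = attr_map["transcript_id"]
            except KeyError as exc:
                raise TableParseError(
                    f"{path}:{line_no}: missing attribute {exc}"
                ) from None
            tx = per_gene.setdefault(gene_id, {}).setdefault(
                tx_id, {"chrom": chrom, "strand": strand, "exons": []}
            )
            tx["exons"].append((int(start), int(end)))

    models = {}
    for gene_id, txs in per_gene.items():
        transcripts = [
            Transcript(tid, t["chrom"], t["strand"], tuple(sorted(t["exons"])))
            for tid, t in sorted(txs.items())
        ]
        models[gene_id] = flatten_gene_model(gene_id, transcripts)
    return models


def write_gtf(models: Mapping[str, GeneModel], path, source: str = "tissueresp") -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(models):
            m = models[gene_id]
            for tx in m.transcripts:
                for start, end in tx.exons:
                    attrs = (
                        f'gene_id "{gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        f"{m.chrom}\t{source}\texon\t{start}\t{end}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Counts / totals / RPKM
# ---------------------------------------------------------------------------

def read_counts_table(counts_path, totals_path) -> list[SampleCounts]:
    """Read a gene x sample count TSV plus its library-size companion.

    The counts file has a ``gene_id`` column and one column per sample
    named ``<tissue>_<SF|GC>``. Duplicate gene ids and non-integer counts
    are errors.
    """
    df = _read_tsv(counts_path)
    if "gene_id" not in df.columns:
        raise TableParseError(f"{counts_path}: missing 'gene_id' column")
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if not dupes.empty:
        raise DuplicateRecordError(
            f"{counts_path}: duplicate gene_id(s): "
            + ", ".join(map(str, dupes.unique()[:5]))
        )
    df = df.set_index("gene_id")
    if df.empty:
        logger.warning("%s: header-only counts table (no genes)", counts_path)
    for col in df.columns:
        if "_" not in col or col.rsplit("_", 1)[1] not in ("SF", "GC"):
            raise TableParseError(
                f"{counts_path}: sample column {col!r} is not "
                "'<tissue>_<SF|GC>'"
            )
        col_data = df[col]
        if col_data.empty:
            df[col] = col_data.astype("int64")
            continue
        if col_data.dtype.kind == "f":
            fractional = col_data.isna() | (col_data % 1 != 0)
            if fractional.any():
                row = df.index[fractional][0]
                raise TableParseError(
                    f"{counts_path}: non-integer count at gene {row!r}, "
                    f"column {col!r}"
                )
            col_data = col_data.astype("int64")
        elif col_data.dtype.kind not in "iu":
            raise TableParseError(
                f"{counts_path}: non-numeric count column {col!r}"
            )
        if (col_data < 0).any():
            row = df.index[col_data < 0][0]
            raise TableParseError(
                f"{counts_path}: negative count at gene {row!r}, column {col!r}"
            )
        df[col] = col_data.astype("int64")

    totals = read_totals(totals_path)
    missing = [c for c in df.columns if c not in totals]
    if missing:
        raise TableParseError(
            f"{totals_path}: missing totals for sample(s): {missing}"
        )
    samples = []
    for col in df.columns:
        tissue, cond = col.rsplit("_", 1)
        samples.append(
            SampleCounts(
                sample_id=(tissue, cond),
                gene_counts=df[col].to_dict(),
                total_mapped_reads=int(totals[col]),
            )
        )
    return samples


def read_totals(path) -> dict[str, int]:
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["sample", "total_mapped_reads"]:
        raise TableParseError(
            f"{path}: expected columns 'sample', 'total_mapped_reads'"
        )
    return dict(zip(df["sample"], df["total_mapped_reads"].astype(int)))


def write_counts_table(expr_or_samples, counts_path, totals_path) -> None:
    """Write counts + totals TSVs from an ExpressionTable or sample list."""
    if isinstance(expr_or_samples, ExpressionTable):
        counts = expr_or_samples.counts
        totals = expr_or_samples.total_mapped_reads.to_dict()
    else:
        samples: Sequence[SampleCounts] = expr_or_samples
        genes = sorted({g for s in samples for g in s.gene_counts})
        counts = pd.DataFrame(
            {s.label: [s.gene_counts.get(g, 0) for g in genes] for s in samples},
            index=pd.Index(genes, name="gene_id"),
        )
        totals = {s.label: s.total_mapped_reads for s in samples}
    counts.index.name = "gene_id"
    counts.to_csv(counts_path, sep="\t")
    with open(totals_path, "w") as fh:
        fh.write("sample\ttotal_mapped_reads\n")
        for label in counts.columns:
            fh.write(f"{label}\t{int(totals[label])}\n")


def write_rpkm_table(rpkm: pd.DataFrame, path) -> None:
    rpkm = rpkm.copy()
    rpkm.index.name = "gene_id"
    rpkm.to_csv(path, sep="\t")


def read_rpkm_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "gene_id" not in df.columns:
        raise TableParseError(f"{path}: missing 'gene_id' column")
    return df.set_index("gene_id")


# ---------------------------------------------------------------------------
# SR tables, responder calls, reports
# ---------------------------------------------------------------------------

def write_sr_table(srt: SRTable, path) -> None:
    out = srt.sr.copy()
    out["TSR"] = srt.tsr
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sr_table(path) -> SRTable:
    df = _read_tsv(path).set_index("gene_id")
    tsr = df.pop("TSR") if "TSR" in df.columns else None
    return SRTable(sr=df, tsr=tsr)


def write_responder_calls(calls: Iterable[ResponderCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\ttissues\tdirection\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.call_class}\t{','.join(c.tissues)}\t"
                f"{c.direction}\n"
            )


def read_responder_calls(path) -> list[ResponderCall]:
    calls = []
    df = _read_tsv(path)
    for _, row in df.iterrows():
        tissues = tuple(str(row["tissues"]).split(",")) if pd.notna(row["tissues"]) else ()
        calls.append(
            ResponderCall(
                gene_id=str(row["gene_id"]),
                call_class=row["class"],
                tissues=tissues,
                direction=row["direction"],
            )
        )
    return calls


def write_fisher_table(df: pd.DataFrame, path, alpha: float = 1e-4) -> None:
    """Fisher comparison report: tissue, counts, p, significance flag."""
    out = df.copy()
    out["significant"] = out["p"] < alpha
    out.to_csv(path, sep="\t", index=False)


def write_enrichment_table(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("go_id\tterm\tdirection\tk\tK\tn\tN\tp\tq\n")
        for r in results:
            fh.write(
                f"{r.go_id}\t{r.term_label}\t{r.direction}\t{r.k}\t{r.K}\t"
                f"{r.n}\t{r.N}\t{r.p:.6g}\t{r.q:.6g}\n"
            )
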