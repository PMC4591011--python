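"""GO annotation mapping and over-representation testing.

Species gene ids are annotated with GO terms through a three-step join:
species gene -> human ortholog gene id -> Entrez gene id -> GO ids. Each
link is many-to-many; a gene's resolved annotation is the union over all
paths. Over-representation of a GO category in a study set against a
background is scored with the hypergeometric upper tail, and p-values are
adjusted with the Benjamini-Hochberg step-up procedure. No GO-graph
propagation is performed: records are joined flat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AnnotationParseError, SubsetViolationError

GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class AnnotationMap:
    """gene -> GO ids via the ortholog / Entrez / GO join chain."""

    ortholog_map: Mapping[str, frozenset[str]]
    entrez_map: Mapping[str, frozenset[int]]
    go_map: Mapping[int, frozenset[str]]
    term_labels: Mapping[str, str] = field(default_factory=dict)
    resolved: Mapping[str, frozenset[str]] = field(init=False)

    def __post_init__(self):
        resolved: dict[str, frozenset[str]] = {}
        for gene, humans in self.ortholog_map.items():
            gos: set[str] = set()
            for h in humans:
                for entrez in self.entrez_map.get(h, ()):
                    gos.update(self.go_map.get(entrez, ()))
            resolved[gene] = frozenset(gos)
        self.resolved = resolved

    def go_ids(self, gene: str) -> frozenset[str]:
        """Resolved GO set; empty when any link in the chain is missing."""
        return self.resolved.get(gene, frozenset())

    def annotated_genes(self, genes: Iterable[str]) -> set[str]:
        return {g for g in genes if self.go_ids(g)}


def _read_tsv_rows(path, n_fields: int, skip_comments: bool = True):
    """Yield (line_no, fields) from a TSV, skipping '#' comments and blanks."""
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (skip_comments and line.startswith("#")):
                continue
            fields = line.split("\t")
            if len(fields) < n_fields:
                raise AnnotationParseError(
                    path, line_no,
                    f"expected >= {n_fields} tab-separated fields, "
                    f"got {len(fields)}",
                )
            yield line_no, fields


def build_annotation_map(
    ortholog_tsv, gene2ensembl_tsv, gene2go_tsv
) -> AnnotationMap:
    """Assemble an :class:`AnnotationMap` from the three mapping files.

    File dialects:

    * ortholog TSV: ``species_gene_id <tab> human_gene_id``
    * gene2ensembl-style TSV: ``tax_id <tab> entrez_id <tab> ensembl_gene_id``
    * gene2go-style TSV: ``tax_id <tab> entrez_id <tab> go_id <tab> evidence
      <tab> qualifier <tab> term_label``

    Empty files produce empty maps (a warning state, not an error).
    Malformed GO ids raise :class:`AnnotationParseError` with the line.
    """
    ortho: dict[str, set[str]] = {}
    for _, f in _read_tsv_rows(ortholog_tsv, 2):
        if f[1]:
            ortho.setdefault(f[0], set()).add(f[1])

    entrez: dict[str, set[int]] = {}
    for line_no, f in _read_tsv_rows(gene2ensembl_tsv, 3):
        try:
            eid = int(f[1])
        except ValueError:
            raise AnnotationParseError(
                gene2ensembl_tsv, line_no, f"non-integer Entrez id {f[1]!r}"
            ) from None
        entrez.setdefault(f[2], set()).add(eid)

    go: dict[int, set[str]] = {}
    labels: dict[str, str] = {}
    for line_no, f in _read_tsv_rows(gene2go_tsv, 3):
        go_id = f[2]
        if not GO_ID_RE.match(go_id):
            raise AnnotationParseError(
                gene2go_tsv, line_no, f"malformed GO id {go_id!r}"
            )
        try:
            eid = int(f[1])
        except ValueError:
            raise AnnotationParseError(
                gene2go_tsv, line_no, f"non-integer Entrez id {f[1]!r}"
            ) from None
        go.setdefault(eid, set()).add(go_id)
        if len(f) >= 6 and f[5]:
            labels.setdefault(go_id, f[5])

    return AnnotationMap(
        ortholog_map={k: frozenset(v) for k, v in ortho.items()},
        entrez_map={k: frozenset(v) for k, v in entrez.items()},
        go_map={k: frozenset(v) for k, v in go.items()},
        term_labels=labels,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    go_id: str
    term_label: str
    k: int  # study hits
    K: int  # category size in background
    n: int  # study size
    N: int  # background size
    p: float
    q: float = float("nan")
    direction: Literal["up", "down", "all"] = "all"

    def with_q(self, q: float) -> "EnrichmentResult":
        return EnrichmentResult(
            self.go_id, self.term_label, self.k, self.K, self.n, self.N,
            self.p, q, self.direction,
        )


def hypergeometric_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    ann: AnnotationMap,
    direction: Literal["up", "down", "all"] = "all",
    restrict_to_annotated: bool = True,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test for every GO category in the background.

    For a category with K members among N background genes and k hits in a
    study of n genes, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    By default the background (and study) are restricted to genes carrying
    at least one resolved GO annotation. BH-adjusted q-values are filled in
    across all tested categories. Results are sorted by (p, go_id).
    """
    study = set(study)
    background = set(background)
    if not study <= background:
        extra = sorted(study - background)[:5]
        raise SubsetViolationError(
            f"study set is not a subset of the background "
            f"(e.g. {', '.join(extra)})"
        )
    if restrict_to_annotated:
        background = ann.annotated_genes(background)
        study = study & background

    N, n = len(background), len(study)
    category_members: dict[str, set[str]] = {}
    for gene in background:
        for go_id in ann.go_ids(gene):
            category_members.setdefault(go_id, set()).add(gene)

    results = []
    for go_id in sorted(category_members):
        members = category_members[go_id]
        K = len(members)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                go_id=go_id,
                term_label=ann.term_labels.get(go_id, ""),
                k=k, K=K, n=n, N=N,
                p=min(p, 1.0),
                direction=direction,
            )
        )
    qs = bh_adjust([r.p for r in results])
    results = [r.with_q(q) for r, q in zip(results, qs)]
    results.sort(key=lambda r: (r.p, r.go_id))
    return results


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, input order preserved.

    q_(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted scale.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = adjusted
    return q.tolist()


def significant_terms(
    results: Iterable[EnrichmentResult],
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> list[EnrichmentResult]:
    """Results with p < p_cut and q < q_cut, sorted by (p, go_id)."""
    kept = [r for r in results if r.p < p_cut and r.q < q_cut]
    kept.sort(key=lambda r: (r.p, r.go_id))
    return kept
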