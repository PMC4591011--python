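"""Hierarchical clustering of response-score profiles.

Reimplements the clustering conventions of Eisen's Cluster 3.0: pairwise
distances over gene SR vectors (uncentered correlation by default),
average-linkage agglomeration, and tab-delimited CDT/GTR output that Java
TreeView can open. GTR records joining *similarities* (1 - distance), which
are non-increasing along the merge sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConsistencyError, UndefinedDistanceError
from .responsiveness import SRTable

Metric = Literal["uncentered-correlation", "centered-correlation", "euclidean"]


@dataclass
class ClusterTree:
    """Dendrogram over a fixed, ordered gene list.

    ``merges`` follows the scipy node convention: leaves are nodes
    ``0..n-1`` in input order; merge ``i`` creates node ``n + i`` joining
    ``(node_a, node_b)`` at the recorded similarity. ``leaf_order`` is the
    left-to-right leaf permutation of the dendrogram.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[int, ...]

    def __post_init__(self):
        if len(self.merges) != len(self.leaves) - 1:
            raise ConsistencyError(
                f"{len(self.leaves)} leaves require "
                f"{len(self.leaves) - 1} merges, got {len(self.merges)}"
            )

    @property
    def ordered_genes(self) -> list[str]:
        return [self.leaves[i] for i in self.leaf_order]

    def linkage_matrix(self) -> np.ndarray:
        """Scipy-style linkage matrix (distances = 1 - similarity)."""
        n = len(self.leaves)
        sizes = {}
        z = np.zeros((n - 1, 4))
        for i, (a, b, sim) in enumerate(self.merges):
            size = sizes.get(a, 1) + sizes.get(b, 1)
            sizes[n + i] = size
            z[i] = [a, b, 1.0 - sim, size]
        return z


def sr_distance_matrix(
    srt: SRTable,
    genes: Sequence[str] | None = None,
    metric: Metric = "uncentered-correlation",
) -> np.ndarray:
    """Symmetric gene-by-gene distance matrix over SR vectors.

    Correlation metrics return ``1 - r`` (uncentered r omits mean
    subtraction, Cluster 3.0's default). A zero-norm vector (uncentered) or
    zero-variance vector (centered) has no defined correlation and raises
    :class:`UndefinedDistanceError` naming the gene.
    """
    genes = list(genes) if genes is not None else srt.genes
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    x = srt.sr.loc[genes].to_numpy(dtype=float)

    if metric == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    elif metric in ("uncentered-correlation", "centered-correlation"):
        if metric == "centered-correlation":
            x = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((x**2).sum(axis=1))
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            kind = ("zero-variance" if metric == "centered-correlation"
                    else "zero-norm")
            raise UndefinedDistanceError(
                f"{kind} SR vector for gene '{genes[bad[0]]}' under {metric}"
            )
        r = (x @ x.T) / np.outer(norms, norms)
        d = 1.0 - np.clip(r, -1.0, 1.0)
    else:
        raise ValueError(f"unknown metric: {metric!r}")

    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage_tree(
    dist: np.ndarray, genes: Sequence[str] | None = None
) -> ClusterTree:
    """Agglomerative average-linkage (UPGMA) dendrogram of a distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dist must be a square matrix")
    n = dist.shape[0]
    if genes is None:
        genes = [f"G{i}" for i in range(n)]
    elif len(genes) != n:
        raise ConsistencyError(
            f"gene list length {len(genes)} != matrix size {n}"
        )
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    merges = tuple(
        (int(a), int(b), 1.0 - float(h)) for a, b, h, _ in z
    )
    order = tuple(int(i) for i in hierarchy.leaves_list(z))
    return ClusterTree(leaves=tuple(genes), merges=merges, leaf_order=order)


def cut_tree(tree: ClusterTree, k: int = 5) -> dict[str, int]:
    """Partition into exactly k clusters by undoing the last k-1 merges.

    Labels run 1..k in order of first appearance along the dendrogram's
    leaf order.
    """
    n = len(tree.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (a, b, _) in enumerate(tree.merges[: n - k]):
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node

    labels: dict[str, int] = {}
    root_label: dict[int, int] = {}
    for leaf_idx in tree.leaf_order:
        root = find(leaf_idx)
        if root not in root_label:
            root_label[root] = len(root_label) + 1
        labels[tree.leaves[leaf_idx]] = root_label[root]
    assert len(root_label) == k
    return labels


def _node_name(idx: int, n: int) -> str:
    return f"GENE{idx}X" if idx < n else f"NODE{idx - n + 1}X"


def write_cdt_gtr(srt: SRTable, tree: ClusterTree, cdt_path, gtr_path) -> None:
    """Write Cluster-3.0 dialect CDT and GTR files for a gene tree.

    The CDT lists genes in dendrogram leaf order with GID/ORF/NAME/GWEIGHT
    leading columns; the GTR lists one merge per line as
    ``NODEmX <tab> child <tab> child <tab> similarity``.
    """
    missing = set(tree.leaves) - set(srt.genes)
    if missing:
        raise ConsistencyError(
            f"tree genes absent from SR table: {sorted(missing)[:5]}"
        )
    n = len(tree.leaves)
    tissues = srt.tissues
    with open(gtr_path, "w") as fh:
        for i, (a, b, sim) in enumerate(tree.merges):
            fh.write(
                f"NODE{i + 1}X\t{_node_name(a, n)}\t{_node_name(b, n)}\t"
                f"{sim:.6f}\n"
            )
    with open(cdt_path, "w") as fh:
        fh.write("GID\tORF\tNAME\tGWEIGHT\t" + "\t".join(tissues) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t1.000000" * len(tissues) + "\n")
        for leaf_idx in tree.leaf_order:
            gene = tree.leaves[leaf_idx]
            vals = "\t".join(
                f"{srt.sr.at[gene, t]:.6f}" for t in tissues
            )
            fh.write(f"GENE{leaf_idx}X\t{gene}\t{gene}\t1.000000\t{vals}\n")


def read_gtr(gtr_path, n_leaves: int) -> tuple[tuple[int, int, float], ...]:
    """Parse a GTR file back into scipy-convention merge triples."""

    def parse(name: str) -> int:
        if name.startswith("GENE"):
            return int(name[4:-1])
        return n_leaves + int(name[4:-1]) - 1

    merges = []
    with open(gtr_path) as fh:
        for line in fh:
            _, a, b, sim = line.rstrip("\n").split("\t")
            merges.append((parse(a), parse(b), float(sim)))
    return tuple(merges)


def read_cdt(cdt_path) -> tuple[list[str], list[int], list[str]]:
    """Parse a CDT: (genes in row order, leaf indices, tissue columns)."""
    genes, idx = [], []
    with open(cdt_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        tissues = header[4:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "EWEIGHT":
                continue
            idx.append(int(fields[0][4:-1]))
            genes.append(fields[1])
    return genes, idx, tissues
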