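"""Breed clustering: Euclidean distances over frequency vectors and
unweighted average-linkage (UPGMA) agglomeration with deterministic
tie-breaking, plus Newick export.

Works on any haplotype-x-breed or variant-x-breed frequency matrix;
absent entries count as zero, frequencies are used unstandardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .models import CaseinhapError


class ClusterError(CaseinhapError):
    pass


def euclidean_distances(freq_table: pd.DataFrame,
                        exclude_rows: tuple[str, ...] = ()) -> pd.DataFrame:
    """Pairwise Euclidean distances between the columns of a frequency
    table (breeds)."""
    table = freq_table.drop(index=[r for r in exclude_rows
                                   if r in freq_table.index])
    if table.isna().any().any():
        raise ClusterError("frequency table contains NaN")
    mat = squareform(pdist(table.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(mat, index=table.columns, columns=table.columns)


def nearest_breed(dist: pd.DataFrame, breed: str) -> str:
    """Closest other column by distance (ties: lexicographic)."""
    col = dist[breed].drop(index=breed)
    best = col.min()
    return sorted(col.index[col == best])[0]


@dataclass
class Node:
    """Dendrogram node; leaves carry a label, internal nodes two children
    and a merge height."""

    label: str | None = None
    left: "Node | None" = None
    right: "Node | None" = None
    height: float = 0.0
    size: int = 1

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()


@dataclass
class Dendrogram:
    root: Node

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def merge_heights(self) -> list[float]:
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append(node.height)
                walk(node.left)
                walk(node.right)
        walk(self.root)
        return sorted(out)


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    The closest pair is merged first; inter-cluster distance is the
    unweighted mean of member pairwise distances.  Ties are broken by the
    lexicographically smallest pair of cluster keys (a cluster's key is
    its smallest leaf label), so the tree is permutation-invariant.
    """
    labels = list(dist.index)
    if len(labels) < 2:
        raise ClusterError("need at least two items to cluster")
    D = {(a, b): float(dist.loc[a, b]) for a in labels for b in labels if a != b}
    clusters: dict[str, Node] = {lab: Node(label=lab) for lab in labels}

    def key(a, b):
        return (min(a, b), max(a, b))

    while len(clusters) > 1:
        best = min(
            ((D[key(a, b)], *key(a, b)) for a in clusters for b in clusters
             if a < b),
        )
        d, a, b = best
        na, nb = clusters[a].size, clusters[b].size
        merged = Node(left=clusters[a], right=clusters[b], height=d,
                      size=na + nb)
        del clusters[a], clusters[b]
        new_key = min(a, b)
        for c in clusters:
            dc = (na * D[key(a, c)] + nb * D[key(b, c)]) / (na + nb)
            D[key(new_key, c)] = dc
        clusters[new_key] = merged
    return Dendrogram(root=next(iter(clusters.values())))


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths = parent height - child height."""

    def render(node: Node, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{length:.6f}"
        inner = ",".join(render(c, node.height)
                         for c in (node.left, node.right))
        return f"({inner}):{length:.6f}"

    root = dendrogram.root
    inner = ",".join(render(c, root.height) for c in (root.left, root.right))
    return f"({inner});"


def linkage_matrix(dist: pd.DataFrame) -> np.ndarray:
    """Scipy-style linkage matrix from the same UPGMA (for plotting or
    cross-checks against :func:`scipy.cluster.hierarchy.linkage`)."""
    from scipy.cluster.hierarchy import linkage

    condensed = squareform(dist.to_numpy(), checks=False)
    return linkage(condensed, method="average")
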