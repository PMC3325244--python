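"""Unsupervised check: complete-linkage hierarchical clustering of sample
profiles, with dendrogram cuts scored by Fisher's exact test.

Agglomerative complete linkage on Euclidean distances produces a
dendrogram whose merge heights are non-decreasing; cutting it at a height
(or target cluster count) yields sample clusters whose association with
the diagnostic classes is scored by a two-tailed Fisher exact test on the
2x2 cluster-membership x class table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .datatypes import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "hierarchical_cluster",
    "cut_and_test",
    "fisher_exact_2x2",
]


@dataclass
class Dendrogram:
    """A complete-linkage merge tree over samples.

    ``merges`` is a scipy linkage matrix (child, child, height, count);
    heights are non-decreasing (the ultrametric property of complete
    linkage).
    """

    merges: np.ndarray
    leaf_ids: list[str]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.merges, self.leaf_ids)
        return str(tree).strip()


def hierarchical_cluster(matrix: ExpressionMatrix) -> Dendrogram:
    """Agglomerative complete-linkage clustering on Euclidean distances."""
    ids = matrix.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least two samples to cluster")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    merges = linkage(pdist(matrix.values, metric="euclidean"),
                     method="complete")
    return Dendrogram(merges, list(ids))


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-tailed Fisher exact p for a 2x2 table.

    Sums, over all tables with the observed margins, the probabilities of
    tables whose point probability does not exceed the observed one (the
    convention of the standard implementations).
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("a 2x2 table is required")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise ValueError("table entries must be non-negative integers")
        table = table.astype(int)
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def cut_and_test(dendrogram: Dendrogram, labels,
                 heights: list[float] | None = None,
                 n_clusters: list[int] | None = None) -> pd.DataFrame:
    """Cut the dendrogram and score each cut's class association.

    Each cut yielding two clusters produces one two-tailed Fisher p-value
    from the 2x2 cluster x class table; cuts with more clusters are scored
    one-cluster-vs-rest (a Bonferroni note applies — the per-cluster
    p-values are not adjusted here).  Cuts leaving a single cluster are
    skipped with a warning.

    Returns a table with columns cut_type, cut_value, n_clusters, cluster
    and fisher_p.
    """
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("binary labels required")
    if len(y) != len(dendrogram.leaf_ids):
        raise ValueError("labels must align with dendrogram leaves")
    cuts: list[tuple[str, float]] = []
    if heights is not None:
        cuts += [("height", float(h)) for h in heights]
    if n_clusters is not None:
        cuts += [("maxclust", int(k)) for k in n_clusters]
    if not cuts:
        raise ValueError("give heights and/or n_clusters")

    pos = y == np.unique(y)[0]
    rows = []
    for cut_type, value in cuts:
        if cut_type == "height":
            assign = fcluster(dendrogram.merges, t=value, criterion="distance")
        else:
            assign = fcluster(dendrogram.merges, t=value, criterion="maxclust")
        clusters = np.unique(assign)
        if clusters.size < 2:
            warnings.warn(f"cut {cut_type}={value} produced a single "
                          "cluster; skipped", stacklevel=2)
            continue
        for c in clusters:
            inside = assign == c
            table = np.array([[np.sum(inside & pos), np.sum(inside & ~pos)],
                              [np.sum(~inside & pos), np.sum(~inside & ~pos)]])
            rows.append({"cut_type": cut_type, "cut_value": value,
                         "n_clusters": int(clusters.size), "cluster": int(c),
                         "fisher_p": fisher_exact_2x2(table)})
            if clusters.size == 2:
                break  # the two one-vs-rest tables are identical
    return pd.DataFrame(rows)
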