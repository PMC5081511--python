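"""Clustering of lncRNA modules by co-expressed-mRNA overlap.

The association index between two lncRNAs is the arithmetic mean of the
Jaccard and Simpson (overlap) coefficients of their co-expressed mRNA
sets; 1 - association serves as the distance for average-linkage
hierarchical clustering. Small clusters (fewer than five lncRNAs by
default) are set aside. A separate routine clusters enrichment-profile
matrices (rows/columns) with Pearson-correlation distance and complete
linkage for heatmap ordering.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from lncmod.enrichment import jaccard, simpson

__all__ = [
    "association_index",
    "association_matrix",
    "hierarchical_cluster",
    "filter_clusters",
    "profile_heatmap_cluster",
]


def association_index(genes_a: Iterable[str], genes_b: Iterable[str]) -> float:
    """(JC + OC) / 2 of two gene sets, in [0, 1]."""
    a, b = set(genes_a), set(genes_b)
    if not a or not b:
        raise ValueError("association index of an empty gene set is undefined")
    return (jaccard(a, b) + simpson(a, b)) / 2.0


def association_matrix(partner_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Symmetric lncRNA x lncRNA association-index matrix.

    lncRNAs are ordered lexicographically, which also fixes the merge
    order of downstream clustering when distances tie.
    """
    ids = sorted(partner_sets)
    sets = {k: set(partner_sets[k]) for k in ids}
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = association_index(sets[ids[i]], sets[ids[j]])
    return pd.DataFrame(mat, index=ids, columns=ids)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    linkage: str = "average",
    n_clusters: int | None = None,
    height: float | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Agglomerative clustering on 1 - association distances.

    Returns the scipy linkage matrix and, if ``n_clusters`` or ``height``
    is given, a flat assignment lncRNA -> cluster label (1-based).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if n_clusters is not None and height is not None:
        raise ValueError("give at most one of n_clusters / height")
    dist = 1.0 - matrix.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    labels: dict[str, int] = {}
    if n_clusters is not None:
        flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        labels = dict(zip(matrix.index, (int(c) for c in flat)))
    elif height is not None:
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
        labels = dict(zip(matrix.index, (int(c) for c in flat)))
    return Z, labels


def filter_clusters(
    labels: Mapping[str, int], min_members: int = 5
) -> tuple[dict[str, int], list[str]]:
    """Drop clusters with fewer than ``min_members`` lncRNAs.

    Returns the retained assignment and the list of unassigned lncRNAs.
    """
    sizes: dict[int, int] = {}
    for c in labels.values():
        sizes[c] = sizes.get(c, 0) + 1
    kept = {k: c for k, c in labels.items() if sizes[c] >= min_members}
    unassigned = sorted(k for k in labels if k not in kept)
    return kept, unassigned


def clusters_as_sets(labels: Mapping[str, int]) -> list[set[str]]:
    """Group a flat assignment into member sets, largest first."""
    groups: dict[int, set[str]] = {}
    for k, c in labels.items():
        groups.setdefault(c, set()).add(k)
    return sorted(groups.values(), key=lambda s: (-len(s), sorted(s)))


def _pearson_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; zero-variance rows get r = 0."""
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    flat = norms == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance profile(s): correlation taken as 0",
            stacklevel=3,
        )
    norms[flat] = 1.0
    unit = centered / norms[:, None]
    r = unit @ unit.T
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    return dist


def profile_heatmap_cluster(
    matrix: pd.DataFrame,
    linkage: str = "complete",
) -> dict:
    """Cluster an enrichment-profile matrix for heatmap rendering.

    Rows and columns are clustered independently with
    distance = 1 - Pearson correlation (range [0, 2]) and the requested
    linkage (complete by default). Returns a dict with linkage matrices
    (``None`` for a single row/column) and leaf orderings.
    """

    def one_axis(data: np.ndarray, names: Sequence) -> tuple[np.ndarray | None, list]:
        if data.shape[0] < 2:
            return None, list(names)
        Z = hierarchy.linkage(squareform(_pearson_distance_matrix(data), checks=False),
                              method=linkage)
        order = hierarchy.leaves_list(Z)
        return Z, [names[i] for i in order]

    row_Z, row_order = one_axis(matrix.to_numpy(dtype=float), list(matrix.index))
    col_Z, col_order = one_axis(matrix.to_numpy(dtype=float).T, list(matrix.columns))
    return {
        "row_linkage": row_Z,
        "col_linkage": col_Z,
        "row_order": row_order,
        "col_order": col_order,
        "ordered": matrix.loc[row_order, col_order],
    }
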