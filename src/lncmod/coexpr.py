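"""Bipartite lncRNA-mRNA co-expression network from mutual correlation ranks.

Co-expression between a lncRNA and an mRNA is measured by the Spearman
correlation coefficient (SCC); |SCC| is ranked in both directions (the
mRNA's rank among all mRNAs from the lncRNA's view, and vice versa) and
the mutual rank MR = sqrt(rank_ab * rank_ba) is the geometric mean of the
two. Mutually top-ranked pairs (small MR) are selected as co-expressed,
either as a top fraction of all lncRNA x mRNA pairs or by an explicit MR
cutoff. Ranking by mutual rank rather than raw correlation lets a pair
with modest absolute correlation qualify when neither partner has any
stronger alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lncmod.data_io import ExpressionMatrix

__all__ = [
    "CoexpressionNetwork",
    "spearman_lnc_mrna",
    "mutual_rank",
    "select_coexpressed",
    "build_coexpression_network",
]


@dataclass
class CoexpressionNetwork:
    """Selected lncRNA-mRNA co-expression edges.

    ``edges`` has columns ``lnc, mrna, scc, rank_lnc_to_mrna,
    rank_mrna_to_lnc, mr``; ``selection`` records the selection mode and
    the realized MR cutoff.
    """

    edges: pd.DataFrame
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"lnc", "mrna", "scc", "rank_lnc_to_mrna", "rank_mrna_to_lnc", "mr"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")
        if self.edges.duplicated(["lnc", "mrna"]).any():
            raise ValueError("duplicate (lnc, mrna) pair in edge table")

    @property
    def neighbors(self) -> dict[str, list[str]]:
        """lncRNA -> co-expressed mRNAs, ordered by increasing MR."""
        ordered = self.edges.sort_values(["lnc", "mr", "mrna"], kind="mergesort")
        return {
            lnc: grp["mrna"].tolist() for lnc, grp in ordered.groupby("lnc", sort=True)
        }

    @property
    def partner_sets(self) -> dict[str, set[str]]:
        return {lnc: set(ms) for lnc, ms in self.neighbors.items()}

    @property
    def degrees(self) -> dict[str, int]:
        return {lnc: len(ms) for lnc, ms in self.neighbors.items()}

    def to_tsv(self, path) -> None:
        out = self.edges.sort_values(["lnc", "mr", "mrna"], kind="mergesort")
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def spearman_lnc_mrna(expr: ExpressionMatrix) -> pd.DataFrame:
    """Spearman correlation of every lncRNA against every mRNA.

    Returns a (lncRNA x mRNA) DataFrame of signed correlations. Ties get
    average ranks; genes with constant expression have undefined
    correlation, recorded as 0 with a warning.
    """
    if expr.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for Spearman correlation")
    lncs, mrnas = expr.lnc_ids, expr.mrna_ids
    mat = expr.values.to_numpy(dtype=float)
    ranks = stats.rankdata(mat, axis=1)  # average ranks by default
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        warnings.warn(
            "constant expression, correlation recorded as 0: "
            f"{[g for g, c in zip(expr.gene_ids, constant) if c]}",
            stacklevel=2,
        )
    norms[constant] = 1.0
    unit = centered / norms[:, None]
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    li = [idx[g] for g in lncs]
    mi = [idx[g] for g in mrnas]
    corr = unit[li] @ unit[mi].T
    corr[np.asarray(constant)[li], :] = 0.0
    corr[:, np.asarray(constant)[mi]] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    return pd.DataFrame(corr, index=lncs, columns=mrnas)


def mutual_rank(corr: pd.DataFrame) -> pd.DataFrame:
    """Mutual-rank matrix from a signed (lncRNA x mRNA) correlation matrix.

    |corr| is ranked descending within each row (the lncRNA's view over
    all mRNAs, rank 1 = largest) and within each column (the mRNA's view
    over all lncRNAs); ties get average ranks. MR is the geometric mean of
    the two directional ranks, so MR = 1 means mutually top-ranked.
    """
    a = np.abs(corr.to_numpy(dtype=float))
    if not np.isfinite(a).all():
        raise ValueError("correlation matrix contains non-finite values")
    rank_row = stats.rankdata(-a, axis=1)
    rank_col = stats.rankdata(-a, axis=0)
    mr = np.sqrt(rank_row * rank_col)
    return pd.DataFrame(mr, index=corr.index, columns=corr.columns)


def directional_ranks(corr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two |corr| rank matrices behind the MR index (row view, column view)."""
    a = np.abs(corr.to_numpy(dtype=float))
    rank_row = stats.rankdata(-a, axis=1)
    rank_col = stats.rankdata(-a, axis=0)
    return (
        pd.DataFrame(rank_row, index=corr.index, columns=corr.columns),
        pd.DataFrame(rank_col, index=corr.index, columns=corr.columns),
    )


def select_coexpressed(
    mr: pd.DataFrame,
    corr: pd.DataFrame,
    top_fraction: float | None = None,
    mr_cutoff: float | None = None,
) -> CoexpressionNetwork:
    """Keep the mutually top-ranked (smallest-MR) lncRNA-mRNA pairs.

    Exactly one of ``top_fraction`` (default 0.001 if neither is given) or
    ``mr_cutoff`` selects the pairs: a fraction keeps
    floor(fraction * n_pairs) pairs plus every pair tied with the boundary
    MR; a cutoff keeps pairs with MR <= cutoff. The realized cutoff is
    recorded in ``selection``.
    """
    if top_fraction is not None and mr_cutoff is not None:
        raise ValueError("give exactly one of top_fraction / mr_cutoff")
    if top_fraction is None and mr_cutoff is None:
        top_fraction = 0.001
    if mr.shape != corr.shape:
        raise ValueError("mr and corr shapes differ")

    mr_values = mr.to_numpy(dtype=float)
    n_pairs = mr_values.size
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        n_keep = int(math.floor(top_fraction * n_pairs))
        if n_keep == 0:
            cutoff = -np.inf  # keeps nothing
        else:
            cutoff = float(np.partition(mr_values.ravel(), n_keep - 1)[n_keep - 1])
        mode = {"mode": "top_fraction", "top_fraction": top_fraction}
    else:
        cutoff = float(mr_cutoff)
        mode = {"mode": "mr_cutoff"}

    keep = mr_values <= cutoff
    li, mi = np.nonzero(keep)
    rank_row, rank_col = directional_ranks(corr)
    edges = pd.DataFrame(
        {
            "lnc": mr.index.to_numpy()[li],
            "mrna": mr.columns.to_numpy()[mi],
            "scc": corr.to_numpy()[li, mi],
            "rank_lnc_to_mrna": rank_row.to_numpy()[li, mi],
            "rank_mrna_to_lnc": rank_col.to_numpy()[li, mi],
            "mr": mr_values[li, mi],
        }
    )
    edges = edges.sort_values(["mr", "lnc", "mrna"], kind="mergesort").reset_index(drop=True)
    mode["mr_cutoff"] = cutoff
    mode["n_selected"] = int(len(edges))
    return CoexpressionNetwork(edges, selection=mode)


def build_coexpression_network(
    expr: ExpressionMatrix,
    top_fraction: float | None = None,
    mr_cutoff: float | None = None,
) -> CoexpressionNetwork:
    """Full chain: Spearman correlations -> mutual ranks -> selection."""
    corr = spearman_lnc_mrna(expr)
    mr = mutual_rank(corr)
    return select_coexpressed(mr, corr, top_fraction=top_fraction, mr_cutoff=mr_cutoff)
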