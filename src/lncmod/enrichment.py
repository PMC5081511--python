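"""GO over-representation analysis and the enriched-term overlap network.

Each GO term is tested by the one-sided Fisher exact test — equivalently
the hypergeometric upper tail P(X >= k_hit) — against a background gene
universe, with Benjamini-Hochberg correction across terms. Significant
terms are organized into a network whose edges score the overlap of
hit-gene sets by the arithmetic mean of the Jaccard and Simpson
coefficients.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncmod.data_io import GoResource
from lncmod.go_semantics import DEFAULT_NAMESPACE

__all__ = [
    "fisher_enrichment",
    "bh_adjust",
    "enrich",
    "enrichment_overlap_network",
    "enrichment_profile_matrix",
]


def hypergeom_upper_tail(k_hit: int, n_module: int, K_term: int, N_bg: int) -> float:
    """P(X >= k_hit) for X ~ Hypergeom(N_bg, K_term, n_module)."""
    return float(stats.hypergeom.sf(k_hit - 1, N_bg, K_term, n_module))


def fisher_enrichment(
    module_genes: Iterable[str],
    go: GoResource,
    background: Iterable[str],
    namespace: str = DEFAULT_NAMESPACE,
) -> pd.DataFrame:
    """One-sided Fisher enrichment p per GO term for a module's genes.

    Only the module genes and background genes carrying >= 1 annotation in
    the namespace enter the 2x2 tables; only terms annotating >= 1
    background gene are tested. Returns one row per tested term with
    columns ``term, name, k_hit, n_module, K_term, N_bg, p_raw,
    hit_genes``; BH correction is applied separately (see :func:`enrich`).
    """
    bg = set(background)
    module = set(module_genes)
    outside = module - bg
    if outside:
        raise ValueError(f"module genes outside background: {sorted(outside)[:5]}")
    ns_terms = go.terms_in_namespace(namespace)
    bg_annot = sorted(g for g in bg if go.gene_terms(g, namespace))
    mod_annot = sorted(g for g in module if go.gene_terms(g, namespace))
    N_bg = len(bg_annot)
    n_module = len(mod_annot)
    rows = []
    for term in sorted(ns_terms):
        term_bg = go.term_genes.get(term, set()) & set(bg_annot)
        K_term = len(term_bg)
        if K_term == 0:
            continue
        hits = sorted(term_bg & set(mod_annot))
        k_hit = len(hits)
        p = hypergeom_upper_tail(k_hit, n_module, K_term, N_bg)
        rows.append(
            {
                "term": term,
                "name": go.term_names.get(term, term),
                "k_hit": k_hit,
                "n_module": n_module,
                "K_term": K_term,
                "N_bg": N_bg,
                "p_raw": p,
                "hit_genes": ",".join(hits),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["term", "name", "k_hit", "n_module", "K_term", "N_bg", "p_raw", "hit_genes"],
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    module_genes: Iterable[str],
    go: GoResource,
    background: Iterable[str],
    namespace: str = DEFAULT_NAMESPACE,
) -> pd.DataFrame:
    """Fisher enrichment plus a ``p_adj`` BH-corrected column."""
    table = fisher_enrichment(module_genes, go, background, namespace)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy()) if len(table) else []
    return table


def jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def simpson(a: set, b: set) -> float:
    m = min(len(a), len(b))
    return len(a & b) / m if m else 0.0


def enrichment_overlap_network(
    enriched: pd.DataFrame,
    threshold: float = 0.85,
    alpha: float | None = 0.05,
) -> nx.Graph:
    """Network of enriched GO terms linked by hit-gene overlap.

    Nodes are the terms with p_adj < ``alpha`` (or all rows if ``alpha``
    is None), with their adjusted p and hit-gene count as attributes (node
    size in a rendering is proportional to the gene count). An edge joins
    two terms when (JC + SC) / 2 >= ``threshold`` over their hit-gene
    sets.
    """
    rows = enriched
    if alpha is not None and "p_adj" in enriched.columns:
        rows = enriched[enriched["p_adj"] < alpha]
    graph = nx.Graph()
    hit_sets: dict[str, set[str]] = {}
    for _, r in rows.iterrows():
        hits = set(r["hit_genes"].split(",")) if r["hit_genes"] else set()
        hit_sets[r["term"]] = hits
        graph.add_node(
            r["term"],
            name=r.get("name", r["term"]),
            p_adj=float(r["p_adj"]) if "p_adj" in rows.columns else float("nan"),
            n_genes=len(hits),
        )
    terms = sorted(hit_sets)
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            jc = jaccard(hit_sets[a], hit_sets[b])
            sc = simpson(hit_sets[a], hit_sets[b])
            score = (jc + sc) / 2.0
            if score >= threshold:
                graph.add_edge(a, b, jc=jc, sc=sc, score=score)
    return graph


def enrichment_profile_matrix(
    group_enrichments: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    cell_p: str = "raw",
) -> pd.DataFrame:
    """-log10 p matrix (terms x groups) over terms enriched in >= 1 group.

    A term enters as a row if its BH-adjusted p is below ``alpha`` in at
    least one group; each cell holds -log10 of that group's p for the term
    (``cell_p`` = "raw" or "adj"), significant there or not. Groups that
    never tested a term contribute 0.
    """
    if not group_enrichments:
        raise ValueError("need at least one group")
    if cell_p not in {"raw", "adj"}:
        raise ValueError("cell_p must be 'raw' or 'adj'")
    col = "p_raw" if cell_p == "raw" else "p_adj"
    keep: set[str] = set()
    for table in group_enrichments.values():
        if len(table):
            keep |= set(table.loc[table["p_adj"] < alpha, "term"])
    terms = sorted(keep)
    groups = list(group_enrichments)
    mat = np.zeros((len(terms), len(groups)))
    for j, g in enumerate(groups):
        table = group_enrichments[g]
        if not len(table):
            continue
        lookup = dict(zip(table["term"], table[col]))
        for i, t in enumerate(terms):
            p = lookup.get(t)
            if p is not None and p > 0:
                mat[i, j] = -np.log10(p)
            elif p == 0:
                mat[i, j] = np.inf
    return pd.DataFrame(mat, index=terms, columns=groups)
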