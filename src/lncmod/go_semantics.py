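"""Information-content GO semantic similarity (Rel term measure, BMA combining).

Term information content is IC(c) = -ln p(c), where p(c) is the fraction
of annotated genes in the namespace carrying term c after propagation.
The Rel similarity of two terms maximizes, over their common ancestors c
(each term counts as its own ancestor),

    s(t1, t2) = max_c [ 2 IC(c) / (IC(t1) + IC(t2)) ] * (1 - p(c)),

so similarity is discounted for promiscuous ancestors: a shared ancestor
that annotates everything (p -> 1) carries no evidence of relatedness.
Gene-gene similarity combines the term-pair matrix by best-match average
(BMA): the mean of the row maxima and column maxima. The functional
homogeneity fm of a gene set is the mean pairwise gene similarity over
all C(n, 2) pairs, and module-module similarity applies the same BMA
combining one level up, with gene-gene BMA scores as the kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from lncmod.data_io import GoResource

__all__ = [
    "ICTable",
    "information_content",
    "term_similarity_rel",
    "gene_similarity_bma",
    "functional_homogeneity",
    "module_functional_similarity",
    "GeneSetFunctionalScore",
]

DEFAULT_NAMESPACE = "biological_process"


@dataclass
class ICTable:
    """Annotation probabilities and information content per GO term."""

    namespace: str
    term_prob: dict[str, float]
    term_ic: dict[str, float]
    n_annotated_genes: int


@dataclass
class GeneSetFunctionalScore:
    """Functional homogeneity fm of a gene set (mean pairwise similarity)."""

    gene_set: tuple[str, ...]
    fm: float
    pair_scores: dict[tuple[str, str], float]
    excluded_unannotated: tuple[str, ...] = ()


def information_content(go: GoResource, namespace: str = DEFAULT_NAMESPACE) -> ICTable:
    """IC table over the supplied annotation corpus, one namespace at a time.

    Only terms with at least one (propagated) annotated gene get a
    probability; the namespace root has p = 1, IC = 0.
    """
    terms = go.terms_in_namespace(namespace)
    annotated = {
        g for g, ts in go.propagated_annotations.items()
        if any(t in terms for t in ts)
    }
    total = len(annotated)
    if total == 0:
        raise ValueError(f"no annotated genes in namespace {namespace!r}")
    prob: dict[str, float] = {}
    ic: dict[str, float] = {}
    for t in terms:
        k = len(go.term_genes.get(t, ()))
        if k == 0:
            continue
        prob[t] = k / total
        ic[t] = -math.log(prob[t])
    return ICTable(namespace, prob, ic, total)


def term_similarity_rel(t1: str, t2: str, go: GoResource, ic: ICTable) -> float:
    """Rel similarity between two GO terms of one namespace, in [0, 1]."""
    for t in (t1, t2):
        if t not in ic.term_ic:
            raise ValueError(f"term {t!r} has no defined IC in {ic.namespace}")
    denom = ic.term_ic[t1] + ic.term_ic[t2]
    if denom == 0.0:  # both roots
        return 0.0
    common = go.ancestors(t1) & go.ancestors(t2)
    best = 0.0
    for c in common:
        ic_c = ic.term_ic.get(c)
        if ic_c is None:
            continue
        s = (2.0 * ic_c / denom) * (1.0 - ic.term_prob[c])
        if s > best:
            best = s
    return best


def _annotated_terms(gene: str, go: GoResource, ic: ICTable) -> list[str]:
    """A gene's directly annotated terms of the namespace (with defined IC).

    BMA combining works on the terms a gene is annotated to, not on the
    ancestor closure: shared ancestry enters through the Rel term measure,
    and padding the sets with propagated ancestors (ultimately the root,
    whose similarity to everything is 0) would only dilute the average.
    """
    return sorted(
        t for t in go.direct_annotations.get(gene, ())
        if go.namespaces.get(t) == ic.namespace and t in ic.term_ic
    )


def _bma(matrix: np.ndarray) -> float:
    """Best-match average of a similarity matrix: mean of row and column maxima."""
    m, n = matrix.shape
    return float((matrix.max(axis=1).sum() + matrix.max(axis=0).sum()) / (m + n))


def gene_similarity_bma(g1: str, g2: str, go: GoResource, ic: ICTable) -> float:
    """BMA-combined Rel similarity between the GO term sets of two genes."""
    t1 = _annotated_terms(g1, go, ic)
    t2 = _annotated_terms(g2, go, ic)
    if not t1 or not t2:
        missing = g1 if not t1 else g2
        raise ValueError(f"gene {missing!r} has no annotation in {ic.namespace}")
    S = np.empty((len(t1), len(t2)))
    for i, a in enumerate(t1):
        for j, b in enumerate(t2):
            S[i, j] = term_similarity_rel(a, b, go, ic)
    return _bma(S)


def functional_homogeneity(
    gene_set: Iterable[str], go: GoResource, ic: ICTable
) -> GeneSetFunctionalScore:
    """fm: mean gene-gene BMA similarity over all unordered pairs of the set.

    Unannotated genes are excluded (and reported); at least two annotated
    genes are required.
    """
    genes = sorted(set(gene_set))
    annotated = [g for g in genes if _annotated_terms(g, go, ic)]
    excluded = tuple(g for g in genes if g not in set(annotated))
    if len(annotated) < 2:
        raise ValueError("functional homogeneity needs >= 2 annotated genes")
    pair_scores: dict[tuple[str, str], float] = {}
    for i, a in enumerate(annotated):
        for b in annotated[i + 1 :]:
            pair_scores[(a, b)] = gene_similarity_bma(a, b, go, ic)
    fm = sum(pair_scores.values()) / len(pair_scores)
    return GeneSetFunctionalScore(tuple(annotated), fm, pair_scores, excluded)


def module_functional_similarity(
    genes_a: Iterable[str], genes_b: Iterable[str], go: GoResource, ic: ICTable
) -> float:
    """Set-level BMA over gene-level BMA scores between two gene sets.

    Used e.g. to compare the modules a lncRNA is associated with in two
    tumor subtypes.
    """
    a = [g for g in sorted(set(genes_a)) if _annotated_terms(g, go, ic)]
    b = [g for g in sorted(set(genes_b)) if _annotated_terms(g, go, ic)]
    if not a or not b:
        raise ValueError("both gene sets need >= 1 annotated gene")
    S = np.empty((len(a), len(b)))
    for i, ga in enumerate(a):
        for j, gb in enumerate(b):
            S[i, j] = gene_similarity_bma(ga, gb, go, ic)
    return _bma(S)
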