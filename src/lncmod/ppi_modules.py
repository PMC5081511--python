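"""Permutation test for lncRNA-associated PPI modules.

For a lncRNA with n co-expressed mRNAs connected by x PPIs, random n-sets
of mRNAs are drawn from the full mRNA pool; the mean mu and standard
deviation sigma of the internal PPI counts over the draws convert x to a
z-score z = (x - mu) / sigma, whose upper-tail normal probability is the
module p-value. lncRNAs with p < alpha form dense modules, the rest loose
ones; modules with fewer than ``min_size`` co-expressed mRNAs are set
aside as too small for functional analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationTestResult",
    "LncModule",
    "count_internal_ppi",
    "interaction_density",
    "permutation_test",
    "classify_modules",
    "module_table",
]


@dataclass
class PermutationTestResult:
    """Null moments and z/p for one lncRNA's internal PPI count."""

    n: int
    x: int
    mu: float
    sigma: float
    z: float
    p: float
    p_empirical: float
    reps: int
    seed: int | None
    degenerate: bool = False


@dataclass
class LncModule:
    """One lncRNA, its co-expressed mRNAs, and the induced PPI subgraph."""

    lnc_id: str
    coexpressed_mrnas: frozenset[str]
    internal_edges: frozenset[tuple[str, str]]
    stats: PermutationTestResult
    klass: str  # "dense" | "loose"
    density: float

    @property
    def members(self) -> frozenset[str]:
        """mRNAs incident to at least one internal PPI (non-isolated nodes)."""
        return frozenset(g for e in self.internal_edges for g in e)

    @property
    def size(self) -> int:
        return len(self.coexpressed_mrnas)


def count_internal_ppi(gene_set: Iterable[str], ppi: nx.Graph) -> int:
    """Number of PPI edges with both endpoints in ``gene_set``.

    Genes absent from the PPI network simply contribute no edges.
    """
    members = [g for g in set(gene_set) if g in ppi]
    return nx.induced_subgraph(ppi, members).number_of_edges()


def internal_edges(gene_set: Iterable[str], ppi: nx.Graph) -> frozenset[tuple[str, str]]:
    members = [g for g in set(gene_set) if g in ppi]
    sub = nx.induced_subgraph(ppi, members)
    return frozenset(tuple(sorted(e)) for e in sub.edges)


def interaction_density(gene_set: Iterable[str], ppi: nx.Graph) -> float:
    """Internal edge count over the number of possible pairs C(n, 2)."""
    genes = set(gene_set)
    n = len(genes)
    if n < 2:
        raise ValueError("interaction density needs a gene set of size >= 2")
    return count_internal_ppi(genes, ppi) / math.comb(n, 2)


def _edge_index(ppi: nx.Graph, pool: Sequence[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """Index the PPI edges whose both endpoints lie in the pool."""
    pos = {g: i for i, g in enumerate(pool)}
    u, v = [], []
    for a, b in ppi.edges:
        if a in pos and b in pos:
            u.append(pos[a])
            v.append(pos[b])
    return np.asarray(u, dtype=np.intp), np.asarray(v, dtype=np.intp), len(pool)


def _null_counts(
    n: int,
    u: np.ndarray,
    v: np.ndarray,
    pool_size: int,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Internal-edge counts of ``reps`` uniform n-subsets of the pool."""
    counts = np.zeros(reps, dtype=np.int64)
    if len(u) == 0:
        return counts
    batch = max(1, min(reps, int(4e7 // max(pool_size, 1))))
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        keys = rng.random((b, pool_size))
        # the n smallest keys per row form a uniform n-subset
        picks = np.argpartition(keys, n - 1, axis=1)[:, :n]
        member = np.zeros((b, pool_size), dtype=bool)
        np.put_along_axis(member, picks, True, axis=1)
        counts[done : done + b] = (member[:, u] & member[:, v]).sum(axis=1)
        done += b
    return counts


def permutation_test(
    lnc_id: str,
    coexpressed_mrnas: Iterable[str],
    ppi: nx.Graph,
    mrna_pool: Sequence[str],
    reps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationTestResult:
    """Permutation test of the internal PPI count of one lncRNA's mRNA set.

    Each draw takes a uniform n-subset of ``mrna_pool`` without
    replacement. sigma is the population standard deviation over draws.
    Besides the normal upper-tail p of the z-score, the empirical
    p = (#draws >= x + 1) / (reps + 1) is reported. When sigma = 0 the
    result is flagged degenerate with p = 1 if x <= mu else p = 0.
    """
    genes = set(coexpressed_mrnas)
    n = len(genes)
    pool = list(mrna_pool)
    if n < 1:
        raise ValueError("empty co-expressed mRNA set")
    if n > len(pool):
        raise ValueError(f"n = {n} exceeds pool size {len(pool)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    x = count_internal_ppi(genes, ppi)
    u, v, pool_size = _edge_index(ppi, pool)
    counts = _null_counts(n, u, v, pool_size, reps, rng)
    mu = float(counts.mean())
    sigma = float(counts.std())  # population SD
    p_emp = float((np.count_nonzero(counts >= x) + 1) / (reps + 1))
    if sigma == 0.0:
        z = math.inf if x > mu else (0.0 if x == mu else -math.inf)
        p = 0.0 if x > mu else 1.0
        return PermutationTestResult(n, x, mu, sigma, z, p, p_emp, reps, seed, True)
    z = (x - mu) / sigma
    p = float(stats.norm.sf(z))
    return PermutationTestResult(n, x, mu, sigma, z, p, p_emp, reps, seed)


def classify_modules(
    partner_sets: Mapping[str, Iterable[str]],
    ppi: nx.Graph,
    mrna_pool: Sequence[str],
    alpha: float = 0.05,
    min_size: int = 6,
    reps: int = 1000,
    seed: int | None = None,
    size_on: str = "coexpressed",
) -> tuple[list[LncModule], list[LncModule]]:
    """Test every lncRNA with >= 1 internal PPI; split dense/loose by p < alpha.

    Returns ``(modules, discarded)``: modules whose size passes
    ``min_size`` and those set aside by the size filter (still carrying
    their statistics). ``size_on`` counts either the co-expressed mRNAs
    (default) or only the PPI-connected members toward the filter. Each
    lncRNA gets its own child seed derived from ``seed``, so results do
    not depend on which other lncRNAs are tested.
    """
    if size_on not in {"coexpressed", "members"}:
        raise ValueError("size_on must be 'coexpressed' or 'members'")
    kept: list[LncModule] = []
    discarded: list[LncModule] = []
    for lnc in sorted(partner_sets):
        genes = frozenset(partner_sets[lnc])
        edges = internal_edges(genes, ppi)
        if not edges:
            continue  # only lncRNAs with at least one internal PPI are tested
        child_seed = None
        rng = None
        if seed is not None:
            child_seed = int(
                np.random.SeedSequence([seed, _stable_hash(lnc)]).generate_state(1)[0]
                % (2**31)
            )
            rng = np.random.default_rng(child_seed)
        res = permutation_test(lnc, genes, ppi, mrna_pool, reps=reps,
                               seed=child_seed, rng=rng)
        klass = "dense" if res.p < alpha else "loose"
        density = len(edges) / math.comb(len(genes), 2) if len(genes) >= 2 else 0.0
        module = LncModule(lnc, genes, edges, res, klass, density)
        size = len(genes) if size_on == "coexpressed" else len(module.members)
        (kept if size >= min_size else discarded).append(module)
    return kept, discarded


def _stable_hash(text: str) -> int:
    """Deterministic 32-bit hash of a gene id (process-independent)."""
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


def module_table(modules: Sequence[LncModule]) -> pd.DataFrame:
    """Flat summary table: one row per lncRNA module."""
    rows = []
    for m in modules:
        s = m.stats
        rows.append(
            {
                "lnc_id": m.lnc_id,
                "n": s.n,
                "x": s.x,
                "mu": s.mu,
                "sigma": s.sigma,
                "z": s.z,
                "p": s.p,
                "p_empirical": s.p_empirical,
                "klass": m.klass,
                "density": m.density,
                "members": ",".join(sorted(m.members)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lnc_id", "n", "x", "mu", "sigma", "z", "p", "p_empirical",
            "klass", "density", "members",
        ],
    )
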