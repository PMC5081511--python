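"""Null-model and comparison machinery for the pipeline's sanity checks.

Random co-expression networks keep each lncRNA's degree but resample its
mRNA partners uniformly from the pool; comparing the real network's PPI
connectivity, mean internal-PPI count, and interaction density against
these nulls shows whether co-expressed mRNAs are interconnected beyond
chance. A permutation background for functional similarity shuffles
partner assignments among PPI pairs. Distribution comparisons use the
two-sample Kolmogorov-Smirnov test; set comparisons between subtypes use
the left-sided (depletion) Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import networkx as nx
import numpy as np
from scipy import stats

from lncmod.coexpr import CoexpressionNetwork
from lncmod.data_io import GoResource
from lncmod.go_semantics import ICTable, gene_similarity_bma
from lncmod.ppi_modules import count_internal_ppi

__all__ = [
    "NullComparisonReport",
    "randomize_coexpression",
    "null_connectivity_comparison",
    "functional_similarity_background",
    "ks_two_sample",
    "overlap_depletion_test",
]


@dataclass
class NullComparisonReport:
    """Real-vs-random co-expression network comparison."""

    frac_real: float
    frac_null: np.ndarray
    mean_ppi_real: float
    mean_ppi_null: np.ndarray
    density_real: float
    density_null: np.ndarray
    ks_mean_ppi: tuple[float, float] | None
    ks_density: tuple[float, float] | None
    n_random: int


def randomize_coexpression(
    partner_sets: dict[str, set[str]] | CoexpressionNetwork,
    mrna_pool: Sequence[str],
    rng: np.random.Generator | int | None = None,
) -> dict[str, set[str]]:
    """Degree-preserving randomization of a co-expression network.

    Every lncRNA keeps its number of partners; the partners themselves are
    replaced by a uniform draw (without replacement per lncRNA) from
    ``mrna_pool``. Correlation attributes do not survive randomization.
    """
    if isinstance(partner_sets, CoexpressionNetwork):
        partner_sets = partner_sets.partner_sets
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pool = np.asarray(sorted(mrna_pool))
    max_deg = max((len(s) for s in partner_sets.values()), default=0)
    if max_deg > len(pool):
        raise ValueError("pool smaller than the largest lncRNA degree")
    return {
        lnc: set(rng.choice(pool, size=len(partners), replace=False))
        for lnc, partners in sorted(partner_sets.items())
    }


def _connectivity_stats(
    partner_sets: dict[str, set[str]],
    ppi: nx.Graph,
    connected_lncs: Iterable[str] | None = None,
) -> tuple[float, float, float]:
    """(fraction with >=1 internal PPI, mean count, mean density) over lncRNAs.

    Means are taken over ``connected_lncs`` when given (the lncRNAs that
    are PPI-connected in the REAL network), else over the lncRNAs with
    >= 1 internal PPI in this network.
    """
    counts = {lnc: count_internal_ppi(s, ppi) for lnc, s in partner_sets.items()}
    n_lnc = len(partner_sets)
    frac = sum(1 for c in counts.values() if c > 0) / n_lnc if n_lnc else 0.0
    if connected_lncs is None:
        connected_lncs = [lnc for lnc, c in counts.items() if c > 0]
    sel = [lnc for lnc in connected_lncs if lnc in partner_sets]
    if not sel:
        return frac, 0.0, 0.0
    mean_ppi = float(np.mean([counts[lnc] for lnc in sel]))
    densities = [
        counts[lnc] / math.comb(len(partner_sets[lnc]), 2)
        for lnc in sel
        if len(partner_sets[lnc]) >= 2
    ]
    mean_density = float(np.mean(densities)) if densities else 0.0
    return frac, mean_ppi, mean_density


def null_connectivity_comparison(
    real: CoexpressionNetwork | dict[str, set[str]],
    ppi: nx.Graph,
    mrna_pool: Sequence[str],
    n_random: int = 1000,
    seed: int | None = None,
) -> NullComparisonReport:
    """Compare PPI connectivity of the real network against degree-matched nulls.

    For the real network and each of ``n_random`` randomized networks the
    report records the fraction of lncRNAs with >= 1 internal PPI and, over
    the lncRNAs that are PPI-connected in the real network, the mean
    internal-PPI count and mean interaction density. KS tests compare the
    per-lncRNA real values against the pooled null per-network means.
    """
    if isinstance(real, CoexpressionNetwork):
        real = real.partner_sets
    rng = np.random.default_rng(seed)
    counts_real = {lnc: count_internal_ppi(s, ppi) for lnc, s in real.items()}
    connected = sorted(lnc for lnc, c in counts_real.items() if c > 0)
    frac_real, mean_real, dens_real = _connectivity_stats(real, ppi, connected)
    frac_null = np.empty(n_random)
    mean_null = np.empty(n_random)
    dens_null = np.empty(n_random)
    for i in range(n_random):
        random_net = randomize_coexpression(real, mrna_pool, rng)
        frac_null[i], mean_null[i], dens_null[i] = _connectivity_stats(
            random_net, ppi, connected
        )
    ks_mean = ks_two_sample(
        [counts_real[lnc] for lnc in connected], mean_null
    ) if connected and n_random else None
    real_dens = [
        counts_real[lnc] / math.comb(len(real[lnc]), 2)
        for lnc in connected
        if len(real[lnc]) >= 2
    ]
    ks_dens = ks_two_sample(real_dens, dens_null) if real_dens and n_random else None
    return NullComparisonReport(
        frac_real, frac_null, mean_real, mean_null, dens_real, dens_null,
        ks_mean, ks_dens, n_random,
    )


def functional_similarity_background(
    ppi_pairs: Sequence[tuple[str, str]],
    go: GoResource,
    ic: ICTable,
    n_perm: int = 1,
    seed: int | None = None,
    mode: str = "permute_pairs",
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Real vs permuted functional-similarity distributions over PPI pairs.

    The real distribution scores each given pair with gene-level BMA
    similarity. The background permutes the right-hand partner across
    pairs (``permute_pairs``, occurrence-preserving; a derangement is not
    required) or draws uniform random gene pairs from the same gene
    multiset (``uniform``), ``n_perm`` times. Returns (real scores,
    background scores, KS (D, p)).
    """
    if mode not in {"permute_pairs", "uniform"}:
        raise ValueError("mode must be 'permute_pairs' or 'uniform'")
    rng = np.random.default_rng(seed)

    def score(a: str, b: str) -> float | None:
        try:
            return gene_similarity_bma(a, b, go, ic)
        except ValueError:
            return None

    real = np.array(
        [s for a, b in ppi_pairs if (s := score(a, b)) is not None]
    )
    left = [a for a, _ in ppi_pairs]
    right = [b for _, b in ppi_pairs]
    bg: list[float] = []
    for _ in range(n_perm):
        if mode == "permute_pairs":
            shuffled = list(rng.permutation(right))
        else:
            genes = left + right
            shuffled = list(rng.choice(genes, size=len(left), replace=True))
        for a, b in zip(left, shuffled):
            s = score(a, b)
            if s is not None:
                bg.append(s)
    background = np.asarray(bg)
    ks = ks_two_sample(real, background)
    return real, background, ks


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov statistic D and p-value.

    Uses the exact small-sample p when both samples have n <= 25, else the
    asymptotic formula.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs two non-empty samples")
    method = "exact" if max(a.size, b.size) <= 25 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def overlap_depletion_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Left-sided Fisher exact p for depleted overlap of two sets.

    Small p means the sets share fewer elements than expected for their
    sizes within the universe (hypergeometric lower tail
    P(X <= |A ∩ B|)).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must lie within the universe")
    overlap = len(a & b)
    return float(stats.hypergeom.cdf(overlap, len(u), len(a), len(b)))
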