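"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (explicit loops, integer
combinatorics, exhaustive enumeration) and deliberately shares no code
path with the package.
"""

from __future__ import annotations

import itertools
import math


# --- rank / correlation chain -------------------------------------------


def average_ranks_desc(values):
    """Rank 1 = largest value; ties get the average of their positions."""
    n = len(values)
    ranks = [0.0] * n
    for i, v in enumerate(values):
        greater = sum(1 for w in values if w > v)
        ties = sum(1 for w in values if w == v)
        ranks[i] = greater + (ties + 1) / 2.0
    return ranks


def average_ranks_asc(values):
    return average_ranks_desc([-v for v in values])


def spearman(x, y):
    """Pearson correlation of average ranks (general tie-safe form)."""
    rx = average_ranks_asc(list(x))
    ry = average_ranks_asc(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    if dx == 0 or dy == 0:
        return 0.0
    return num / (dx * dy)


def mutual_rank_matrix(corr_rows):
    """MR of each cell from |corr| ranks within its row and column."""
    n_rows = len(corr_rows)
    n_cols = len(corr_rows[0])
    a = [[abs(v) for v in row] for row in corr_rows]
    mr = [[0.0] * n_cols for _ in range(n_rows)]
    for i in range(n_rows):
        row_ranks = average_ranks_desc(a[i])
        for j in range(n_cols):
            col = [a[k][j] for k in range(n_rows)]
            col_rank = average_ranks_desc(col)[i]
            mr[i][j] = math.sqrt(row_ranks[j] * col_rank)
    return mr


def select_top_pairs(mr, fraction):
    """(row, col) pairs with the smallest MR: floor(fraction*N) plus boundary ties."""
    flat = [(mr[i][j], i, j) for i in range(len(mr)) for j in range(len(mr[0]))]
    flat.sort()
    n_keep = math.floor(fraction * len(flat))
    if n_keep == 0:
        return set()
    cutoff = flat[n_keep - 1][0]
    return {(i, j) for v, i, j in flat if v <= cutoff}


# --- permutation-test null moments --------------------------------------


def internal_edge_count(gene_set, edges):
    s = set(gene_set)
    return sum(1 for a, b in edges if a in s and b in s)


def exact_subset_moments(pool, edges, n):
    """Mean and population SD of the internal edge count over all n-subsets."""
    counts = [
        internal_edge_count(subset, edges)
        for subset in itertools.combinations(sorted(pool), n)
    ]
    mu = sum(counts) / len(counts)
    var = sum((c - mu) ** 2 for c in counts) / len(counts)
    return mu, math.sqrt(var)


# --- hypergeometric tails -----------------------------------------------


def hypergeom_pmf(k, N, K, n):
    if k < max(0, K + n - N) or k > min(K, n):
        return 0.0
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def hypergeom_upper(k, N, K, n):
    return sum(hypergeom_pmf(i, N, K, n) for i in range(k, min(K, n) + 1))


def hypergeom_lower(k, N, K, n):
    return sum(hypergeom_pmf(i, N, K, n) for i in range(0, k + 1))


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, pvalues[i] * m / rank_from_end)
        adjusted[i] = running_min
    return adjusted


# --- set overlap ---------------------------------------------------------


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 0.0


def simpson(a, b):
    a, b = set(a), set(b)
    return len(a & b) / min(len(a), len(b)) if a and b else 0.0


# --- BMA combining -------------------------------------------------------


def bma(matrix):
    row_max = [max(row) for row in matrix]
    col_max = [max(matrix[i][j] for i in range(len(matrix)))
               for j in range(len(matrix[0]))]
    return (sum(row_max) + sum(col_max)) / (len(row_max) + len(col_max))


# --- KS statistic --------------------------------------------------------


def ks_statistic(a, b):
    """Max gap between empirical CDFs, evaluated at every data point."""
    a, b = sorted(a), sorted(b)
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d
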