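# Methods

`lncmod` predicts long non-coding RNA (lncRNA) function by
guilt-by-association: a lncRNA whose strongly co-expressed mRNAs form a
tight cluster in the protein–protein interaction (PPI) network is assumed
to participate in the processes those proteins carry out. This note
records the model, the parameters that matter, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## Co-expression by mutual rank

For every lncRNA–mRNA pair the Spearman correlation coefficient (SCC) is
computed across samples; SCC is rank-based, so the expression units and
any monotone transform of them are irrelevant, and it is robust to
outliers. |SCC| is then ranked in both directions — the mRNA's position
among all mRNAs from the lncRNA's view and vice versa, rank 1 = largest,
ties receiving average (fractional) ranks — and the mutual rank

    MR = sqrt(rank_{lnc->mRNA} * rank_{mRNA->lnc})

is the geometric mean of the two. Small MR means the two genes are each
other's top partners even when the absolute correlation is modest, which
is the point of ranking over thresholding the correlation itself.

Selection supports two modes: keep the globally smallest-MR fraction of
all lncRNA × mRNA pairs (default 0.1%), or keep pairs with MR below an
explicit cutoff. Boundary ties at the fraction quantile are all included,
so selection is deterministic and independent of sort order. Increasing
the fraction never removes a selected pair. Genes with constant
expression have undefined SCC; it is recorded as 0 with a warning, which
keeps them out of any plausible selection.

A practical note on the two modes: under the fraction mode, reciprocal
best-hit pairs that arise by chance in the background compete with true
partners for the global quota, because a noise pair can reach MR = 1.
When partner sets of a known size k are expected (as in the synthetic
benchmark), the natural cutoff is MR <= sqrt(k): a true partner ranked
j <= k on one side and 1 on the other has MR <= sqrt(k), while any pair
ranked worse than k on either side cannot pass.

## PPI modules by permutation z-score

For a lncRNA with n co-expressed mRNAs joined by x PPI edges (only
lncRNAs with x >= 1 are tested), the null distribution of the internal
edge count is estimated by drawing `reps` (default 1000) uniform
n-subsets, without replacement within a draw, from the pool of all mRNAs
in the expression matrix — not just PPI-covered ones, which makes the
null conservative. With the null mean mu and population standard
deviation sigma (dividing by `reps`; at 1000 draws the distinction from
the sample SD is negligible, but it is fixed for reproducibility),

    z = (x - mu) / sigma,   p = P(Z >= z)  (standard normal upper tail).

p < alpha (default 0.05) classifies the module as dense, otherwise loose.
The empirical tail probability (#draws >= x + 1)/(reps + 1) is reported
alongside for robustness but the classification uses the normal p. When
sigma = 0 the result is flagged degenerate with p = 1 if x <= mu and 0
otherwise. Modules with fewer than `min_size` (default 6) co-expressed
mRNAs are classified but set aside, since sets that small rarely support
enrichment analysis; the filter can alternatively count only the
PPI-connected members. The interaction density of a gene set is
d = k / C(n, 2), the internal edge count over the possible pairs.

Each lncRNA's test draws from its own child random stream (seeded from
the run seed and a stable string hash of the lncRNA id), so results do
not depend on which other lncRNAs are in the run.

**Known limitation.** The internal edge count is a discrete statistic;
thresholding its normal-approximation upper tail at alpha is
anti-conservative when the null mean is small (roughly, below ~5 edges),
where the realized type-I error can exceed alpha by a few points. The
type-I benchmark therefore runs in a regime with a null mean of ~6–7
internal edges, where direct measurement puts the dense-call rate at
0.045–0.06. On data where modules ride on a very sparse interactome, the
empirical p is the safer of the two reported values.

## GO semantics

Annotations are propagated along is_a and part_of edges (configurable) to
all ancestors. Term information content is computed from the supplied
annotation corpus itself, per namespace (biological_process by default):
p(c) is the fraction of annotated genes carrying c after propagation and
IC(c) = -ln p(c), so the namespace root has IC 0. Term similarity uses
the Rel measure: over common ancestors c of the two terms (each term its
own ancestor),

    s(t1, t2) = max_c [2 IC(c) / (IC(t1) + IC(t2))] * (1 - p(c)),

which weighs the most informative common ancestor and discounts it by its
own annotation probability; self-similarity is exactly 1 - p(t), so rarer
terms are allowed to testify more strongly. Gene–gene similarity combines
the term-pair matrix over the genes' *directly* annotated term sets by
best-match average (BMA = mean of row maxima and column maxima);
propagated ancestors enter through the Rel measure, and padding the term
sets with them (ultimately the root, similar to nothing) would only
dilute the average. Functional homogeneity fm of a gene set is the mean
gene–gene BMA over all C(n, 2) pairs. Module-versus-module similarity
applies BMA one level up with gene-level BMA as the kernel — the same
construction GoSemSim uses for gene clusters; whether such comparisons
should instead use enriched-term sets is an open choice, and the gene-set
reading is adopted here.

## Enrichment and overlap networks

Each GO term annotating at least one background gene is tested by the
one-sided Fisher exact test, computed as the hypergeometric upper tail
P(X >= k_hit) of the 2×2 table, with Benjamini–Hochberg correction across
terms. The background defaults to all annotated mRNAs of the expression
matrix; enrichment runs on module member genes (the PPI-connected
subset), switchable to the full co-expressed set. Significant terms
(corrected p < 0.05) form a network with edges where the mean of the
Jaccard and Simpson coefficients of their hit-gene sets reaches a
threshold (default 0.85). Enrichment-profile matrices hold -log10 p per
term and group for terms significant in at least one group; the corrected
p gates row inclusion and the raw p fills cells by default (both
switchable), since a cell's job is to show the strength of evidence in
that group rather than repeat the gate.

## Module clustering

The association index between two lncRNAs is (JC + OC)/2 over their
co-expressed mRNA sets (full sets, not just PPI members; switchable),
where JC is the Jaccard and OC the Simpson (overlap) coefficient; OC = 1
whenever one set contains the other, which deliberately tolerates nested
modules. 1 - association feeds average-linkage agglomerative clustering
(scipy); items are ordered lexicographically before the distance matrix
is built, which fixes the merge order under ties, and both cut-by-count
and cut-by-height are supported — the caller chooses, since no principled
default exists. Clusters below `min_cluster_size` (default 5) lncRNAs are
reported as unassigned. Heatmap ordering of enrichment profiles uses
1 - Pearson distance (range [0, 2]) with complete linkage on rows and
columns; zero-variance profiles get correlation 0 by convention, with a
warning.

## Validation machinery

Degree-preserving randomization keeps each lncRNA's partner count and
redraws the partners uniformly from the mRNA pool. The connectivity
comparison computes, for the real network and each of `n_random` nulls,
the fraction of lncRNAs with at least one internal PPI and — over the
lncRNAs connected in the *real* network — the mean internal edge count
and mean density; per-network means are the default summary (pooling all
per-lncRNA null values is exposed as a variant). Distribution contrasts
use the two-sample Kolmogorov–Smirnov test, exact for samples up to 25
and asymptotic beyond. The functional-similarity background permutes the
right-hand partner across the given PPI pairs (gene-occurrence
preserving; a uniform-pair variant is available). Between-subtype set
comparisons use the left-sided (depletion) Fisher exact test, the
hypergeometric lower tail.

## Synthetic data

Each planted lncRNA is a latent Gaussian driver; its k partner mRNAs are
rho·driver + sqrt(1 - rho²)·noise, so partner–driver SCC concentrates
near rho (default 0.95) and partner–partner SCC near rho². Background
genes are independent noise. The PPI layer is Erdős–Rényi at
`ppi_background_p` over all mRNAs plus within-module edges at
`ppi_module_p`; the GO layer is a generated DAG in which each planted set
has a private leaf term under a private branch, and background genes draw
1–3 background leaves uniformly. Defaults for the planted benchmark —
10 modules of 8 partners, rho 0.95, module PPI probability 0.8 over
background 0.02, 60 lncRNAs × 200 mRNAs × 50 samples, 1000 permutation
draws — are the package's standard study conditions; the null benchmark
uses 250 lncRNAs × 300 mRNAs, background PPI probability 0.10 and a
selection fraction giving ~12 partners per lncRNA (see the limitation
above for why the null edge mean matters). Identical parameters and seed
produce byte-identical files.

What the generator does not emulate: real marginal expression
distributions, tumor subtype structure, correlated measurement noise,
scale-free PPI topology, or the shallow/biased annotation of real GO.
Passing benchmarks therefore demonstrate correctness of the machinery
and sane operating characteristics under clean Gaussian co-expression,
not recovery rates to be expected on cohort data.

## Reproducibility

One master seed in the pipeline config; per-stage seeds derive from it by
SeedSequence over (master, stable string hash of the stage name), reduced
mod 2³¹, so a stage re-run in isolation with its derived seed reproduces
the monolithic run's bytes. The run manifest records the config, derived
seeds, package version and SHA-256 of every input.

## Problem sizes in the shipped benchmarks

The test-suite and acceptance-script benchmarks run the planted fixture
at 60 × 200 × 50 with 1000 permutation draws, the null fixture at
250 × 300 × 50, brute-force co-expression oracles at 20 × 20 × 10,
exhaustive permutation enumeration at pools of 6–8, and hypergeometric
closed forms exhaustively to N = 20 (spot-swept to 60). These sizes give
each check comfortable statistical power while keeping a full run on one
CPU in well under a minute for the unit suite.
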