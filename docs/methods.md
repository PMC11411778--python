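# Methods

## The statistical problem

Raw single-cell RNA-seq UMI counts are discrete, sparse and acquired at
sequencing depths that vary by orders of magnitude across cells.  Both
properties break the classical theory connecting a Pearson correlation
coefficient to a p-value (the Fisher z-transform tail,
`p = erfc(sqrt((n-3)/2) * arctanh|r|)`): for genes with mean expression
below ~1 UMI/cell the formula is anti-conservative by orders of magnitude,
and depth variation corrupts it even after normalization-by-scaling.  This
package assigns statistical significance to per-gene variability and to
every pairwise gene-gene correlation by building the null distribution of
the statistics analytically, from moments, instead of assuming normality.

## Model

A count `x_ij` (cell `i`, gene `j`) is modeled under the null as Poisson
around a latent rate that fluctuates lognormally:

* technical sampling: `x | rate ~ Poisson(rate)`;
* expression noise: `rate ~ Lognormal` with mean `mu_ij` and coefficient of
  variation `c` (one global `c`; typical biological values 0.2-0.6);
* depth correction: `mu_ij = (gene j total) * (cell i total) / grand total`
  — the expectation, not the data, is scaled, so the counts stay raw.

The modified corrected Pearson residual

    P'_ij = (x_ij - mu_ij) / sqrt(mu_ij (1 + c^2 mu_ij))

has mean 0 and variance exactly 1 under this null (the denominator is the
Poisson-lognormal variance).  Derived statistics:

* `phi'_j = sum_i P'_ij^2 / (n-1)` — the modified corrected Fano factor,
  ~1 for null genes at every expression level;
* `PCC'_ab = sum_i P'_ia P'_ib / ((n-1) sqrt(phi'_a phi'_b))` — the
  modified corrected correlation, expectation 0 under independence.

## Null moments

The Poisson-lognormal pmf has no closed form, but its moments do: the r-th
factorial moment of a mixed Poisson equals the r-th raw moment of the
mixing distribution, `E[(X)_r] = mu^r (1+c^2)^(r(r-1)/2)`, and
Stirling-number conversion yields raw moments to any order.  Central
moments are evaluated from polynomial coefficient tables in `(mu, c^2)`
that were expanded symbolically once and frozen in `_pln_tables.py`
(orders up to 10): the naive alternating raw-moment sum loses roughly
`m*log10(mu)` decimal digits to cancellation at high expression, while the
frozen polynomials perform the cancellation exactly.  Tests cross-check the
tables against a Gauss-Hermite quadrature oracle and Monte Carlo.

Cumulants of `phi'` follow because cumulants of independent per-cell
summands add; five moments of `phi'` need residual moments to order 10.
For `PCC'` the numerator's per-cell product moments factorize under
independence (`E[(P'_a P'_b)^k] = E[P'_a^k] E[P'_b^k]`), and the
`phi'` denominator is treated as a constant at its observed value — an
approximation that is accurate because `phi'` aggregates information over
all cells.  In the implementation the per-pair cumulant sums for all pairs
reduce to three matrix products of per-gene moment matrices, so a scan is
BLAS-bound and chunked; results are independent of the chunking.

## Tail probabilities (Cornish-Fisher)

Given null cumulants `k1..k5`, the observation is standardized and matched
to a normal deviate `z` by solving the degree-4 Cornish-Fisher quantile
polynomial built from standardized cumulants `g1, g2, g3`; the real root
nearest the standardized observation is used (the expansion perturbs the
identity map, so the contiguous root is the meaningful one), subject to the
expansion being locally increasing there.  One-sided tails come from the
normal tail at `z`; two-sided p-values are `min(1, 2p)` with the direction
reported separately.  Three escape hatches, each flagged in the output:

* `normal_fallback` — no usable real root, or a locally decreasing
  expansion: the unadjusted normal tail is reported and flagged;
* `fast_path` — when a quartic-free first-order inversion of the expansion
  (one Newton step, which already carries the skew correction) puts the
  tail below `fast_path_floor` (default 1e-20), the exact solve is skipped.
  Gating on the raw normal deviate instead is unsafe: for ultra-sparse gene
  pairs it can understate the p-value by more than 15 orders of magnitude
  and manufacture false discoveries under the null;
* observations exactly at the null mean report p = 1.

Validity: the expansion is an asymptotic series in the standardized
cumulants, which shrink as `1/sqrt(n)`.  Monte-Carlo calibration holds the
99th-percentile tail within 3 binomial SE across the operating regime
(means 0.3-100, c up to 0.5, n >= 100 cells); with few cells and strongly
overdispersed high-expression genes (null skewness approaching 1, e.g.
mu=10, c=0.5, n=100) the mid-distribution quantiles degrade first.  The
method is intended for hundreds of cells or more.

## Multiple testing and reporting

Benjamini-Hochberg step-up is applied jointly to the two-sided p-values of
all retained pairs (default FDR 0.02, both signs together).  Each
significant pair is additionally reported as a signed *equivalent PCC*:
the inverse Fisher transform of its p-value at the same `n`, signed by
`PCC'`.  This expresses strength on a scale comparable across datasets
with different cell counts; the inverse uses an asymptotic branch of
`erfcinv` so p-values down to ~1e-300 invert stably.

## Choosing c

Under-correcting (`c` too small) leaves `phi'` rising with mean expression;
over-correcting pushes it down.  `estimate_c` scans a grid (default 0.05 to
0.80, step 0.05) and picks the value minimizing the absolute OLS slope of
`log10 phi'` against `log10 mean` over genes with mean >= 1 UMI/cell (at
least 20 such genes required), ties toward smaller `c`.  On simulated data
the estimator recovers the generating `c` to within one grid step.  A
single global `c` is used; per-gene noise levels would be better but are
rarely known, and `c` mostly matters for highly expressed genes.

## Synthetic data

The null generator emulates a droplet experiment with no gene-gene
structure: per-gene target means on a deterministic log-uniform grid
(defaults 0.0351-3467 transcripts/cell, 1000 genes x 999 cells; the large
benchmark variant is 15,369 x 3,570), per-cell depth factors
`~ Lognormal(mean 1, CV 0.75)`, per-gene-per-cell lognormal noise of CV
`c = 0.5`, Poisson sampling.  Lognormals are parameterized by (mean m, CV
c): log-variance `ln(1+c^2)`, log-mean `ln m - ln(1+c^2)/2`.  Each gene
draws from its own RNG stream derived from `(seed, gene index)`, so planted
modifications leave other genes' counts bit-identical.  Planted
correlations use a Gaussian copula on the log-noise of a disjoint gene
pair, giving latent correlation ~rho.

What the generator does not emulate: ambient RNA, doublets, batch effects,
gene-length or capture-efficiency bias, per-gene noise heterogeneity, and
any real co-regulation structure.  Passing null tests therefore shows
correct calibration under the stated model, not robustness to every
artifact of real data.

Note an internal tension in the stated defaults: target means up to 3467
with depth factors of mean 1 imply several hundred thousand UMI per cell,
an order of magnitude deeper than the "typical 10x" depths the same
defaults are said to mimic (which would correspond to realized means
topping out around 231, i.e. an effective depth scale near 1/15).  The
generator follows the stated recipe; `depth_mean` is exposed for users who
want the shallower regime, and the null-calibration results are
insensitive to this choice.

## Metacell benchmark

`run_benchmark` counts significant pairs on one null simulation under six
pipelines (raw PCC, depth-normalized PCC, log-normalized PCC, metacell-
averaged PCC at the grouped sample size, PCC' + Fisher threshold, PCC' +
analytic p-values with BH FDR), using the Fisher formula at p < 0.02 by
default (`use_bh` switches the PCC pipelines to BH at the same level).
Metacell grouping embeds cells with PCA (<= 20 components), clusters with
k-means, and balances groups by greedy capacity-limited assignment to the
nearest centroid — the inflation it demonstrates is generic to aggregating
cells by similarity, not to a particular grouping algorithm.  On null data
the observed ordering is stable: raw >> metacell > log-normalized >
PCC'+Fisher > PCC'+BH = 0.

Two caveats documented from our own measurements: (i) for any calibrated
statistic a literal per-pair threshold of p < 0.02 must flag ~2% of pairs,
so the log-normalized and PCC' pipelines sit near that floor (the depth
effect pushes the log pipeline somewhat above it); counts far below the 2%
floor are only reachable under a stricter effective threshold.  (ii) the
plug-in `mu_ij` estimate biases mean `phi'` by `O(1/n_genes + 1/n_cells)`
and mean `PCC'` positively by `O(1/n)`; both are negligible at the default
sizes but visible to tests that assume exact centering.

## Gene communities

Significant pairs (optionally floored on |equivalent PCC|) define a signed
graph, canonicalized by gene id so the pipeline is deterministic.  Stages:
walktrap (4 steps) on the unweighted adjacency per connected component;
within each community, negative edges are dropped and walktrap reruns,
separating anti-correlated blocks; community pairs whose positive
inter-community density exceeds `merge_density` (default 0.25) times the
smaller intra-community density are merged greedily, with a guard that the
positive-subgraph modularity never drops more than 0.05 below its
pre-merge value; communities above `max_size` (default 1000) get one more
walktrap pass.  The merge rule automates a step that is otherwise manual
curation; its threshold is a declared package choice.  Genes attached only
by negative edges are reassigned to the community they touch most, which
affects reporting only.

Fold enrichment against reference pair lists (paralogs, protein-protein
interactions) is the observed frequency of reference pairs among
significant positive pairs divided by their frequency among all possible
pairs of detected genes, with reference pairs restricted to detected genes
first.

## Numerical and engineering choices

* Quartic roots via batched companion-matrix eigenvalues, with per-
  observation degree reduction when leading coefficients vanish.
* p-values are clamped into `(0, 1]` (smallest positive double) so
  downstream logs and BH never see 0.
* The pair scan stores one p-value, one PCC' and two int32 indices per
  pair; at 10^8 pairs this is a few GB, so genome-scale runs should use
  `significant_only` output.  Results are exactly independent of
  `block_size`.
* Gene filters: genes expressed in fewer than `min_cells_expressed` cells
  (default 8) are dropped, or alternatively a minimum-total-UMI filter;
  zero-total cells and zero-variance genes are dropped with a log message.
  Statistical power fades below roughly several hundred nonzero entries
  per gene, so the filter mostly saves compute.

## Problem sizes used by the test suite

Unit and property tests run at 200-1000 genes x 500-1000 cells; the
benchmark ordering property runs 10 seeds at 2000 x 1000; the two
full-size benchmark checks run once at 15,369 x 3,570.  These sizes keep
the whole suite under a few minutes while leaving every statistical
property at the scale where its expected behavior is unambiguous.
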