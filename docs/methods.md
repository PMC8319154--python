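# Methods

`coexpand` implements an integration of GWAS-derived gene lists with
case/control expression data: it asks whether the listed genes are
co-expressed beyond chance, extracts and expands the co-expressed core into
a list large enough for gene-set enrichment, checks whether
differential-expression signal is concordant across datasets, and tests
whether a pathway shifts coherently between cases and controls even when no
single gene does. This note records the models, the defaults and why they
are what they are, the numerical choices, and what the synthetic data do
and do not establish.

## Correlation-pattern significance

For a gene list within one diagnosis group (and region), all pairwise
Pearson coefficients are computed over the group's samples. A pair is
"significant" either when its two-sided correlation p-value is below a
level `alpha` (default 0.05; the p comes from the exact t transform
`t = r sqrt((n-2)/(1-r^2))` with `n-2` degrees of freedom) or, in the
alternative mode, when `|r|` exceeds a fixed cutoff. The test statistic is
the count `b0` of significant pairs. The null is empirical: `B` (default
1000) gene groups of the same size are drawn uniformly without replacement
from all genes of the matrix, the same count is computed for each, and the
p-value is the fraction of null counts at or above `b0`. The more
conservative `(b+1)/(B+1)` estimate is reported alongside; the plain `b/B`
is the primary value because its granularity (e.g. 0.006 at B = 1000)
matches how such empirical p-values are conventionally quoted.

The analytic t transform stands in for per-pair sample-order permutation
tests: at these group sizes the two agree in distribution, and the analytic
form is deterministic. In the null loop the per-pair threshold is applied
as the equivalent critical `|r|` (e.g. 0.497 at n = 16, alpha = 0.05), so
both modes share one vectorised path. A gene with zero variance in the
group yields r = 0 with a warning rather than an exception — a random null
group must not crash the test when it hits a degenerate gene.

## Cluster detection and expansion

The correlation matrix is seriated by average-linkage hierarchical
clustering on distance `1 - r`, taking the dendrogram leaf order; genes are
fed to the linkage lexicographically so the result does not depend on input
order. Published analyses of this kind typically select the visually
apparent block from such a sorted matrix; an algorithmic substitute has to
make that judgement explicit, and two design points deserve a record:

* **Window objective.** Among contiguous windows with size >= `min_size`
  (3) and mean pairwise r >= `min_mean_r` (0.5), the selected window
  maximises the summed excess correlation `sum_pairs (r - min_mean_r)`,
  not the mean pairwise r. A bare mean-r objective is dominated by small
  sub-windows whose mean is inflated by noise (with a 7-gene block at
  true pair r = 0.81 and n = 16, some 3-gene sub-window almost always
  beats the full block's mean); the summed-excess objective grows with
  block size and recovers the full block.
* **Boundary refinement.** The winning window is then refined: a boundary
  gene whose mean correlation to the rest of the window is below 0.8 times
  the window's own mean pairwise r is trimmed, and an adjacent gene
  reaching that bar is absorbed, iterated to stability. The absolute
  threshold alone cannot reject a background gene that reaches mean
  r ~ 0.55 to a real block by sampling luck (at n = 16 this happens for
  roughly one gene per 23-gene list in a tenth of datasets) — what
  identifies it is falling well short of the block's internal coherence.
  The ratio 0.8 sits on a plateau (0.80–0.825) found by simulating the
  generative model below; exact-recovery rates there are ~0.92, and no
  one-parameter rule did materially better, because at n = 16 the weakest
  true member and the luckiest outsider genuinely overlap.

A caller may also pass an explicit cluster (`override`) to reproduce a
block chosen by eye from a published figure.

The cluster's **average profile** is the per-sample mean of the
z-scored (per gene, across the group's samples, ddof = 1) cluster rows;
z-scoring keeps high-variance genes from dominating. Expansion ranks every
gene in the matrix by Pearson correlation to this profile (ties broken by
gene name) and keeps the top `M` (default 800, counting the seed genes,
which are always retained); the correlation of the M-th gene is reported as
`min_r_attained`. Nesting holds by construction: the M = 600 list is a
subset of the M = 800 list, and `min_r_attained` is non-increasing in M.

## Enrichment

Over-representation uses the hypergeometric upper tail `P(X >= k)` for an
overlap of `k` between the query (size `K`) and a set (size `n`) in a
universe of `N` genes, Benjamini–Hochberg corrected across sets. Scores are
`-log2(p_adj)` with the usual tiers (high: p_adj <= 1e-4; medium: <= 0.05;
low: otherwise). The universe is explicit everywhere: overlap p-values are
meaningless without one, and published overlap figures frequently cannot be
reproduced because the universe is unstated. Replication of enrichment
between two analyses is itself a hypergeometric test on the enriched set
names given a stated universe of testable sets.

## Comparability

Per-gene two-sample t statistics (case minus control; pooled-variance
Student t by default, Welch optional) are computed per region; two regions
are comparable when the Pearson correlation of their t-vectors over shared
genes exceeds 0.1 with p < 0.001 (two-sided, t transform at
`n_shared - 2` df). Pooled t was chosen because the classic concordance
measure this follows predates Welch-by-default practice; the flag exists
because the choice is not substantive at these group sizes.

## Pathway-level differential expression

Per gene: `d = (Mp - Mc) / Sc`, with `Mc`, `Sc` (ddof = 1) from control
samples only and `Mp` the case mean — the case shift in control-SD units.
Genes with `Sc = 0` are excluded with a warning. The pathway's genes are
joined by co-expression edges with score strictly above 0.1 (a literal
reading of "above"; configurable), isolated genes are dropped, and the
graph is exported as GraphML with `deviation` on nodes and `score` on
edges — the graph file, not any drawing, is the deliverable. The tendency
test counts signs of `d` (zeros excluded, minimum five non-zero), and
reports the exact binomial tail `P(X >= max(n_pos, n_neg))` at p = 1/2 in
the majority direction (ties break to "up"), with the exact two-sided value
logged alongside since published directional p-values often leave sidedness
unstated.

## Synthetic data

One latent factor `f_s ~ N(0,1)` per sample drives the planted structure:
cluster and pool genes follow
`x = mu_g + lambda_g f_s + sqrt(1 - lambda_g^2) sigma eps`, so with
`sigma = 1` (default) the expected pair correlation is the product of the
loadings — `lambda^2` for the equal-loading cluster. Pathway genes carry
`delta sigma` added to case samples (`delta = 0.5` by default); background
genes are independent noise; baselines `mu_g ~ N(8,1)` mimic log2
microarray intensities. Defaults mirror a typical post-mortem brain
microarray cohort: 16 cases vs 18 controls, a 7-gene cluster at loading
0.8, a 100-gene pool with loadings uniform on [0.6, 0.9], a 20-gene
pathway, 10,000 genes. A rank-1 factor is the generative assumption matching an
expansion built on a single average profile.

The generator omits batch effects, covariates (age, sex, PMI), multiple
latent factors, count noise, and probe-level structure. Passing tests
therefore show that the statistics behave as designed when their model
holds — calibration of the permutation and sign tests, power against
planted structure, parameter recovery — not that real post-mortem data
satisfy that model.

Companion generators emit a GMT collection (the planted pathway plus
background-drawn decoys) and an edge table (dense, high-score edges within
the pathway; sparse, low-score edges over a sampled background subset —
sampling rather than all ~n^2/2 pairs, which nothing downstream needs).

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at sizes where each check's
Monte-Carlo error is small relative to its margin: 200 null datasets
(10,000 genes, B = 1000) for permutation calibration; 50 planted datasets
for power; 100 runs at loading 0.9 for cluster recovery (a 1,000-gene
universe — recovery depends only on the 23 listed genes); 50 runs at
10,000 genes for expansion recall, with the profile computed over all 34
samples since the latent factor is diagnosis-independent in the generator;
200 delta = 0 pathways for sign-test calibration; a 32 + 36 cohort with
500 of 5,000 genes at delta = 0.5, split into 16/18 halves, for
comparability. Exactness checks (hypergeometric, binomial) enumerate all
configurations up to N = 12 and n = 20 respectively.

## Known limitations

* Exact cluster recovery is capped near 92% under the default conditions;
  see the boundary-refinement note above.
* The QC rule (iterated removal of samples whose mean inter-sample
  correlation falls 3 SD below the group mean) is a reasonable stand-in
  for undocumented per-study curation, not a reconstruction of it.
* Enrichment is generic ORA over user-supplied GMT files; no pathway
  database ships with the package, and scores are only as meaningful as
  the chosen universe.
* Expression input is assumed log2-scale (with a `log2(x+1)` fallback when
  values look linear); no quantile/RMA-style normalisation is performed.
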