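# Methods

`psychnet` implements a network-based structural validation workflow for
multidimensional ordinal questionnaires. Instead of fitting a latent factor
model, the questionnaire is represented as a Gaussian graphical model over its
items; the dimensions of the scale are the topological communities of that
network, and validity evidence is the agreement between those communities and
the theoretical subscale/composite structure, together with their stability
under resampling. This note records the models, the defaults and why they were
chosen, and the known limits of what the synthetic benchmark demonstrates.

## Correlation input

Likert items (categories `0..likert_max`, default 0–4) are ordinal, so the
default association measure is the **polychoric correlation**: each pair of
items is modeled as a discretized bivariate normal. Estimation is the standard
two-step procedure — thresholds are fixed at `Phi^{-1}` of the cumulative
marginal proportions, then the latent correlation maximizes the bivariate
normal likelihood of the observed contingency table (bounded scalar search on
(−0.9999, 0.9999); rectangle probabilities evaluated through an Owen's-T
formulation of the bivariate normal CDF, unit-tested against
`scipy.stats.multivariate_normal`). The pairwise matrix is smoothed to the
nearest positive-semidefinite correlation matrix by eigenvalue clipping at
1e−8 and rescaling to unit diagonal.

Pearson correlations are a configuration option throughout. Composite
variables produced by redundancy merging are continuous factor scores, so any
pair involving one of them automatically uses Pearson (polyserial estimation is
deliberately out of scope). Every downstream artifact records which method fed
it.

## Network estimation

The precision matrix maximizes
`log det(Theta) − tr(S·Theta) − lambda·sum_{i≠j}|theta_ij|`. The solver is the
classic block coordinate descent on the covariance side (each column solved as
a lasso regression, working-covariance diagonal fixed at `S`'s — the exact
stationarity condition when the diagonal is unpenalized), with warm starts
along the penalty path. Convergence is declared when the largest elementwise
change of the working covariance in a sweep falls below 1e−6 (at most 10 000
sweeps; non-convergence is an error that reports the residual). The solver is
verified in the test suite against two independent optimizers — an L-BFGS-B
run on a positive/negative split parameterization of the penalized objective
and (during development) an ADMM solver — agreeing to ~1e−8, with KKT
residuals ~1e−12.

Model selection: 100 log-spaced penalties from `lambda_max` (the smallest
penalty that empties the graph, i.e. `max|S_offdiag|`) down to
`lambda_max/100`, scored by the extended BIC
`−n[log det Theta − tr(S·Theta)] + E log n + 4 E gamma log p` with `gamma=0.5`
and `E` the number of nonzero upper-triangle entries (entries below 1e−10 are
structural zeros). These are the conventional defaults of psychometric GLASSO
tooling; all are configurable. Edges of the reported network are partial
correlations `rho_ij = −theta_ij/sqrt(theta_ii·theta_jj)`.

A note on a tempting invariant: the exact GLASSO path is *not* strictly
monotone in edge count — the brute-force optimizer confirms the solution can
shed an edge as the penalty decreases. Tests assert the trend (empty graph at
`lambda_max`, strongly negative rank correlation between penalty and edge
count), not strict monotonicity.

## Redundancy analysis (UVA)

Locally dependent items are detected on the estimated network via the weighted
topological overlap

`omega_ij = (sum_u |w_iu||w_ju| + |w_ij|) / (min(k_i,k_j) + 1 − |w_ij|)`,
`k_i = sum_u |w_iu|`,

which is symmetric, zero-diagonal, and invariant to a global sign flip of the
weights. A null distribution is fitted to the nonzero overlaps — gamma by
method of moments by default, with lognormal and empirical alternatives,
because the positive support and right skew of wTO values fit a gamma well and
the original choice of family is not documented anywhere we could rely on.
Each pair gets an upper-tail p-value; the cutoff is the adaptive alpha

`alpha_adapt = alpha·sqrt(n_ref(log n_ref + q)) / sqrt(n_tests(log n_tests + q))`,

with `q` the upper-`alpha` chi-square(1) quantile, `alpha=0.05`, `n_ref=10`,
so the threshold tightens as the number of tested pairs grows.

Significant pairs form **redundancy chains** (connected components). Within a
chain the target is the member with the largest summed overlap (the most
redundant hub); the merge set is the target plus its direct neighbors plus any
clique of the chain containing the target; remaining chain members wait for
the next round. Merging fits a one-factor maximum-likelihood model to the
set's correlation matrix (own implementation; two-item sets use the
equal-loading identification) and replaces the sources by the
regression-method factor score, standardized. A Heywood case (uniqueness at
the boundary) or a non-positive two-item correlation falls back to the mean
score with a warning; a plain mean is also available as `method="sum"`.
Composites are named by the underscore-joined sorted source ids ("72_81"
style), and a composite of composites keeps only original ids. The loop
(correlate → estimate → overlap → test → merge) runs to convergence, at most
10 rounds; fewer than 10 nonzero overlap pairs also stops it, since no null
can be fitted then.

## Dimensions: signed spinglass communities

Communities minimize the signed Potts Hamiltonian

`H = −sum_{i<j, same c}(w⁺_ij − γ⁺ p⁺_ij) + sum_{i<j, same c}(w⁻_ij − γ⁻ p⁻_ij)`,

with configuration-model null expectations `p^±_ij = k^±_i k^±_j / 2m^±`
computed separately on the positive and negative subgraphs and resolution
parameters `γ⁺ = γ⁻ = 1`. Annealing is delegated to igraph's
`community_spinglass(implementation="negative")` (25 spins max, start
temperature 1, stop 0.01, cooling 0.99); the Hamiltonian itself is evaluated
in this package, which lets multi-restart runs (default 10 for empirical and
median networks, 1 inside the bootstrap) keep the lowest-energy labeling, and
lets small cases be checked against exhaustive enumeration over all
partitions. Each connected component of the nonzero graph is annealed
separately, because the configuration null is undefined across components;
isolated nodes become singleton communities; an all-zero network is an error.
Runs are deterministic given the seed (igraph draws from Python's `random`
module, which is re-seeded per restart).

Partition agreement uses NMI `2I/(H1+H2)` and AMI
`(I − E[I])/(mean(H1,H2) − E[I])` with arithmetic normalization (the dominant
convention; delegated to scikit-learn). Two single-cluster partitions score
NMI 1 by convention. Partitions over merged items are compared on the original
item set by expanding each composite's label onto its sources.

## Bootstrap EGA and stability

The nonparametric bootstrap resamples respondents (rows) with replacement,
B=500 by default; replicate b re-runs the whole correlate → GLASSO/EBIC →
spinglass pipeline with child seed `seed+b`. Degenerate resamples (an item
collapsing to one category, an unestimable matrix) are redrawn from a fresh
seed stream and counted; more than 10% redraws aborts. The **median network**
takes the elementwise median of the replicate partial-correlation matrices.

Replicate labels are aligned to the empirical (full-data) partition by the
maximum-overlap assignment problem on the label contingency table (surplus
replicate communities keep fresh labels; alignment provably never changes
which nodes share a label). Then

* **item stability** = proportion of replicates in which the item's aligned
  label equals its empirical label (the full item × dimension
  replication-frequency table is also reported);
* **structural consistency** = proportion of replicates in which an empirical
  dimension's *exact* item set recurs as one community; a
  `min_member_fraction` option relaxes membership while still forbidding
  extras (exact-set is the strictest testable form of the construct);
* the **community-count distribution** is summarized by mode, median, mean, sd
  and a normal-approximation 95% CI (`mean ± 1.96 sd` — chosen because such
  intervals are continuous-valued rather than order statistics).

The case-dropping bootstrap for centrality indices re-estimates the network on
subsamples without replacement at increasing drop fractions and Spearman-
correlates each subsample metric with the full-sample metric; the
CS-coefficient is the largest drop fraction up to which ≥95% of correlations
stay ≥0.7.

## Node metrics and subscale agreement

Strength `s_i = sum_j|w_ij|`; one-step expected influence keeps signs
(`EI1_i = sum_j w_ij`, so `|EI1| ≤ strength` with equality on all-positive
networks); two-step adds weight-propagated neighbor influence
`EI2_i = EI1_i + sum_j w_ij·EI1_j`. Network loadings decompose strength over
communities: raw `NL_ic = sum_{j∈c}|w_ij|` (signed variant optional), each
column standardized by the square root of the summed raw loadings of the
community's own members; the raw matrix sums to strength exactly, row by row,
and the standardization constant is recorded in the output metadata since
variants exist in the literature. Rankings break ties by node id.

The agreement table assigns each subscale to the community holding the
plurality of its items (ties to higher Jaccard overlap), then reports per
community the matched subscales, missing items, foreign items (with their true
subscale), the best-overlapping composite score, and unscored items
separately.

## Synthetic benchmark: what it does and does not show

The generator draws latent rows from `N(0, L·Phi·L' + Theta)` with unit total
variance per item (uniquenesses are whatever the loadings leave; non-positive
uniqueness or a non-PD implied covariance is an error naming the violation)
and discretizes through thresholds at z = (−1.5, −0.5, 0.5, 1.5), giving a
unimodal five-category distribution. It plants three kinds of ground truth:
the item → factor partition; near-duplicate items (clone = source latent +
N(0, sd²), rescaled to unit variance and re-discretized); and cohort
perturbations (one item's main loading moved to another factor), which are
stacked with group labels to emulate diagnosis-specific structure.

Benchmark conditions used by the test suite and the acceptance script: easy
dimension recovery uses 4 factors × 5 items, loading 0.7, factor correlation
0.2, n = 1000, 10 generator seeds, B = 100 bootstrap replicates; redundancy
recovery uses 3 factors × 5 items with one clone at noise sd 0.2, n = 500, 20
seeds; the determinism check hashes a complete small pipeline run (9 items,
n = 200, B = 4) twice. Bootstrap-heavy runs use Pearson correlations, the
configuration a practitioner would pick for speed at these sample sizes;
polychoric input is exercised in the correlation and redundancy suites.

What passing these benchmarks does *not* show: real questionnaire data have
skewed category margins, cross-loadings, correlated uniquenesses and
missing-data handling upstream, none of which the default generator includes
(cross-loadings are available but off by default). Recovery at loading 0.7 and
n = 1000 says nothing about weakly determined structures; stability metrics on
real data are expected to be markedly lower, which is precisely what they are
for.

## Numerical choices and degenerate inputs

* PSD smoothing threshold 1e−8; structural-zero floor for edges 1e−10.
* GLASSO convergence 1e−6 (max covariance change per sweep), ≤10 000 sweeps;
  `lambda=0` falls back to the explicit inverse and requires strictly PD input.
* Polychoric pairs with a single observed category are errors; a contingency
  margin emptied by external subsetting is regularized by adding 0.5.
* Spinglass on a network with no nonzero edge is an error ("no structure").
* Ties: rankings by node id; subscale claims by Jaccard; assignment alignment
  as computed by `scipy.optimize.linear_sum_assignment`.
* All randomness flows from a single integer seed: generator seeds, bootstrap
  child seeds (`seed+b`), spinglass restart seeds (`seed+r`). Artifact files
  contain no timestamps, so identical (inputs, config, seed) reproduce
  byte-identical output trees.

## Limitations

Overlapping communities (e.g. clique percolation) are not implemented, so
genuinely multidimensional items can only reveal themselves through low item
stability. The adaptive-alpha reference size, the wTO null family, and the
latent-vs-sum merge choice are defensible defaults for undocumented details of
the workflow this package operationalizes; all three are exposed as
configuration. NMI/AMI use arithmetic normalization; max- and sqrt-normalized
variants are not currently exposed. Polyserial/tetrachoric correlations,
nonparanormal transforms, mixed graphical models and cross-validated penalty
selection are out of scope.
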