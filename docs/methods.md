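# Methods

This note documents the models, parameter choices and numerical decisions
behind `coocnet`, and what the synthetic test bed does and does not
establish about real data.

## Compositional correlation model (SparCC)

Read counts from amplicon sequencing are compositional: per sample only
the fractions `x_i` are informative. SparCC estimates the correlations of
the unobserved *basis* (absolute) abundances from the log-ratio variance
matrix

    t_ij = Var_samples[ ln(x_i / x_j) ]  =  ω_i + ω_j − 2 ρ_ij √(ω_i ω_j),

where `ω_i` is the basis variance of taxon i's log abundance. Under the
sparsity assumption (most `ρ_ij ≈ 0`) the row sums give a linear system

    Σ_j t_ij = (D−1) ω_i + Σ_{j≠i} ω_j,

solved directly (LU; the `(D−2)I + J` structure is well conditioned), after
which `ρ_ij = (ω_i + ω_j − t_ij) / 2√(ω_i ω_j)`, clamped to [−1, 1] since
the closed form can exceed the bounds under sampling noise.

Design points:

* **Dirichlet resampling.** Counts carry multinomial noise; each of
  `n_inner = 20` iterations draws per-sample fractions from the posterior
  Dirichlet(counts + 0.5) and the final estimate is the elementwise
  median (robust to individual draws). Draws are made in canonical
  (sorted-taxon-id) order so relabelling taxa permutes the estimate
  exactly.
* **Strong-pair exclusion.** Up to `n_exclude = 10` pairs with
  `|ρ| > 0.1` are iteratively removed from the system and it is re-solved;
  a taxon already excluded in `D−3` pairs is saturated and its remaining
  pairs stay, which keeps the system non-singular at small D. The 20/10/0.1
  defaults are the de-facto standard for this estimator; all are exposed.
* **Degenerate solutions.** A non-positive solved `ω_i` (possible at very
  small n) is floored at 1e−6 with a warning rather than aborting.
* **Edge significance.** Pseudo p-values come from permuting each taxon's
  counts across samples independently (destroying all between-taxon
  dependence) and re-estimating; `p = (1 + #{|ρ*| ≥ |ρ̂|}) / (n_boot + 1)`.
  Network construction can filter on `|ρ|` alone (default) or additionally
  on `p ≤ α`; both are provided because either convention is common.

The estimator is validated two ways: recovery of planted correlations
under its own generative model (below), and agreement with a naive
Pearson-on-clr estimate within 0.15 mean absolute difference in the
diffuse (low-correlation) regime, which delimits where the sparsity
approximation matters.

## Network construction and topology

An edge joins taxa with `|ρ| > 0.7` (presets 0.5 and 0.75 exist because
different analyses of such data conventionally use all three cutoffs),
labelled by sign. Path metrics (diameter, average path length) are
unweighted and computed on the largest connected component: correlation
weights are not distances, and unweighted metrics match the convention of
the network-viewer tools this analysis style comes from. Average degree is
`2E/N` over connected nodes; weighted degree is the mean signed sum of
incident weights; clustering is the mean unweighted local coefficient.

Modules are Louvain communities on |weight| (the optimization is
ill-defined with mixed-sign weights); isolated nodes count as singleton
modules, following the single-node-module convention of network viewers.
Modularity Q is reported on the same |weight| graph and is ≤ 1 by
construction. Eigenvector centrality uses the |weight| adjacency of the
LCC, scaled to max 1 (nodes outside the LCC get 0); betweenness and
closeness are unweighted and per-component. Louvain and every other
stochastic step are seeded and reproducible.

## Keystone criteria

A keystone taxon must simultaneously (i) occur in every sample of its
group, (ii) have eigenvector centrality ≥ 0.75, and (iii) have mean clr
abundance above the grand mean of all taxa's mean clr values. "Average" in
(iii) is read as the grand mean over taxa (the simplest reading; a
per-sample-mean option exists in the code), and the 0.75 threshold is the
normative default with the cutoff configurable. The criteria select the
apex of the densest network module plus any co-members that genuinely
meet all three conditions — multiple keystones from one module are an
expected outcome, not an error.

## Cross-network statistics

* **Core association network**: edges present in every input network with
  the same unordered pair *and the same sign*; sign-conflicted overlaps are
  not a shared association.
* **Differential network**: Fisher z-transform of both correlation
  estimates, normal test of the difference with
  `SE = √(1/(n_A−3) + 1/(n_B−3))`, BH adjustment over all shared pairs.
  A test on the correlation values (rather than discordance of thresholded
  edges) is used because the target quantity is "correlations that vary";
  a sign-discordance mode is available.
* **Jaccard of central nodes**: for each centrality, the sets are
  shared-universe nodes above the within-network 75th percentile; the hub
  set intersects the top quartiles of degree, betweenness and closeness.
  The null fixes both set sizes and draws them independently from the
  shared universe, making the intersection hypergeometric; `P(J ≤ j)` and
  `P(J ≥ j)` are the two tail probabilities (they overlap in the observed
  point's mass, so they sum to ≥ 1). The universe is the shared node set
  (a union-universe switch exists).
* **ARI**: permutation-model adjusted Rand index on the shared nodes, with
  a node-label-shuffle permutation p-value.
* **Module equivalence**: `100·|A∩B| / |A∪B|` per module pair, matched by
  taxon name (genus labels are the shared namespace), one decimal place.

## Robustness

Connectivity is the number of reachable unordered node pairs; loss after
removing a node set is `1 − R/R₀`. This makes loss(∅) = 0 and
loss(everything) = 1 exact. Strategies: static degree and betweenness
orders (ties by node id), cascading (betweenness recomputed after every
removal), and random (mean over replicates with a standard-error band at
the 0.975 normal quantile, i.e. a 95 % CI). The headline summary is the
smallest node fraction reaching 80 % loss; group differences are reported
in percentage points.

Node addition draws each new node's edge count from the host network's
empirical degree distribution and attaches to uniformly random existing
nodes — this preserves the host's density scale without asserting an
unstated attachment mechanism (fixed-m and preferential options exist).
LCC size and average path length are recorded on a step grid (every step
up to 20, then ~40 evenly spaced checkpoints; path length is all-pairs BFS
on the LCC, so a full 1000-step-per-replicate trace is deliberately
thinned). Paired curves are compared with Wilcoxon signed-rank per metric,
BH-adjusted across the metric family, with bootstrap CIs for the median
per-step difference; the all-differences-zero case short-circuits to p = 1.

## In-silico removal

Default mode deletes the focal node from the fixed network, leaving every
surviving edge untouched — comparing "networks with and without" a taxon
is a graph-level operation. Because compositional estimates are not
strictly deletion-invariant, a re-estimation mode (drop the taxon's counts
and re-run the whole chain) is also provided and labelled.

## Synthetic data: what it emulates

The generator mirrors the post-processing inputs of a two-host-group 16S
study: ~805 genus-level taxa, 13 pooled real samples per group, 5 negative
controls, 50 000 reads per sample, four planted modules sized 208 / 143 /
105 / 71, one dominant keystone hub in the biggest module, one ubiquitous
endosymbiont with exactly 13 planted partners, and 8 reagent contaminants
present in ≥ 80 % of controls but ≤ 20 % of real samples. The two groups
differ in symbiont wiring (inside the third module vs its own tiny
module), reproducing the kind of structural contrast the analysis is meant
to detect.

Basis abundances are multivariate log-normal (log-means uniform on (0, 6)
natural-log units, hub and symbiont above the range, log-sd 1.0) closed to
fractions and read as one multinomial draw per sample — exactly the
generative model under which SparCC is well posed, which is what makes
parameter recovery a meaningful end-to-end check.

**Correlation structure is a factor model**, not equicorrelated blocks:
module member i has loading `λ_i` centred on `√ρ_w` (spread 0.05; zero
spread reproduces an exact block, used by the recovery fixtures) and
`ρ_ij = λ_i λ_j`; the two largest modules' factors are maximally
anticorrelated, giving `ρ ≈ −ρ_w` between them. This is PSD by
construction, produces realistic heterogeneous degree distributions, and
encodes the hub as the member with the top loading (0.99 vs ≤ 0.93). Two
facts drove this choice: in an equicorrelated block every member shares
the hub's eigenvector score, so "the" keystone is undefined; and a pure
correlation star is impossible — positive semi-definiteness forces the
partners of a many-partner hub to be inter-correlated (for k mutually
uncorrelated partners, `ρ_hub ≤ k^(−1/2)`). The default within-module
correlation 0.55 places ordinary member pairs mostly below the 0.7 edge
threshold at n = 13 while hub–member pairs mostly clear it, which is what
makes the hub the network's eigenvector apex. Any hand-edited structure
(keystone partner subsetting) is repaired to the nearest PSD correlation
matrix by eigenvalue clipping and rejected if a planted entry moves by
more than 0.15.

**What the fixture does not emulate**: raw reads, chimeras, amplification
bias, taxonomy misassignment, phylogenetic correlation of abundances, or
the long tail of spurious sample-level effects in real extractions.
Passing the recovery tests shows the chain is correct under its stated
model at the study's sample size; it does not certify SparCC's accuracy on
real midgut data, where n = 13 leaves single-pair correlation estimates
with a null standard deviation near 0.3 and threshold networks therefore
contain substantial estimation noise — as they do in any real study of
this design.

## Numerical choices and degenerate inputs

* clr uses pseudocount 0.5 (a deterministic stand-in for Monte-Carlo
  Dirichlet instances; configurable, and an error is raised if a zero
  count meets a non-positive pseudocount).
* The rare-taxon filter keeps taxa with ≥ 10 total reads AND presence in
  ≥ 3 samples (removal when either condition fails — the stricter and
  standard reading); it is idempotent.
* The contaminant screen is a one-sided Fisher exact test with score
  threshold 0.1 (the cited screening tool's documented default; the
  original reports no value).
* Edgeless networks return explicit NaN sentinels for path metrics; an
  attack on a < 3-node component, an empty collapse result, or a missing
  focal taxon raise errors naming the offending input.
* Jaccard with an empty top-quartile set returns NaN rather than a
  fabricated index.

## Problem sizes used by the test suite

The suite exercises the full default fixture (805 taxa × 13 samples) for
keystone and knockout replication (20 seeds), 20-taxa fixtures at
n = 500–2000 for SparCC recovery, and ≤ 50-node graphs for the exact
oracle comparisons; the demonstration pipeline runs a 50-taxon two-group
study. These sizes were chosen so the whole chain, including replicate
ensembles, runs comfortably on a laptop-class single core.

## Known limitations

* SparCC accuracy degrades when many taxa are strongly correlated (the
  sparsity assumption) or when rare taxa dominate the table; the exclusion
  loop mitigates but does not remove this.
* Louvain module counts fluctuate by ±2 between runs on ~500-node graphs;
  module-count comparisons should be read at ensemble level.
* The hypergeometric Jaccard null conditions on observed set sizes; it is
  the minimal exchangeable model, not a degree-preserving graph null.
* Bootstrap edge p-values are permutation-based and exchange whole
  samples; they do not model compositional coupling under the null.
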