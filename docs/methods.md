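# Methods

## Overview

`netpharm` scores candidate compounds against a disease on a protein–protein
interaction (PPI) scaffold.  The pipeline has four stages — contextualize,
extract, score, combine — each exposed as library functions and as CLI
subcommands.  All graphs are undirected, unweighted and simple; gene identity
is the uppercased symbol string, and probe→gene collapsing is assumed to have
happened upstream.

## Network contextualization

Large interactomes are partitioned with the walktrap algorithm of Pons &
Latapy.  With adjacency matrix `A` and degree matrix `D`, the walk matrix is
`P = D⁻¹A` and node profiles are rows of `P^t`; the distance between
communities C1, C2 is

    r(C1,C2)² = Σ_k (P^t_{C1,k} − P^t_{C2,k})² / deg(k),

with `P^t_{C,k}` the mean over member rows.  Agglomeration merges the
adjacent pair minimizing the variance criterion
`Δσ = |C1||C2| / (|C1|+|C2|) / n · r²`; the dendrogram level with maximum
Newman modularity is reported.  Choices made here:

* **Walk length `t = 4`** by default — the conventional reading of a
  "four-step" walktrap configuration (not four rounds of re-clustering).
* **Disconnected graphs** are partitioned per connected component,
  independently, and per-component max-modularity levels are combined.
  Isolated nodes form singletons.
* **Determinism**: merge ties break on the lexicographically smallest member
  node, so equal inputs give byte-identical partitions.
* The implementation is a dense-matrix one (`numpy.linalg.matrix_power` +
  O(n·m) candidate scans per merge).  It is intended for graphs up to a few
  thousand nodes; the test suite cross-checks it against an independent
  igraph implementation on separable fixtures.

Cluster relevance is a one-tailed over-representation test
(hypergeometric upper tail, `scipy.stats.hypergeom`) of each cluster against
a reference gene list; the **universe is the node set of the partitioned
network** (the conservative choice), the reference is intersected with the
universe first, and the minimum-p cluster wins (ties: larger overlap, then
smaller cluster id).

## Active-subnetwork extraction

Gene-level p-values are modelled as a beta-uniform mixture (BUM)

    f(p) = λ + (1−λ)·a·p^(a−1),    0 < λ, a < 1,

fitted by maximum likelihood with nine fixed L-BFGS-B starts on the
(λ, a) ∈ {0.15, 0.5, 0.85}² grid, bounds [1e−6, 1−1e−6]; the best
log-likelihood wins, so the fit is deterministic.  p-values of exactly 0 are
clipped to 1e−12; fewer than 50 observations is an error; a fit with both
parameters at the boundary raises a degenerate-fit warning.

A target false-discovery rate (default **FDR = 0.05**) is inverted through
the mixture's FDR curve, `FDR(τ) = π·τ / (λτ + (1−λ)τ^a)` with
`π = λ + (1−λ)a`, giving the closed-form threshold
`τ = ((π − FDR·λ) / (FDR·(1−λ)))^(1/(a−1))`, clipped to 1 (with a warning)
when the requested rate exceeds the fitted null fraction.  Node scores are
`S(p) = (a−1)(ln p − ln τ)`: zero at τ, positive below it.

The maximum-weight connected subgraph under these scores is approximated by
a deterministic greedy accretion: connected components of positive-score
nodes are contracted to meta-nodes with summed scores; starting from the
highest-scoring meta-node, the (meta-node, connecting path) pair with the
largest net gain — meta score minus the cheapest path cost through
negative-score nodes (node-weighted multi-source Dijkstra) — is attached
while the gain is positive.  Ties break lexicographically.  If no node
scores positive the single best node is returned with a warning.  An exact
ILP solver is deliberately avoided; on all ≤12-node instances in the test
suite the heuristic stays within 0.8× of the exhaustively enumerated
optimum and matches it whenever the positive nodes form at most two
components.  Genes present in the network but missing from the p-value
table receive the minimum observed score, so they can still serve as
connectors.

**A calibration note on module recovery.**  The fraction of a perturbed
module that can ever enter the subnetwork is bounded by `P(p < τ) = τ^a`
for module p-values ~ Beta(a, 1).  At FDR = 0.05, τ is on the order of
1e−2, so a moderately perturbed module (a ≈ 0.2) can contribute at most
~35 % of its genes regardless of the search algorithm.  The synthetic
generator therefore defaults to `a_signal = 0.05` (median module p ≈ 1e−6,
matching the top of a strongly perturbed differential-expression table),
under which the extractor recovers planted 20-gene modules at Jaccard ≥ 0.6
in ≈95 % of seeds.  Weakly perturbed modules are genuinely not recoverable
at this FDR, which is a property of the score calibration, not of the
search.

## Differential expression

The library computes a per-gene two-sided Welch t-test (log2FC = treated
mean − control mean; Benjamini–Hochberg adjustment via statsmodels) and
also imports externally fitted DEG tables (`gene  log2fc  pvalue[  fdr]`),
which is the recommended path when an empirical-Bayes moderated fit is
available — shrinkage is not re-implemented here.  Signature thresholds are
**strict**: a gene enters the signed signature iff `fdr < 0.05` and
`|log2FC| > 1.2`.  The 1.2 is taken literally in log2 units.  Genes with
missing values are dropped with a logged count; genes constant across all
samples get p = 1 with a warning.  An empty signature is a warning, not an
error: weak perturbations legitimately deregulate nothing at these
thresholds.

## GO semantic similarity (NetSim)

Wang's measure with `w_is_a = 0.8`, `w_part_of = 0.6`.  S-values are
computed by a Dijkstra-style max-product relaxation over the ancestor
closure (all edge weights < 1, so the first finalization is exact).
Aggregation is best-match average (BMA) at both levels — term-pair matrix →
gene–gene similarity, gene–gene matrix → set–set similarity — and only
**biological_process** annotations are used by default (configurable).
Direct annotations suffice; no pre-propagation, since S-values already
traverse ancestors.  Genes without usable annotations are dropped with a
logged count; if either side loses all genes, NetSim is defined as 0 (with
a warning) so composite scores stay finite.  NetSim is always in [0, 1].

Note that on small synthetic ontologies the BMA baseline between *random*
gene sets is high (~0.9), because every term is a few hops from the root;
real GO DAGs are far deeper and discriminate much more.  Tests that need
functional separation therefore construct branch-structured DAGs
explicitly.

## Composite scoring

* Proximity `d = 1 − mean_{n1∈N1} min_{n2∈N2} dist(n1,n2) / Diam`, with
  unweighted shortest paths on the background network and `Diam` computed
  once on its largest connected component and cached.  A source node that
  cannot reach any target contributes `Diam` (normalized 1), which keeps
  `d ∈ [0, 1]`.  The direction is disease→candidate; no symmetrization.
* Orthogonality: cosine of ±1 sign vectors over common genes,
  `(n_agree − n_disagree)/n_common`; 0 if no gene is shared.  The
  prioritization term is `orth = −cosine` (reversal-positive), which makes
  the stated maximum of 3 attainable by a perfectly reversing candidate.
  Both cosine and orth are reported in every output table.
* Final Score = `d + NetSim + orth`, validated component-wise.
* Rankings are emitted both with and without the orthogonality term
  (`rank_final` vs `rank_d_netsim`); ties break on candidate id, so output
  tables are byte-reproducible.

## Drug-combination simulation

The disease subnetwork is the background; the compound subnetwork is the
source.  A drug's target set is its signature genes (|log2FC| > 1.2, signs
kept) united with its literature targets; unsigned known targets count for
proximity and overlap but not for the cosine.  Each (drug, dose) pair is an
independent row, and a cross-dose intersection report lists drugs selected
at every dose.

The combination *overall score* uses the **raw cosine** (concordance) as
its third term: a synergist is a drug that pushes common targets in the
same direction as the compound, so reversal must not be rewarded here.
This deliberately differs in sign from the disease-prioritization score;
both conventions are explicit flags and are recorded in run manifests.
Selection is two-stage: top (synergists) or bottom (enhancers) `k_rank=50`
by overall score — synergists are removed before enhancer selection, so the
two lists are always disjoint — then the `k_overlap=20` among them with the
most targets on the background network.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:

* **Interactome**: Barabási–Albert scale-free graphs (default,
  `m = 2`) or Erdős–Rényi, over synthetic symbols `G0001…`; the largest
  component is kept.  Planted modules are BFS balls thickened with internal
  edges to a target density (default 0.3) — dense, as real pathway modules
  are.
* **p-values**: module genes ~ Beta(`a_signal`, 1) (default 0.05, see the
  calibration note), background Uniform(0, 1); a direct BUM sampler with
  chosen (λ, a) supports calibration tests.
* **Drug signatures**: each drug shares `⌈ω·|sig|⌉` genes with a disease
  signature and flips the sign of a fraction ρ of them, giving expected
  cosine `1 − 2ρ` on shared genes; remaining genes come from an
  off-signature pool.
* **GO**: random single-root BP DAGs (1–2 parents per term, 15 % part_of)
  with 1–5 leaf-biased annotations per gene.

Everything is driven by one seeded generator per scenario; equal seeds give
byte-identical fixtures, and every written file embeds the scenario JSON in
a header comment.  What the generator does *not* emulate: microarray noise
and batch structure, the depth of the real GO hierarchy, degree-correlated
annotation biases, and LINCS-scale (≈1000-drug) panels — so passing tests
demonstrate correctness of the computations and the designed selection
behavior, not field performance on real transcriptomes.

## Problem sizes and tolerances

Bundled simulations run at 100–300 network nodes, 10–50 drugs, 25–40 GO
terms and 25–100 seeds per property — sizes chosen so the full suite
completes in well under a minute per module while estimator variance stays
far below the asserted margins (e.g. BUM recovery to ±0.05 at n = 10⁴).
Oracle equivalences (proximity vs. all-pairs BFS, Wang/BMA vs. recursive
brute force, Fisher vs. hypergeometric summation) are asserted to 1e−12;
the BUM FDR inversion round-trips to 1e−9.

## Known limitations

* The MWCS heuristic has no global optimality guarantee beyond the tested
  regime; very fragmented positive-node sets can lose to the exact optimum.
* The walktrap implementation is dense and not suitable for interactomes
  beyond ~10⁴ nodes without sparsification.
* Proximity uses raw normalized distance; degree-preserving permutation
  nulls (z-scored proximity) are intentionally out of scope.
* Expression import is gene-level only; probe mapping, normalization and
  batch correction must happen upstream.
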