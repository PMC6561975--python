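# Methods

## Model

A clustering is a map from N labeled elements to K nonempty clusters;
overlap means multiple memberships per element, and a hierarchical
clustering additionally carries an acyclic parent/child DAG over the
clusters. Each cluster gets a level `l` in [0, 1] by taking the
*longest* path from any root (multiple roots are allowed) and rescaling
by the maximum depth D; a flat clustering is the degenerate D = 0 case
with all levels 0. Levels depend only on the cluster DAG, never on
which elements sit where.

The element-centric similarity of two clusterings A and B is computed
in four steps:

1. **Affiliation graph.** Bipartite weights `a_ib = exp(r * l_b)` for
   every membership; `r` trades off coarse against fine hierarchy
   levels, and `r = 0` collapses a hierarchy into an equally weighted
   overlapping clustering. A single `r` applies to both sides of a
   comparison; a flat clustering sits at level 0 and is therefore
   unaffected by `r`.
2. **Element graph.** `W = D⁻¹ A C⁻¹ Aᵀ` with D the diagonal of
   element weight sums and C the diagonal of cluster weight sums. Rows
   sum to 1 by construction (checked to 1e-12 in tests); the entries
   equal the landing probabilities of a two-step walk element → cluster
   → element, so co-occurrence in a small cluster counts for more than
   in a large one and many memberships dilute each. Self-loops are
   kept; under overlap or hierarchy W may be asymmetric.
3. **Affinity.** Per-element personalized PageRank
   `p_i = (1 − α) v_i + α p_i W` with restart probability `1 − α`.
   The default α = 0.90 weights how far overlap and shared hierarchy
   lineage propagate; every row keeps at least `1 − α` on its own
   element.
4. **Score.** `S_i = 1 − (1/2α) Σ_j |p^A_ij − p^B_ij|`, and S is the
   plain mean over elements. The `2α` correction rescales the
   attainable L1 range (the restart mass can never differ) so that
   S_i spans [0, 1]. The L1 metric is used because it weighs
   probability differences independently of their magnitude, i.e.
   cluster sizes are treated equally; squared or Hellinger-type metrics
   would re-introduce a size bias and are deliberately not offered.

Over a set of clusterings, the *average agreement* of a reference is
the per-element mean of S_i against each member; the *consistency* of a
set is the per-element mean of S_i over all unordered pairs. The raw
pairwise mean is 1 for perfectly consistent sets; because reports often
want "high = inconsistently grouped (frustrated)", the complement
1 − value is exposed alongside, with the raw value canonical.

## Solvers and numerics

For a disjoint flat clustering the fixed point has a closed form:
within a cluster of size n, self-affinity `(1 − α) + α/n` and `α/n`
per co-member, zero elsewhere. A published variant of this formula
places the `(1 − δ_ij)(1 − α)` term off-diagonal, which does not yield
probability rows; the form used here is derived directly from the
restart equation and verified against the iterative solver to 1e-10
over random partitions in the test suite.

Every other input goes through power iteration on the fixed-point
equation (contraction rate α, residual tolerance 1e-12 in max norm,
iteration cap 1e5 — roughly 260 iterations at α = 0.9). Rows are
solved once per *membership class* (elements with identical weighted
membership sets); class mates' rows differ only by exchanging the two
element indices, which is applied exactly rather than re-solved.
Affinity matrices are stored sparse; for partitions the per-row support
is the element's cluster.

Degenerate-input conventions, chosen for determinism and documented
rather than silent: duplicate membership rows collapse (membership is a
set property); universe alignment is strict by default and
`pad-singletons` (each missing element becomes its own new cluster)
must be requested, because silent padding changes scores; NMI of two
zero-entropy partitions is 1; pair-counting denominators of 0 give 0
with a warning; ranked score ties break by element id; size-sequence
entropy is reported in bits (base 2 — the monotone comparisons it
feeds are base-independent).

## Classic measures

Pair-counting measures (Rand, Jaccard, F, Fowlkes–Mallows, adjusted
Rand) are computed from exact pair counts via the contingency table and
restricted to partitions. ARI uses the permutation-model expectation in
its pair-count form `2(n11·n00 − n10·n01) / ((n11+n10)(n10+n00) +
(n11+n01)(n01+n00))`; NMI defaults to the arithmetic-mean normalization
`2I/(H_A+H_B)` with `max` and `sqrt` variants available; VI is reported
in nats. Percentage matching uses an optimal one-to-one cluster
assignment (Hungarian) by default — deterministic and faithful to
"best match" semantics — with greedy matching as an option.

Two cover-capable measures are included. The Omega index adjusts the
fraction of element pairs sharing the same *number* of common clusters
by its chance expectation; on partitions it reduces exactly to ARI
(verified to 1e-12 in tests). ONMI is the per-cluster binary-variable
cover NMI: each cluster's best conditional entropy over the other
cover's clusters, subject to the admissibility constraint
`h(11)+h(00) ≥ h(01)+h(10)`, normalized by the cluster's entropy and
averaged in both directions. One convention is ours: a zero-entropy
membership variable (a cluster spanning the whole universe) carries no
information, so it counts as unexplained unless the other cover
contains the identical cluster — without this, a clustering that has
collapsed to a single cluster would receive ONMI 0.5 against any
partition, which contradicts the measure's observed near-zero behaviour
throughout the size-skew benchmark while keeping identical covers at 1.

## Synthetic benchmarks

The generators define the benchmark conditions:

* `randomized_membership` — 1,024 elements in 32 equal clusters,
  compared to a copy in which a fraction f of uniformly chosen elements
  have their memberships permuted *among themselves*. This
  interpretation of "shuffled" preserves the cluster size sequence
  exactly for every f, which is the point of the scenario: a good
  measure should stay above zero at f = 1 because the shapes still
  agree.
* `skewed_sizes` — from the same base with all memberships first
  randomized uniformly over the 32 clusters, each step removes one
  uniformly chosen element from its cluster and reassigns it
  proportionally to current cluster sizes (rich-get-richer; an emptied
  cluster has zero probability and is dropped from snapshots). The
  study condition is 5×10⁶ steps with a comparison every 500 steps;
  the scenario runner defaults to summarizing at 10 evenly spaced
  snapshots and both cadence and length are parameters. Tests and the
  acceptance script use 5×10⁵ steps, snapshots every 5×10⁴, 10
  replicates — enough for the size entropy to fall by over 4 bits,
  which is the regime the directional claims concern.
* `num_clusters` — 1,024 elements in 8 equal clusters versus random
  partitions into c near-equal clusters, c swept over powers of two
  from 2 to 1,024; 10 replicates in tests.
* `matching_triplet(n, k, f)` — A the equal partition; B moves the
  first `m = floor(f·n/k)` elements of each cluster to the next cluster
  cyclically; C spreads the same elements evenly over the other k − 1
  clusters. Any set-matching measure scores B and C identically.
* `kary_hierarchy` — full k-ary cluster trees with equal leaf blocks
  and internal members equal to descendant unions; each level slice is
  a partition, used for the zooming-lens comparisons.

All generators are deterministic under a fixed seed; scenario summaries
report mean and standard deviation per measure per sweep point.

## What the synthetic benchmarks do and do not show

The generators probe measure *biases* under controlled, worst-case
cluster-shape manipulations: they use uniform random memberships, exact
size control, and no data-driven cluster structure. Passing the
directional checks shows a measure's response to membership noise, size
skew, and cluster-count mismatch — it does not certify behaviour on
real data, where cluster structure, overlap patterns, and hierarchy
shapes are correlated with the elements themselves. Hierarchy
benchmarks here use nested unions (internal clusters contain their
descendants' elements); the data model deliberately permits arbitrary
member sets per cluster, since real hierarchical community detectors
sometimes assign elements directly to internal clusters.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α | 0.90 | restart survival probability; higher α spreads affinity further through overlaps/hierarchy |
| r | 0.0 | hierarchy weighting exponent in `h(l) = exp(r·l)`; dimensionless |
| tol | 1e-12 | max-norm residual target of the iterative solver |
| alignment | strict | `pad-singletons` adds missing elements as singletons |
| NMI normalization | arithmetic mean | `max`, `sqrt` variants |

## Known limitations

* Exact solves only; no approximate/streaming personalized PageRank,
  so highly overlapping, deeply hierarchical clusterings at large N are
  the worst case (one linear solve per membership class).
* Pair-counting and information-theoretic measures are deliberately
  partition-only; the Omega index and ONMI are the overlap-capable
  baselines.
* Dendrograms with merge-distance weights (branch lengths) are not
  supported; levels come from path lengths in the cluster DAG only.
* The affiliation weighting is fixed to the exponential family
  `exp(r·l)`; arbitrary user-supplied weighting functions are out of
  scope.
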