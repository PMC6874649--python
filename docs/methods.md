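# Methods

## Data model

A network is a plants × bees matrix of nonnegative integer visit counts.
Counts are tallies: fractional values in input files are rejected rather
than rounded. After loading, all-zero rows and columns are removed (a
species with no observed visits carries no information for any index
here), and every operation preserves the file's first-appearance label
order so that seeded stochastic procedures are reproducible run-to-run.
Honeybee exclusion removes flagged bee columns and then any plant row left
with zero visits (a plant visited exclusively by the flagged species).

## Species-level metrics

For plant *i* with visits `a_ij` (bee totals `A_j`, bee count *B*):

* **ND** = (number of partner bees) / *B*.
* **ST** = Σ_j `a_ij / A_j` — the sum of bee dependencies, so plant
  strengths always sum to *B* (a conservation law used as a test).
* **CC / BC** are computed on the *unweighted one-mode plant projection*
  (two plants adjacent iff they share at least one bee). The sources this
  procedure derives from do not specify the graph; the unweighted
  projection is the common practice for these indices. Closeness uses the
  Wasserman–Faust component scaling (reachable fraction / (n−1));
  betweenness is Brandes' algorithm normalized by (n−1)(n−2)/2; plants in
  singleton components score 0, and a single-plant network reports 0 for
  all projection-based metrics with a warning.
* **FC** (functional complementarity): the network-level quantity is the
  total branch length of a UPGMA dendrogram over Euclidean distances
  between plant visit rows, computed as the sum of merge heights. The
  per-plant value is the leave-one-out contribution
  FC_total(all) − FC_total(all∖{i}), which is brute-force testable and
  makes a duplicate visitor profile worth exactly 0. Total branch length
  is not strictly monotone under point removal with average linkage, so
  rare slightly-negative contributions are floored at 0.

## Specialization (d′, H2′)

d for species *j* is the Kullback–Leibler divergence
Σ_i p′_ij ln(p′_ij/q_i) between the species' use distribution p′ and the
partners' marginal availability q. It is standardized to
d′ = (d − d_min)/(d_max − d_min) and clipped to [0, 1], with discrete
bounds given the observed marginal totals:

* **d_min** distributes the species' total as proportionally to q as
  integers allow. Because the objective is separable and convex in each
  cell, adding one visit at a time wherever the marginal increase is
  smallest yields the *exact* integer optimum (verified against
  exhaustive enumeration at small totals in the tests).
* **d_max** fills partners in order of increasing availability, each
  capped at its marginal total — the field-standard algorithm. It is a
  heuristic: when caps bind, concentrating on a slightly commoner partner
  can exceed the rarest-first fill, so the clipping above is load-bearing.
  Whenever the rarest partner can absorb the species' full total the fill
  is provably optimal (ln(1/q_min)); the tests check exactly that case.

H2′ = (H2_max − H2)/(H2_max − H2_min), clipped to [0, 1]. H2 is the
Shannon entropy of the interaction frequencies; H2_max is the entropy of
the outer-product-of-marginals table, the maximum-entropy table with the
observed marginals (so H2 ≤ H2_max always and any integer independence
table scores exactly 0); H2_min comes from greedy packing of the largest
remaining row and column marginals, which reproduces any
permutation-diagonal table exactly (score 1) but can overestimate the true
minimum entropy in general — another reason the ratio is clipped. Natural
logarithms throughout; 0·ln 0 = 0.

## Müller shared-visitor index

`PAC[target i, acting k] = Σ_j (a_ij/A_i·)(a_kj/A_·j)`. Target rows sum
to 1 by construction. Per-plant acting scores sum each plant's column over
the *other* targets; self-pairs are excluded by default because a plant
"supporting its own pollinators" is not exported function
(`include_self=True` restores the inclusive variant, under which total
mass equals the number of plants).

## Robustness

Bees (the higher level only) are removed uniformly at random one at a
time; a plant goes secondarily extinct with its last bee. Robustness is
the trapezoidal area under the survivors-vs-removed curve with endpoints
(0, 1) and (1, 0), averaged over removal orders. Exact enumeration of all
orders is available for ≤ 8 bees and pins the forced values 0.5 (one bee)
and 0.75 (two bees shared by every plant).

## Restoration simulations

Coverage of a plant set is the fraction of bee species reached
(richness) or of visits retained (visitation). Simulations evaluate set
sizes in multiples of two (the final size capped at the plant count); a
`step=1` refinement flag exists but defaults to 2 to match the procedure
being reproduced. The reported outcome is the smallest evaluated size
whose coverage meets the threshold (default 0.8), and its proportion of
the flora.

* **Random baseline**: by default the exact expectation — per bee with
  `P_b` host plants, P(covered by a uniform k-subset) =
  1 − C(P−P_b, k)/C(P, k); expected visitation coverage is k/P by
  symmetry. A Monte-Carlo mode (default 1000 subsets per size) mirrors
  simulation-based practice and is tested against the closed form.
* **Genetic algorithm**: fixed-cardinality bit-vector chromosomes,
  fitness = coverage; tournament selection (size 3), one-point
  cardinality-preserving crossover (repair by random swap, rate 0.9),
  per-bit swap mutation (rate 0.02), elitism 1, population 100, up to 200
  generations with a 30-generation no-improvement stop. The cited
  selection tool's hyperparameters are not published; these defaults were
  chosen for reliable convergence on ≤ 100-plant networks and are
  config-overridable. Deterministic given the seed.
* **Exhaustive oracle**: for visitation the objective is additive, so
  descending-total order is provably optimal at every cardinality; for
  richness subsets are enumerated (guarded to ≤ 20 plants). Used in tests
  to certify the greedy and GA results.

## Phylogenetic structure

MPD is the mean over ordered pairs of the patristic distance; MNTD the
mean nearest-neighbour distance within the sample. Null sets are k-subsets
of the pool drawn without replacement with probability proportional to the
supplied weights (visit counts within a network; occurrence counts for the
global pool; uniform when absent). Weighted draws use exponential sort
keys, which is distributionally identical to sequential
draw-remove-renormalize sampling — stated explicitly because alternative
weighted-without-replacement schemes change the null distribution. The
null sd uses ddof = 0 (the null sample is the population being summarized);
an exhaustive mode enumerates all k-subsets for small uniform pools.

SES = (observed − null mean)/null sd is reported directly as
"negative NRI/NTI" (negative ⇒ clustering) alongside the classic Webb
indices (−SES). Both the normal-approximation z-test p (one- and
two-tailed, since the source convention is ambiguous) and the
distribution-free rank p = (r+1)/(n_null+1) are emitted; α = 0.025 is a
reporting default, never hard-coded.

`comdist` averages distances over the full cross-product of species pairs
(unweighted; an identical species contributes 0). ANOSIM is implemented
in-package so permutations are seedable — R = (mean between-group rank −
mean within-group rank)/(N(N−1)/4) with average ranks for ties — and is
cross-checked against scikit-bio's implementation in the tests.

## Family enrichment

Expected counts are fractional: family share of the network's plants ×
selection size. Differences observed − expected are pooled per network (a
family absent from a network contributes nothing there — it could not
have been selected), and tested with a one-sample z-test (sample sd,
n−1; normal reference). With few networks per family the normal reference
is mildly anticonservative relative to a t reference; the calibration test
therefore runs at 12 networks and accepts a 2–10% empirical type-I rate at
nominal 5%. Families with ≥ 10 summed occurrences are flagged common; no
multiple-testing adjustment is applied (matching the raw-z reporting this
reproduces), though the tidy output carries everything needed to add one.

## Restored-network evaluation

The two criteria's selections are compared at equal size: the visitation
selection is truncated, in its ranking order, to the richness selection's
size (the richness target typically needs fewer plants; if the visitation
selection is already shorter both are truncated to the shorter length so
the equal-size contract always holds). Proportions use full-network
denominators. Müller acting scores are always taken from the full
network's PAC matrix: the fraction of exported function retained is a
property of each plant in the intact community, not of the truncated one.

## Synthetic data

`gen_network` draws lognormal plant and bee abundance weights, mixes the
neutral outer-product rates with a sparse partner-affinity matrix by the
specialization parameter θ, and allocates the configured visit total
multinomially — the total is exact, keeping visitation denominators
deterministic. `gen_tree` builds ultrametric family subtrees (depth 0.3)
grafted on a stem tree (root depth 1.0) with Yule-distributed topologies,
so within-family distances are always below between-family distances.
`gen_conserved_scenario` simulates a Brownian log-abundance trait on the
tree (covariance = shared path length), blends it with white noise as
√λ·B + √(1−λ)·ε, and exponentiates it into plant weights. The blend is a
controllable signal knob, *not* an estimate of any empirical branch-length
transformation.

What the generator does **not** emulate: phenology and temporal turnover,
behavioural rewiring, sampling effort and detection bias, or abundance
standardization per flower. Passing tests therefore certify the
correctness and calibration of the procedures on data with the assumed
structure, not the field validity of the original survey conclusions.

## Problem sizes

Desk-scale sizes keep the full suite and the acceptance script fast while
leaving every comparison statistically meaningful: the strategy study uses
24 networks of 24 plants × 30 bees and 1500 visits (σ = 1.2, θ = 0.3);
oracle agreement uses 100–200 networks of ≤ 12 plants; null-model
calibration uses a 100-leaf pool, samples of 20, 10 000 nulls and 1000
replicates; the conserved-trait power scenario uses 20 families × 5
species, 30 bees, 3000 visits, σ = 1.5, θ = 0, with 200 replicates in the
tests and 50 in the acceptance script.

## Known limitations

* CC/BC on the unweighted projection discard visit weights by design;
  weighted-path centralities are out of scope.
* The d_max and H2_min heuristics are the standard algorithms but not
  exact combinatorial optima; d′ and H2′ are clipped to [0, 1] and their
  extreme-table identities (0 on independence tables, 1 on
  permutation-diagonal tables, d′ = 0 for a lone bee) hold exactly.
* Aggregated networks: no multilayer/temporal support, no
  pollen-transport networks, and the Müller index is a proxy — it weighs
  shared visitors, not pollination effectiveness.
* The GLMM/AICc model-selection layer that consumes the per-network
  tables emitted here is deliberately out of scope.
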