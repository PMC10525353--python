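# Methods

This note documents the models and procedures implemented in `richclubnet`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and the limits of what the synthetic validation shows.

## Input model

A structural connectome is a symmetric, non-negative weighted adjacency
matrix over the nodes of a parcellation atlas; by default the 90-region
AAL cortical/subcortical parcellation (45 bilateral regions). Weights are
streamline-count-derived and dimensionless; they are used exactly as given
— no streamline normalization is applied, so any weight preprocessing is
the caller's responsibility. An edge exists wherever w > 0; binary degrees
are computed on that support with no weight threshold. Matrices are stored
as headerless delimited text; symmetry is enforced to 1e-8 absolute
tolerance (round-trip noise is symmetrized away, anything larger is an
error).

The rich-club node set is fixed a priori by atlas flags — bilateral
superior frontal cortex, superior parietal cortex, precuneus, hippocampus,
putamen and thalamus (12 nodes) — rather than derived per subject from the
normalized coefficient. The cohort-level existence test below acts as a
sanity gate for that choice; by default it runs on the element-wise mean
connectome of the cohort (per-subject testing is available).

## Global metrics

* **Connectivity strength.** Node level: row sum of weights. Network
  level: the *mean* node strength. The mean (rather than raw-sum)
  convention is what puts whole-brain values of normalized streamline
  networks on the familiar ~4–6 scale; the raw per-node vector remains
  available.
* **Clustering coefficient.** Onnela form — geometric mean of triangle
  weights with all weights first divided by the network maximum — averaged
  over nodes, degree<2 nodes contributing 0. Delegated to networkx, which
  implements exactly this estimator. The max-normalization makes the value
  scale-invariant.
* **Efficiency.** Edge length is 1/w, the standard mapping for
  streamline-weight networks (stronger = shorter; `-log w` would be the
  alternative if weights were probabilities). Global efficiency averages
  inverse shortest-path length over ordered pairs, unreachable pairs
  contributing 0, so it is well defined on disconnected graphs. Local
  efficiency is the mean over nodes of the neighborhood subgraph's global
  efficiency (node removed; degree<2 nodes contribute 0). Shortest paths
  use Dijkstra via scipy's sparse csgraph.

All four are validated against brute-force enumeration (explicit
Floyd–Warshall, ordered-pair triangle counting) on 1000 random graphs of
≤ 8 nodes.

## Weighted rich-club coefficient

For each degree threshold κ, take the subgraph of nodes with binary degree
strictly greater than κ. With E(κ) edges inside it,

    Φw(κ) = (sum of weights inside the subgraph)
            / (sum of the E(κ) largest edge weights in the whole network),

so Φw ∈ [0, 1] by construction. Φw is undefined where the subgraph has no
edges; undefined entries are NaN, never zero, and because the >κ node sets
shrink monotonically the defined κ range is always a prefix of 1..κmax.

## Null ensemble and normalization

Random comparison networks preserve each node's degree exactly and the
multiset of edge weights exactly: Maslov–Sneppen double edge swaps on the
binary topology (target `swap_factor`·|E| accepted swaps, default
swap_factor = 10, a conventional mixing heuristic; proposals creating
self-loops or multi-edges are rejected), followed by reassignment of the
original weight multiset onto the rewired edge list in a random
permutation. Graphs too dense or too small to admit any swap (e.g.
complete graphs, whose degree sequence has a unique realisation) fall back
to weight shuffling with a warning. The swap loop is numba-compiled; a
single 90-node, ~900-edge rewire takes about a millisecond, which is what
makes ensembles of m = 1000 per network practical.

    Φnorm(κ) = Φw(κ) / mean over m nulls of Φw,rand(κ),

defined where both numerator and null mean are defined and positive.
Values above 1 over a range of κ indicate rich-club organization.

## Existence test

The observed statistic is the trapezoidal AUC of Φw(κ) over its defined κ
range; the null distribution is the AUCs of freshly rewired ensemble
members. The two-tailed permutation p uses the +1-corrected estimator
p = min(1, 2·min((b≥+1)/(n+1), (b≤+1)/(n+1))), so p ≥ 1/(n+1) and a
constant statistic yields p = 1. Because the source description of this
test ("two-tailed t-test with permutation testing") is ambiguous, a
two-tailed one-sample t-test of the null AUC sample against the observed
AUC is reported alongside; the permutation p is primary. The binary
decision requires p < 0.05 *and* Φnorm > 1 on at least 2 consecutive κ
(a single exceedance point is not a "range"). Defaults m = 1000 nulls for
normalization and 10,000 permutations for the AUC test.

## Edge classes and region strengths

Edges partition by endpoint flags into rich (both endpoints in the club),
feeder (exactly one) and local (neither); the three per-subject class
strengths are sums of class edge weights and therefore add up to the
connectome's total weight (checked to 1e-9 relative). Region-specific
strengths sum one rich-club node's class edges per hemisphere and average
left and right; a rich edge joining two club regions contributes to both
regions' totals, including the homotopic left–right edge of a single
region. The hippocampus is included in the hemisphere-averaged outputs
like every other club region. Z-scores standardize all subjects by the
reference group's mean and sample SD (n−1 denominator; reference group
cognitively unimpaired by default), so reference members have mean 0, SD 1
by construction. GLMs run on raw strengths; z-scores are for
visualization and cross-variable comparability.

## Group/sex inference

Ordinary least squares of a per-subject outcome on diagnostic group, sex
and nuisance covariates (age in years, education in years by default),
with Type-III sums of squares under sum-to-zero factor coding; effect size
is partial eta squared, SS_term/(SS_term + SS_error). Covariate-adjusted
(least-squares) cell means ± SE are evaluated at the covariate sample
means.

Permutation-adjusted p-values, always (b+1)/(n_perm+1):

* **Main effects** permute the tested factor's labels across subjects
  while every other column stays attached to its subject. This is only
  asymptotically exact when covariates correlate with the permuted factor:
  on null synthetic cohorts of 30 subjects the group term rejected at 6.3%
  instead of 5% (1000 replicates), while at 60 subjects it is calibrated
  (4.25%, 800 replicates). Treat group-term permutation p-values from
  cohorts far smaller than that with caution.
* **Interactions** use Freedman–Lane residual permutation: residuals of
  the reduced (no-interaction) model are permuted and added back to its
  fitted values, because plain label permutation is invalid for an
  interaction under non-null main effects. Both schemes are selectable.
* **Exhaustive mode** enumerates all distinct label arrangements when the
  design is small enough, giving exact p-values (observed arrangement
  included, p = b/n_total).

Family-wise control uses the max statistic: one shared permutation stream,
each permutation contributing its maximum F across the family, each
outcome compared against that max-F null. The default family for the
per-group sex comparisons is the full figure-panel set — every
(diagnostic group × edge class) test jointly, permuting sex labels within
each group stratum — matching the convention of adjusting across all
comparisons displayed together; per-outcome adjustment is available by
config.

Correlations between connectivity and cognition (K-MMSE, CDR sum of
boxes) trim subjects outside the inclusive [P5, P95] interval of the
cognitive variable (linear-interpolation percentiles) before Pearson's r;
the permutation p shuffles one variable and is two-tailed on |r|.

## Synthetic cohorts

The generator exists so that every stage is testable without imaging data.
Its template is a three-block core–periphery graph over the atlas: edge
probabilities 0.9 / 0.4 / 0.15 and weight scales 0.6 / 0.3 / 0.15 for
rich / feeder / local pairs, with log-normal dispersion (log-SD 0.25),
regenerated until connected. These defaults give a 90-node template whose
mean node strength (~4.7) and global efficiency (~0.19) sit in the range
reported for normalized streamline-count networks of elderly clinical
cohorts, and whose rich-club existence test is decisively positive;
the clustering coefficient (~0.07) runs below the empirical ~0.17, a
known simplification of independent-edge block models, which produce
fewer triangles than spatially embedded brains.

Subjects are the template times a multiplicative (group, sex, edge-class)
effect factor times i.i.d. mean-one log-normal edge noise (log-SD 0.2), so
weights stay positive, the sparsity pattern is fixed, and the expected
class strength is exactly the planted factor times the template's.
Effects are planted per edge class because that is the level at which the
cohort findings live. The packaged planted pattern is a women-only 0.8×
deficit on rich and feeder strength in the dementia cell plus a 0.85×
local deficit in both sexes of that cell. Covariates emulate the cohort's
structure: age ~ Normal(μ_group, 8) with group means 69.4/71.7/69.6 years,
education ~ Normal by sex (women 10.3 ± 4.7, men 13.7 ± 4.0 years,
reproducing the education gap that makes covariate adjustment
non-trivial). Cognitive scores are group base levels plus a linear
coupling to relative total connectivity plus Gaussian noise, clamped to
valid ranges (K-MMSE to [0, 30], CDR-SOB ≥ 0). Default cell size is 60
subjects per group × sex cell.

What the generator does *not* emulate: tractography error structure,
distance-dependent connection probability, inter-subject topology
variation (all subjects share the template's support), site or scanner
effects, and realistic triangle density. Passing recovery tests therefore
shows the pipeline's estimators and tests are correct under the stated
generative model, not that the clinical effect sizes themselves are
reproducible.

## Determinism and problem sizes

Every stochastic component takes a seed; per-subject and per-stage seeds
are spawned from one master seed via a counter scheme, so results are
independent of execution order, and two runs with the same master seed
write byte-identical tables (asserted in the suite). Derived seeds stay
below 2^31.

The validation suite scales Monte-Carlo sizes to what the properties need:
1000 random graphs for oracle equivalence, 10,000 rewired draws for the
null-model invariants, 50 replicates × m = 200 for normalization sanity,
500 null cohorts × 500 permutations for type-I calibration, and 50
replicate cohorts (60 subjects/cell, 1000 permutations) for
planted-pattern recovery.

## Known limitations

* Plain label-permutation p-values for covariate-correlated factors are
  mildly liberal in very small cohorts (see above).
* Φnorm inherits Monte-Carlo noise at high κ where few nodes remain; the
  AUC statistic integrates over the defined range and is the quantity to
  test, not single-κ exceedances.
* The existence-test decision couples two criteria (AUC p and a Φnorm
  exceedance run), so its rejection rate on null graphs runs at or below
  the nominal α.
* No alternative null models (strength-preserving annealing, geometric
  surrogates) and no edge-level statistics are provided.
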