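# Methods

`colonynet` analyses the social structure of a group-housed mouse colony from
two delimited-text logs: an agonistic-event log (one row per interaction with
day, winner, loser, behavior, vivarium and zone) and a census log (one row
per sighting of an individual at a daily census time point). This note
documents the statistical procedures, the choices made where the methods
literature leaves room, and what the synthetic colony generator does and does
not emulate.

## Sociomatrices

Events are tabulated into a winner-by-loser **frequency sociomatrix** `M`
(`M[i, j]` = wins of `i` over `j`; the diagonal carries no data and the
entries sum to the event count). The **binary dominance matrix** `B` applies
the Appleby rule: `B[i, j] = 1` iff `i` beat `j` strictly more often than the
reverse; dyads tied on wins — including dyads that never interacted — are 0
in both directions. The **symmetric interaction matrix** `S = M + Mᵀ` counts
total interactions per pair and is the substrate of community detection.
Roster order is lexicographic by id unless an explicit roster is supplied;
all matrices carry id labels so permutation can never silently change
meaning.

The ethogram filter is configurable (`EventLog.filter_behaviors`); by
default every logged behavior with a winner/loser role (fighting, chasing,
mounting, subordinate posture, induced-flee) enters the sociomatrix.

## Hierarchy statistics

All Monte-Carlo p-values use the add-one convention
`p = (1 + #{null ≥ obs}) / (1 + n_rand)`, so `p` is never exactly zero; each
reported p carries its randomization count.

**Directional consistency (DC)** is `Σ(H − L) / Σ(H + L)` over dyads, where
`H`/`L` are the larger/smaller directed counts. Its null flips every
interaction's direction with a fair coin (equivalently, per-dyad binomial
splits), the same event-level null used for steepness.

**Linearity (Landau h, de Vries h′).** Landau's
`h = 12/(N³−N) · Σᵢ (Vᵢ − (N−1)/2)²` with `Vᵢ` the number of individuals
dominated by `i`. Dyads without a strict winner (never interacted, or tied
on wins — exactly the dyads the Appleby rule leaves undirected) carry no
direction information and are imputed with a fair coin; the reported h′ is
the exact mean of h over all such imputations, computed in closed form as h
on the 0.5-filled matrix plus `6u/(N³−N)` for `u` undirected dyads.
Significance uses the two-step randomization: each trial imputes the
undirected dyads at random and compares the resulting h against the h of a
fully random tournament of the same size; `p` is the add-one proportion of
trials in which the random tournament wins. Because the trial p averages the
null tail over imputations, the test is *deliberately conservative when
undirected relationships are common* (measured type-I error ≈ 0.02 when a
third of dyads are undirected, ≈ 0.04 when under 10% are). The calibration
suite therefore exercises it in its applicability regime (dense interaction
data, few undirected dyads).

**David's scores and steepness.** Dyadic win proportions
`Pᵢⱼ = wins_ij/(wins_ij + wins_ji)` (0 for unobserved dyads), or the
chance-corrected variant `Dᵢⱼ = Pᵢⱼ − (Pᵢⱼ − 0.5)/(nᵢⱼ + 1)` behind the
`dyadic="Dij"` flag. `DS = w + w₂ − l − l₂` with `w = ΣⱼPᵢⱼ`,
`w₂ = ΣⱼPᵢⱼwⱼ` and the loss terms symmetric;
`NormDS = (DS + N(N−1)/2)/N`. Steepness is the absolute OLS slope of
NormDS sorted descending against ranks 1..N; a perfectly despotic linear
hierarchy has steepness 1, a flat one 0. Its null is the same
direction-flip randomization as DC.

**Triangle transitivity.** Among *complete* triads (all three dyads
directed), `Pt` is the transitive fraction (a complete triad is either
transitive or a 3-cycle), computed via `trace` identities:
complete = `tr(R³)/6` on the undirected relation graph, cycles =
`tr(B³)/3`. The scaled statistic is `t.tri = 4(Pt − 0.75)`: 0 at the random
expectation (3 of 4 random orientations of a triangle are transitive), 1 at
full transitivity. The null keeps *which* dyads are related fixed and
randomizes each relation's orientation with a fair coin; the alternative of
also regenerating relation presence was rejected because the observed
sparsity pattern (who ever interacts) is not part of the hypothesis being
tested.

**I&SI ranking** minimizes lexicographically the pair (I, SI): the number of
dyads whose direction contradicts the order, and the total rank distance of
those dyads. The search starts from the descending David's-score order and
sweeps all position pairs, accepting any swap that strictly improves,
with random-permutation restarts (default 20); the result can never be worse
than its David's-score start, and matches exhaustive search over all
orderings on every random matrix up to N = 6 that the test suite throws at
it. Ties in David's score break by roster order, so the result is
deterministic given the seed.

## Network metrics

The dominance network is `B` as a directed graph (edge `i→j` = `i` dominates
`j`).

* **Density** = edges / N(N−1).
* **Average path length**: mean directed geodesic over ordered pairs, with
  unreachable pairs assigned the maximum finite geodesic (the diameter).
* **Closeness**: `(N−1)/Σⱼδ(i,j)` with unreachable targets at distance N
  (the convention of the classical sna software family). The two
  unreachable-handling conventions intentionally differ and are both
  documented because they serve different statistics.
* **Freeman centralizations**: degree centralization normalizes
  `Σ(c_max − cᵢ)` by the directed-star maximum `(N−1)²`; closeness
  centralization by the same sum evaluated on a directed out-star under the
  identical unreachable convention, `(N−1)²/N`.
* **Kleinberg hub score**: principal eigenvector of `A·Aᵀ` by power
  iteration from a uniform start, scaled to maximum 1 for cross-network
  comparability (not unit norm). With a degenerate leading eigenvalue the
  iteration returns the projection of the uniform start onto the leading
  eigenspace — the HITS limit.
* **Degree assortativity**: Newman's edge-wise Pearson correlation between
  source and target degrees of the chosen mode. "Randomizing the degree
  distribution" is ambiguous, so the default null redraws the same number of
  edges uniformly at random (fixed N and edge count); a degree-label
  permutation null is available behind `null="permute"`.
* **Extreme-degree test**: per replicate, `n_random` directed Bernoulli
  graphs with the observed N and density; `p_max` = add-one proportion whose
  maximum out-degree reaches the observed maximum, `p_min` analogous for
  minimum in-degree; mean ± SD over replicates is reported. Because the
  statistic is integer-valued, the achievable significance levels are a
  discrete set and the test is conservative between them — e.g. at the
  calibration suite's density the tail steps from 0.115 to 0.029 across one
  degree unit, so a nominal α = 0.05 realizes ≈ 0.03. This is a property of
  any tail test on a discrete extreme statistic, not an artifact.
* **Spearman correlation panel** across node measures (and any user-supplied
  per-individual covariates such as body mass or relative gene expression),
  Holm-adjusted; constant columns are flagged and excluded.

## Communities

Girvan–Newman on `S`: repeatedly remove the highest-scoring edge, re-score,
and evaluate weighted modularity
`Q = (1/2m) Σ [Aᵢⱼ − kᵢkⱼ/2m] δ(cᵢ,cⱼ)` at every stage of the removal
sequence (partitions = connected components); the partition maximizing Q is
returned. The default edge score is Newman's weighted rule — shortest-path
edge betweenness divided by edge weight — so that weak ties carrying much
traffic (community boundaries) go first. A pure 1/weight-length betweenness
variant and an unweighted variant are available behind the `betweenness`
flag; in colonies with many weak cross-community ties the length-based
variant fails structurally (the removal sequence never isolates the
communities because the many parallel weak bridges split the traffic), which
is why it is not the default. Equal scores break toward the smallest
(row, column) pair, making the dendrogram deterministic. The output is
invariant under uniform rescaling of all weights.

**Bootstrap comembership**: resample the raw events with replacement to the
original count (the observation is the resampling unit), rebuild `S`, rerun
Girvan–Newman; the comembership matrix holds the proportion of replicates
placing each pair in the same community (individuals isolated in a replicate
co-occur with nobody; diagonal 1). **Consensus communities** run
Girvan–Newman on the weighted comembership matrix itself; an individual
whose mean comembership with the members of every detected community falls
below `assign_threshold` (default 0.5, configurable and reported) is
labelled *unassigned*. The threshold rule is this package's
operationalization of "could not be placed in either community"; weighted
(not binarized) comembership ties are used in the consensus step.

## Association

From each census period the dyadic counts x (both seen, same vivarium), yAB
(both seen, different vivaria), yA/yB (only one seen) feed the half-weight
index `HWI = x/(x + yAB + 0.5(yA + yB))` in [0, 1]. Mice unseen in a period
contribute to no count — the half-weight denominator is precisely the
correction for partial observability. Association is defined at the vivarium
level; the finer zone labels are retained in the event log but not used by
the spatial statistics.

The **Mantel test** correlates off-diagonal upper triangles (Pearson by
default, Spearman behind a flag), permuting rows and columns of the second
matrix jointly; two-sided add-one p on |r|; 1000 permutations by default.
The **within/between contrast** compares the median within-community HWI to
the median between-community HWI, with a label-permutation null over the
assigned individuals (unassigned individuals excluded).

## Spatial analyses

Per-individual, per-vivarium counts of aggression given (wins) and received
(losses) must marginally agree with the sociomatrix row/column sums (checked
in tests). **Shannon's evenness** `J = H/ln K` with `H = −Σ pₖ ln pₖ` over
the K = 4 vivaria; `J = 1` for uniform use, 0 for single-vivarium
concentration. The per-individual **unevenness test** is this package's
operationalization (the choice of null was open): the same total thrown
uniformly over vivaria, one-sided toward low evenness, add-one p; a single
event yields p = 1 by construction.

**Usage distances** between individuals' per-vivarium total-activity
profiles default to Bray–Curtis (the standard for count compositions in
community-ecology software; Euclidean behind a flag); all-zero individuals
are excluded with a warning. **nMDS** minimizes Kruskal stress-1 by
non-metric SMACOF (iterative majorization with isotonic regression of
configuration distances on dissimilarity ranks), initialized from classical
metric scaling plus seed-controlled random restarts (default 20); the best
configuration is returned centered at the origin.

## Synthetic colony generator

There is no public raw dataset for this kind of study, so the generator
plants the structure the analyses assume and the test suite verifies that
the pipeline recovers it:

* **Dominance**: latent scores evenly spaced with spacing `sigma_d`
  (default 1.0) between adjacent ranks; contests resolve by the
  Bradley–Terry rule `P(i beats j) = 1/(1 + exp(−β(dᵢ − dⱼ)))` with
  steepness `β` (default 3). This is the simplest latent-score model
  consistent with a steep near-linear hierarchy. `sigma_d` is parameterized
  as adjacent-rank spacing (not total range) so that `β ≥ 10` drives
  adjacent win probabilities to ~1 and produces a fully transitive binary
  matrix, the regime a despotic colony approaches.
* **Communities**: sizes default to 19 + 8 + 3 "floaters"; community
  membership is shuffled independently of dominance rank; dyads are drawn
  with weight `w` (default 5) if both members share a community, else 1.
* **Space**: community A holds vivaria {1, 2}, B holds {3, 4}; events and
  census sightings fall in the home territory with fidelity `φ`
  (default 0.9), floaters split evenly between territories. Each individual
  is sighted per census with probability 0.8, a realistic detectability for
  visual censusing of a structured enclosure.
* **Scale**: 30 mice, 1230 events over 19 days, 3 census time points per
  day — the size of colony study the package targets.
* `null_colony` removes every structure (uniform dyads, fair-coin winners,
  uniform locations) and is the calibration input for all randomization
  tests.

What the generator does **not** emulate: temporal hierarchy formation and
rank reversals, wounding-driven removal, huddling or affiliative behavior,
observation effort varying by day, or zone-level microstructure. Passing
recovery tests therefore show that the pipeline inverts this generative
model at realistic size and noise — not that it is robust to every
real-world complication.

## Problem sizes and numerical choices

The test suite exercises the pipeline at the sizes the methods target:
recovery experiments use 20 colonies of 30 mice and 1230 events with 50
bootstrap replicates; null calibration uses 500 structureless colonies of
20 mice and 800 events with 199 randomizations per test (the linearity test
uses denser 16-mouse, 4000-event colonies, for the reason given above);
exhaustive oracles run at N ≤ 6 (orderings), 8 nodes (partitions), and 2¹²
graphs. Defaults in the API are the full-strength values (10,000
randomizations; 1000 bootstrap and Mantel replicates; 20 restarts).

Numerical details: modularity and David's-score identities are checked to
1e−12; hub-score power iteration tolerance 1e−12 with a 1000-step cap;
nMDS convergence tolerance 1e−7 with 500-iteration cap; evenness tie
comparison uses a 1e−12 tolerance so float-path differences cannot flip tie
counting; equal edge-betweenness breaks toward the smallest labelled pair.
Degenerate inputs (all-zero matrices, graphs without complete triads,
constant matrices, rosters below the minimum N) raise `ValidationError`
with a reason, and the pipeline reports such stages as "not computed" rather
than aborting the run.

## Known limitations

* The h′ two-step test loses power (and is conservative) when many dyads
  lack a strict winner; with very sparse observation the index itself is
  mostly imputation.
* Girvan–Newman is O(E²·V) per bootstrap replicate; for colonies much
  larger than ~50 individuals the bootstrap dominates runtime.
* The unevenness null assumes equal availability of all four vivaria; if
  enclosure geometry makes some vivaria intrinsically busier, the test
  conflates preference with availability.
* The consensus unassignment threshold is a package choice; reported
  community sizes near the threshold should be read together with the
  comembership matrix.
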