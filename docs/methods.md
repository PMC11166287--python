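# Methods

## Model and assumptions

The package infers a Boolean network — per-gene logic rules over named
regulators, updated synchronously — from continuous expression time series
and prior topological knowledge. The central assumption is that the
influence graph of a real regulatory system resembles related, already
characterized networks in its aggregate topology even when the specific
edges differ: similar sparsity, a heavy-tailed out-degree profile with hub
regulators, restricted in-degree, and a similar spectrum of three-node
motifs. The search therefore optimizes two objectives at once: compliance
with a data-driven ranking of candidate regulations, and similarity of
four topological statistics to expectations extracted from reference
networks. Neither objective is reduced to the other; NSGA-II maintains the
whole Pareto front and the final choice is made by dynamic accuracy on the
binarized data.

Candidate networks forbid self-loops: autoregulation is not representable
in the genotype, and rank matrices correspondingly order the n(n−1)
non-self pairs. Network density is nevertheless defined as |E|/n² (edge
probability over all ordered pairs including the diagonal), so the density
prior extracted from references that may contain self-edges remains
comparable; this convention is fixed throughout and documented here
because the alternative n(n−1) denominator is equally defensible.

## Topology features and the triad census

Four features describe a network: density; in-degree histogram over bins
0..10 (the in-degree is hard-capped at 10 regulators); out-degree
histogram over bins 0..10 with all larger degrees folded into bin 10; and
the census of *connected* triads — the 13 of the 16 three-node isomorphism
classes whose undirected projection is connected (the 003/012/102 classes
are excluded) — normalized to a probability vector. A network with no
connected triads gets the all-zero census vector, which makes the
census-overlap loss evaluate to 1 against any reference: triad-free
candidates are maximally penalized rather than causing a 0/0.

The census is computed by traversing every connected triple of the
undirected projection exactly once (ordering guards on node indices, which
requires only that node indices are totally ordered) and classifying each
triple by its 6-bit edge code through the standard 64→16 lookup. The
lookup table is validated in the test suite by brute-force isomorphism
classification of all 64 labelled 3-node digraphs, which also confirms the
taxonomy: 16 classes, 36 vertex orbits in total.

Alongside the census, an n×n×16 contribution table records, for each
counted triad, a credit to each of its three node pairs. After a
single-edge mutation only triads containing both endpoints can change, so
the census delta is the difference between local triad counts after and
before the toggle — an O(Δ) neighbourhood scan. One subtlety is load-
bearing: the changed triads also alter the credits stored for the *third*
pairs (v,w) and (u,w), not only for the mutated pair (v,u). The update
therefore reconciles those entries per third node using the before/after
local classifications; without this, contribution tables go stale and the
census delta of a later mutation touching those pairs would be wrong. The
invariants — incremental census equals a from-scratch recount after
arbitrary mutation sequences, contribution table sums to three times the
census, all entries non-negative — are enforced by randomized oracle tests.

## Objectives

Rank loss: z₁ = (Σ_{e∈E} rank(e)) / (1+2+⋯+|E|) − (Σ_{m∈E^C} rank(m)) /
(sum of the |E^C| largest ranks). The first term is ≥ 1, the second ≤ 1,
so z₁ ≥ 0 with equality exactly when the edges hold the top-|E| ranks.
Degenerate cases are defined by continuity: the edge term is 0 when
|E| = 0 and the non-edge term is 1 when |E^C| = 0. Ranks are dense
(1..n(n−1)); ties among raw weights break by (weight descending, source
index, target index), which makes the conversion deterministic and
invariant under positive affine transformations of the weights.

Topological loss: z₂ = α₁L₁ + α₂L₂ + α₃L₃ + α₄L₄ with L₁/L₂/L₃ the
histogram-overlap losses 1 − Σᵢ min(x̂ᵢ, xᵢ) on out-degree, in-degree and
normalized census, and L₄ the V-shaped density loss |x−x̂|/x below the
expectation and |x−x̂|/(1−x) above it. For sparse expectations (x < ½) the
right branch is flatter, deliberately tolerating networks slightly denser
than expected — extra candidate regulators cost little and can be pruned
by the rule-minimization stage. Default weights (0.285, 0.0604, 0.7872,
0.3377) are the tuned values shipped as configuration; their sum, 1.4703,
bounds z₂. Reference features are averaged per network on the probability
scale (each reference contributes equally regardless of size); pooled
counting would overweight large references and is not what "expected
distribution" means here.

## Evolutionary search

Canonical NSGA-II: fast non-dominated sorting, crowding distance with
infinite distance at front boundaries, binary tournament by (front rank,
crowding), and elitist (μ+λ) truncation. Crossover exchanges the regulator
columns of a uniformly random nonempty proper subset of genes (each column
independently with probability ½, resampled at the boundaries); children's
features are recomputed from scratch. Mutation toggles one uniformly drawn
edge (add or remove with equal probability); an addition that would exceed
the in-degree cap is reverted, leaving the individual unchanged, and a
removal on an edgeless network is a no-op. Per-individual application
probabilities default to 0.9 (crossover) and 1.0 (mutation); these two
numbers are package defaults, exposed in `GAConfig`, not externally
validated values.

Single-edge mutation is a deliberate design: a bitwise flip operator with
per-entry probability p obeys a_k = a_{k−1}(1−2p) + pn² and drives every
network toward density ½ regardless of p or the start, destroying
sparsity, while a toggle moves the density by at most 1/n² per step. The
recurrence and its limit are kept as a tested property.

Initial populations come in three modes. *density*: the
round(expected_density·n(n−1)) best-ranked pairs form a shared base
network (skipping pairs that would break the in-degree cap), and each
subject is diversified by 0–5 random toggles. *indegree*: each gene
independently draws its regulator count from the expected in-degree
histogram and keeps its best-ranked regulators. *reference_exact*:
subjects are copies of name-matched references, diversified to fill the
population; gene names must match exactly and mismatches are reported by
name.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; per-target ranking models derive seeds as
seed + gene index (mod 2³¹), so runs are bit-reproducible.

## Regulator ranking

For each target, a 100-tree random forest with √p feature subsampling
regresses (x_j(t+Δt) − x_j(t))/Δt + α_d·x_j(t) (decay α_d = 0.02 per unit
time) on all other genes at the previous time point, stacking transitions
from all series. Feature importances become the weight of each candidate
regulation. These defaults are desk-scale choices in the spirit of
tree-ensemble network inference on time series; results are reproducible
at the interface level (a ranking is a ranking), not at the level of any
particular external implementation, and a precomputed weight matrix can be
supplied to bypass the internal ranker entirely.

## Binarization and rule inference

Each gene is binarized by exact 1-D two-means on its pooled values: every
contiguous split of the sorted values is scored by within-cluster sum of
squares via prefix sums and the optimal split is taken directly. This
replaces iterative/restarted k-means refinements with the global optimum
those refinements approximate — deterministic, free of restart parameters,
and invariant under increasing affine transformations of the data. The
higher-mean cluster maps to 1; constant genes binarize to all zeros with a
warning, and per-gene thresholds are retained for audit and for
binarizing held-out series with the training cuts.

Generalized truth tables collect one-step transitions within each series
(never across series seams: consecutive rows of different experiments are
not transitions). Conflicting observations of the same input row —
inevitable after binarization — resolve by majority with ties going to 1;
the raw tallies are kept. Unobserved rows are don't-cares.

Quine–McCluskey minimization is implemented in-package: prime implicants
by iterative merging of (bits, mask) terms, essential-prime extraction,
then an exact minimum cover by branch-and-bound when at most 16 candidate
primes remain and a deterministic greedy cover otherwise. Empty tables
yield the constant 0; tables whose cover collapses to a full wildcard
yield the constant 1. With the 10-regulator cap the 2^r row space stays
tractable. Correctness is checked exhaustively over all fully specified
tables with up to 4 inputs and on random 6-input tables with don't-cares.

## Final selection

Rules are inferred for *every* first-front candidate (the ideal-point
tie-break needs front-wide normalization anyway). Dynamic accuracy is
per-gene-per-transition: each rule predicts its gene's state at t+1 from
the observed full state at t, over all transitions of all series; the
per-state-vector alternative (all genes correct simultaneously) is
stricter but conflates single-gene errors with whole-state errors, and the
per-gene form is the one implemented and reported. The candidate with the
highest dynamic accuracy is selected; ties break by the smallest Euclidean
distance to the origin after min-max normalizing each objective over the
front (a degenerate axis, zmax = zmin, contributes 0). Constant rules in
the winner are replaced by the corresponding rule of the candidate nearest
the ideal point when that rule is non-constant; the replacement may
reference regulators outside the winner's influence graph, which is
accepted as inherited from the donor and logged.

## Synthetic benchmarks

The generator emulates in-silico benchmark data: out-degree propensities
follow a truncated power law (default exponent 2.5), per-gene in-degrees a
truncated geometric capped at the regulator limit (resampled until the
edge total is within 10% of target), random non-constant rules are drawn
until they depend on every declared parent (DNF family by default, a
signed-threshold family as an alternative), and continuous trajectories
map Boolean states to 0.1/0.9 plus Gaussian noise (default sd 0.05),
clipped to [0, 1]. Defaults are 10 series × 56 steps, mirroring the shape
of the standard in-silico compendia. What this does *not* emulate: ODE- or
SDE-based transcription kinetics, intermediate expression levels,
measurement dropout, or unmodelled latent regulators. Passing the recovery
benchmark therefore shows the machinery is sound end-to-end on data whose
generating process matches the model class; it does not certify accuracy
on biological measurements, where binarization loss and model mismatch
dominate.

The packaged recovery benchmark uses 16 genes, in-degree ≤ 3, 10 series of
56 steps, noise sd 0.05, three independently generated reference networks,
population 200 and 10 generations over 10 seeds — sizes chosen so a full
repetition runs in seconds on one CPU while leaving the per-seed search
non-trivial. It reports median held-out dynamic accuracy, median MCC of
the inferred influence graph against the truth, and whether the best
topological loss on the first front is non-increasing across generations
(it must be, under elitist selection with a static objective).

## Numerical and degenerate-input conventions

- Census normalization: all-zero vector when no connected triads exist.
- Rank loss: edge term 0 when |E| = 0; non-edge term 1 when |E^C| = 0.
- Density loss requires the expected density strictly inside (0, 1);
  a reference set with density 0 or 1 is rejected rather than guessed at.
- Metrics with zero denominators (e.g. precision with no predicted edges)
  return 0 and set a degeneracy flag.
- Truth-table conflict ties resolve to 1.
- Crowding distance: fronts of size ≤ 2 are all-infinite; degenerate
  objective spans contribute 0.
- All tolerances in tests are absolute 1e-9 for probability-vector sums
  and exact integer equality for censuses.

## Known limitations

- The regulator ranking is interface-compatible with, but not numerically
  identical to, any specific published tree-ensemble implementation.
- Reference feature aggregation is per-network averaging; pooled-count
  aggregation would weight references by size and is not offered.
- Synchronous-update semantics only; no attractor or perturbation
  analysis.
- The search evaluates z₁ from scratch per candidate (O(n²)); for very
  large n an incremental rank-sum update would be the next optimization.
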