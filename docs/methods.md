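# Methods

This note records the models, estimators, numerical conventions and known
limitations of `spinestats`. Everything stated here is implemented and
exercised by the test suite; no empirical claims are made beyond what the
shipped code computes.

## 1. Linear networks

A dendrite is represented as a rooted tree of straight centerline segments.
Nodes carry planar (or 3-D) coordinates; each non-root node defines the
segment from its parent, identified by the child node's id. Distances are
shortest-path along the network in μm. Structural validation enforces a
single root, |V| − 1 edges, and connectivity; centrifugal branch order
starts at 1 on the root segment and increments only where a node has two or
more children.

Two geometric primitives drive the spatial statistics, both computed exactly
in O(E) per query from per-segment arithmetic rather than by discretization:

- **Ball length** ℓ(u, t): total network length within distance t of point
  u. Per edge (a, b) of length L with endpoint distances dₐ, d_b from u, the
  covered length is min(L, clip(t − dₐ) + clip(t − d_b)); the segment hosting
  u is handled as two arms.
- **Circle count** m(u, r): the number of network points at distance exactly
  r from u, obtained from the piecewise-linear "tent" profile of distance
  along each edge (one crossing per strictly monotone piece, tangency at the
  interior maximum, and degree − 1 continuations when r lands exactly on a
  node; tips contribute 0).

Tests validate both against brute-force discretization oracles and the
derivative identity dℓ/dt = m.

## 2. K-functions on a network

For a pattern of N spines on a network of total length ℓ_T:

- **Geometrically corrected estimator** (the default):
  K̂(t) = ℓ_T / (N(N−1)) · Σ_{i≠j} 1[d_ij ≤ t] / m(i, d_ij),
  where m(i, d_ij) is the circle count at the *i*-th point for radius d_ij.
  Under CSR its expectation is K(t) = t regardless of network geometry, so a
  single 45° line is the null reference for every dendrite.
- **Uncorrected (classical) estimator**:
  K̂(t) = ℓ_T / N² · Σ_{i≠j} 1[d_ij < t], whose CSR expectation depends on
  the geometry: K(t) = (1/ℓ_T) ∫ ℓ(p, t) dp, integrated numerically over
  segment midpoints at a configurable step (0.01 μm reproduces the interval
  closed form 2t − t²/ℓ to 0.1 μm). The two variants deliberately keep their
  distinct normalizations (1/(N(N−1)) with ≤ versus 1/N² with <) rather than
  being unified.

**Tip clamp.** When a pattern point sits exactly on a tip at distance d_ij
from point i, the exact circle count at that radius is 0 under the tip
convention even though a point of the pattern *is* there. The pair weight
uses m = max(count, 1) so such pairs count fully instead of dividing by
zero. This only triggers for events of measure zero under CSR but occurs
for constructed or walk-generated patterns that stop at tips.

**t-grid.** The default grid spans 0 to min(0.98-quantile of observed
pairwise distances, ℓ_T/2) with 512 points; all analyses accept an explicit
grid.

## 3. Monte-Carlo CSR inference

The test statistic is the maximum absolute deviation
d = max_t |K(t) − K̂(t)| over the grid (ties in the argmax resolve to the
first grid point attaining the maximum). The null distribution is obtained
by re-placing the observed N spines uniformly by arc length on the same
network; the p-value is the standard conservative Monte-Carlo count
(1 + #{dᵢ ≥ d_obs}) / (nsim + 1). Pointwise envelopes use the ⌈α·nsim⌉-th
smallest/largest simulated K value per t; they control only the per-t
(marginal) error rate, not whole-curve coverage.

**Q-Q diagnostic.** The CDF of soma distance under CSR is exact and
piecewise linear: F(s) = Σ_segments clip(s − depth(parent), 0, L) / ℓ_T.
Observed order statistics at plotting positions (i − ½)/N are plotted
against F⁻¹ of those positions. This is graphical only; no p-value is
attached.

**False-discovery control.** Across dendrites, p-values are pooled into
Storey q-values: π₀(λ) = #{p > λ}/(m(1 − λ)) over λ = 0.05, 0.10, …, 0.95,
smoothed by a cubic polynomial fit and evaluated at the largest λ (the same
flexibility as the reference implementation's df = 3 smoothing spline),
clipped to (0, 1]; step-down q-values follow. Benjamini–Hochberg is
available as `method="bh"` (π₀ = 1). With Monte-Carlo p-values the q-value
granularity is 1/(nsim + 1), so nsim ≥ 99 is needed to resolve q < 0.05.

## 4. Categorical models

Spine attributes are binned: DIV ∈ {7, 14, 21}; type ∈ {mushroom, stubby,
thin}; branch order 1–4 with ≥ 5 pooled ("5+"); soma distance cut at
quartile breaks (pooled empirical quartiles by default, or the published
breaks 65.65 / 108.99 / 157.04 μm from `presets`). Bins are right-closed: a
value equal to a break falls in the lower bin.

The cross-classified counts are modelled by Poisson log-linear GLMs
(treatment coding). AIC = 2k − 2 log L with k the number of estimated
coefficients. Model selection is forward stepwise from the all-main-effects
(mutual independence) baseline — the standard starting point for
contingency-table analysis, which also avoids hierarchy deadlocks when an
association has uniform margins — adding the interaction with the largest
AIC decrease until none helps; only hierarchical models are considered. The
drop-one table refits the final model without each removable term and
reports df, deviance and AIC, ranking retained terms by their cost of
omission. Two-way independence screens use Pearson chi-square without
continuity correction.

## 5. Neighbor-type MLR

For each spine, the predictor vector X has 7 entries: the types of its three
nearest neighbors by network distance (ties broken by spine index), each
dummy-coded on two indicators — mushroom (1,0), stubby (0,1), thin (0,0) —
plus DIV as a numeric value. Spines on dendrites with fewer than three other
spines are excluded (counted and logged). The response is the spine's own
type with mushroom as the reference category:

log P(stubby)/P(mushroom) = β₁·(1, X),  log P(thin)/P(mushroom) = β₂·(1, X).

Fitting uses maximum likelihood (quasi-Newton); the problem is convex so the
estimate is deterministic given the data. Balanced samples draw equal
per-type counts among spines at least a margin (default 10 μm) from the
image border. The "Bayes factor" for type i at neighborhood X is
P(Y=i|X)/P(Y=i) with the prior taken from the experiment's full spine
population; values above 1 mean the neighborhood is informative. With small
balanced samples the Hessian can be singular (quasi-separation); the point
estimate is returned with a warning and no standard errors.

`presets.MLR_COEFFICIENTS` carries the published per-experiment coefficient
tables (printed at 2 decimals); forward computation from them reproduces the
published prediction probabilities (e.g. 0.45 for an all-mushroom DIV-7
neighborhood in experiment 1) and the mushroom Bayes factor 1.02.

## 6. Synthetic generator: scope and defaults

The generator provides *study conditions*, not fitted reconstructions:

- **Trees**: at each segment end, bifurcate with probability 0.7 until
  centrifugal order 5, else terminate; lognormal segment lengths with median
  30 μm and σ = 0.45 (log scale); random planar turn angles for plotting
  only — the statistics use arc length, not coordinates.
- **Placement**: `csr` (Poisson(λ·ℓ_T) uniform by arc length; default
  densities by DIV: 0.25, 0.45, 0.65 spines/μm for DIV 7/14/21), `cluster`
  (network Neyman–Scott: CSR parents at 0.02/μm, Poisson(8) offspring
  displaced by half-normal network distances of scale 2 μm via a random walk
  that stops at tips), and `hardcore` (CSR thinned sequentially to a 2 μm
  minimum gap).
- **Types**: i.i.d. draws at proportions (0.39, 0.44, 0.17), or a Markov
  chain along the depth-first arc-length order that copies the previous type
  with probability ρ and draws from the base proportions otherwise (long-run
  marginals equal the base proportions).

Everything is seeded through a `numpy.random.Generator`; fixtures are
written as SWC + CSV with a JSON manifest and regenerate byte-identically
from the manifest's seed.

## 7. Validation problem sizes

The stochastic validation suite runs at sizes chosen for desk-scale
determinism (all seeded):

- test size: 100 CSR dendrites (trees with 20 μm median segments, order ≤ 4,
  density 0.4/μm), 200 null simulations each; rejections at 5% compared to
  the exact binomial 99% interval.
- power: 20 clustered dendrites (parameters above), 99 simulations each,
  requiring ≥ 50% rejections.
- estimator bias: 500 CSR simulations of 30 points on one fixed tree, mean
  K̂ within 3 Monte-Carlo standard errors of t.
- q-value null: 3 seeded runs of 485 small CSR dendrites at 99 simulations
  each; the median number of q < 0.05 discoveries must be 0.

## 8. Limitations

- The network model is a tree; reconstructions with anastomoses (loops) are
  rejected rather than supported.
- The uncorrected theoretical K uses numerical integration over segment
  midpoints; accuracy is controlled by the step parameter, with no closed
  form on general trees.
- Envelopes are pointwise, not simultaneous; use the MAD Monte-Carlo p-value
  for formal testing.
- The π₀ smoother is a cubic polynomial over the λ grid, not a smoothing
  spline; on small batches of discrete Monte-Carlo p-values π₀ is clipped
  rather than estimated finely.
- Published coefficient presets are printed at 2 decimals, so forward
  computations from them carry that rounding; only rounding-stable reference
  cells are asserted exactly.
- The synthetic generator does not model spine-size marks, 3-D tortuosity,
  or between-neuron heterogeneity beyond the DIV density schedule.
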