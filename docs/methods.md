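# Methods

`islandpcm` implements the comparative-methods battery used to ask whether
island lineages evolve phenotypes faster, and into wider morphospaces, than
their continental relatives. This note records the models, the numerical
choices, and what the synthetic data do and do not establish.

## Trait models

Traits are continuous (log10-transformed measurements: snout-vent length
`svl` and head length/width/depth `hl`, `hw`, `hd`). Three Gaussian process
models run on a rooted ultrametric phylogeny with branch lengths in
arbitrary time units:

- **BM1** — single-rate Brownian motion. Tip values are multivariate normal
  with mean `z0 * 1` (the root state) and covariance `sigma2 * C`, where
  `C[i, j]` is the height of the most recent common ancestor of tips i and
  j. ML estimates are closed-form GLS: `z0 = (1'C^-1 x)/(1'C^-1 1)`,
  `sigma2 = (x - z0)'C^-1 (x - z0)/n`. An (n-1)-denominator REML rate is
  available (`denom='reml'`); ML is the default and is what every
  simulation-null test uses for its empirical rate.
- **BMS** — multi-rate Brownian motion over a *regime painting*: every
  instant of every branch is assigned to a regime (continent / Socotra /
  AbdAlKuri), and the covariance becomes `sum_r sigma2_r V_r`, with `V_r`
  the per-regime shared-time matrices (they partition `C` exactly). One rate
  and the root are profiled out analytically; the remaining R-1 log rate
  ratios are optimized by L-BFGS-B from three starts (equal rates, x0.1,
  x10). Starting at equal rates makes `logL(BMS) >= logL(BM1)` by
  construction, which the suite asserts.
- **OU1** — single-optimum Ornstein-Uhlenbeck with stationary root:
  `V[i, j] = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))`
  with `d_ij` the patristic distance and `t_ij` the shared time. Requires an
  ultrametric tree (relative tolerance 1e-6 of depth). `theta` and `sigma2`
  are profiled; `alpha` is optimized on a 25-point log grid over
  `[1e-8, 50/depth]` refined by bounded scalar minimization; a fit with
  `alpha` within 1% of the upper bound is flagged `alpha_at_bound`. As
  `alpha -> 0` the covariance tends to BM1's, which the suite verifies at
  `alpha = 1e-8`.

Model comparison uses AICc = `-2 logL + 2k + 2k(k+1)/(n-k-1)` with k = 2
(BM1), 1+R (BMS: R rates + root), 3 (OU1). These k values are a package
convention; they matter only through differences, and all three models are
fitted by full ML on the same data. Fit records report `aicc = NaN` when
`n <= k+1` rather than failing, so toy examples remain fittable.

All Gaussian likelihoods use a Cholesky factorization; if it fails, a single
diagonal jitter of `1e-10 * max(diag)` is added, after which the covariance
is declared singular. Zero-length terminal branches are permitted; contrast
standardization never adds an epsilon — a zero pooled branch length raises.

## Independent contrasts

Felsenstein pruning: contrast `(x_i - x_j)/sqrt(v_i + v_j)` at each internal
node, parent value the inverse-variance weighted mean, parent branch
augmented by `v_i v_j/(v_i + v_j)`. Signs follow the tree's child order. The
sum of squared contrasts equals the GLS quadratic form, so the mean squared
contrast is the REML rate and `ML = REML * (n-1)/n` exactly — asserted on
random trees. The contrasts-through-time envelope simulates single-rate BM
at the ML rate of the observed trait and flags nodes whose |contrast|
exceeds the pointwise 97.5% null quantile (contrasts map one-to-one to nodes
on a fixed tree; a pooled-across-nodes band is available via
`envelope='pooled'`). Under the null roughly 2.5% of nodes flag, which sits
inside the 5% +/- 3% coverage band the acceptance suite checks.

## Discrete characters and stochastic mapping

Island occupancy evolves under a continuous-time Markov chain (Mk). The
likelihood is Felsenstein pruning with `P(t) = expm(Q t)` per branch
(eigendecomposition with an `expm` fallback for ill-conditioned
eigenvectors). `fit_mk` supports ER/SYM/ARD rate structures, optimizing log
rates by bounded L-BFGS-B from three starts around `1/depth`; rates pinned
at the box bounds are flagged. The root prior defaults to the stationary
distribution of Q (uniform switchable). ARD is fitted as specified even
though it is generally non-reversible.

Stochastic maps are drawn exactly: node states by backward pruning / forward
sampling from the joint conditional distribution, then branch interiors by
endpoint-conditioned uniformization (dominating rate = max |Q_ii|, jump
count capped at 10,000). Sampled histories always hit the observed tip
states; node-state frequencies across maps reproduce the pruning-computed
marginal posteriors (oracle test, +/-0.05 at 1,000 maps).

## Simulation-null tests

All Monte-Carlo p-values use the add-one convention
`p = (1 + #extreme)/(1 + n_sims)`, so p is never 0 and floors at
`1/(n_sims+1)`. Group labels are held fixed across null simulations; traits
are re-simulated, never permuted.

- **Phylogenetic ANOVA / MANOVA** — observed F (or Wilks' lambda =
  det(W)/det(W+B); small lambda is extreme, lower tail) against nulls from
  BM simulations at the ML rate (univariate) or ML evolutionary
  rate matrix `R = (X - 1 mu')'C^-1(X - 1 mu')/n` (multivariate).
- **Disparity ratio** — disparity is the mean squared Euclidean distance
  over all unordered species pairs in a group (computed via the centered
  sum-of-squares identity, verified against the brute-force pairwise loop).
  The island/continent ratio is compared to ratios recomputed on BM
  simulations; a zero continental disparity is an error, not an infinity.
  Multivariate disparity uses the three size-corrected head residuals
  jointly as coordinates.
- **Pseudo-communities** — island per-trait ranges against random
  continental subsets of the same size, drawn without replacement. When
  `C(n, k) <= n_resamples` the enumeration is exhaustive and the p-value the
  exact proportion (ties count as reached); otherwise Monte-Carlo with the
  add-one correction.
- **Parametric bootstrap (BMS vs BM1)** — statistic `logL(BMS) - logL(BM1)`,
  null from refitting both models to data simulated under the fitted BM1;
  power = fraction of datasets simulated under the fitted BMS whose
  statistic exceeds the null's empirical 95th percentile (no chi-square
  approximation anywhere). Replicates whose optimizer fails are dropped and
  counted; more than 5% failures aborts.

Size correction for head traits uses phylogenetic (GLS) regression of each
head variable on `svl`; the residuals are raw response residuals
`y - X beta_GLS`, not re-whitened, because they are consumed downstream as
species-level trait values. When a tree set is analyzed, residuals are
recomputed on every tree.

## Synthetic data and the study fixture

`yule_tree` simulates a pure-birth tree forward in time and rescales the
depth to 1, so rates are per total tree depth — the analyses are invariant
to the absolute time scale, which the source system leaves arbitrary.
`study_fixture(seed)` builds the standing test system: a 48-tip tree with a
2-tip island clade ("AbdAlKuri") and a disjoint 5-tip island clade
("Socotra"), chosen as the first clades of those sizes in postorder; a Yule
tree need not contain a 5-tip clade, so trees are redrawn deterministically
from the seeded stream until one does. Clade stems switch from continent to
island regime at mid-stem — island origins genuinely precede the crown, and
any fixed convention serves testing.

Body size evolves under BMS with rates (continent, Socotra, AbdAlKuri) =
(1, 2, 20): the 2x and 20x island accelerations are stand-in values for the
narratively reported island effects, not estimates. Head traits are rate-1
BM whose per-branch increments correlate rho = 0.8 (configurable) with the
size increments, giving size-correlated head dimensions that remain
marginally single-rate.

What the fixture does not emulate: measurement error and intraspecific
variance (species means are taken as exact), missing data patterns, tree
shape imbalance beyond Yule, and any particular absolute scale. Passing
tests therefore demonstrate correctness and calibration of the machinery,
not biological conclusions about any empirical system.

## Problem sizes

The test suite and `scripts/acceptance.py` run Monte-Carlo layers at
reduced but statistically meaningful sizes chosen as the package's test
budget: 199 internal simulations per test, 100-500 calibration trials,
199 bootstrap replicates, 200-1,000 stochastic maps. At these sizes the
type-I windows ([0.02, 0.08] at 500 trials, [0.01, 0.10] at 100) are about
+/-3 binomial standard deviations around 0.05. Users analyzing real data
should raise `n_sims`/`n_boot` to the 10,000/1,000 scale.

## Known limitations

- No multi-optimum OU (OUM/OUMV), measurement error, or phylogenetic signal
  statistics; no hidden-rate Mk models; no reversible-jump rate estimation.
- OU1 assumes a stationary root and refuses non-ultrametric trees.
- `aggregate_over_trees` summarizes numeric leaves only; per-map and
  per-node tables are reported per tree, not aggregated.
- Exhaustive pseudo-community enumeration can report p = 0 (exact); the
  Monte-Carlo path never does.
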