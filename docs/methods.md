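# Methods

## The sampler

Metropolis-coupled MCMC (MC³, parallel tempering) runs `n` chains
against the same posterior.  Chain `i` is *heated* by a temperature
scaler `beta_i`: its Metropolis–Hastings rule raises the posterior
ratio (likelihood × prior together) to the power `beta_i`, while the
proposal (Hastings) ratio enters unheated,

    R_heated = min[1, (posterior ratio)^beta_i x Hastings ratio].

Heating flattens the posterior, so hot chains cross the low-probability
valleys that trap a single chain.  Only the cold chain (`beta_1 = 1`)
samples the true posterior; the others act as a relay that ferries
distant states toward it.

Every `swap_interval` iterations (default 100) one pair of temperature
ranks is drawn — uniformly over all pairs, or over adjacent ranks in
neighbour mode — and an exchange of the two chains' states is proposed,
accepted with

    R_ij = min[1, (p_i^beta_j p_j^beta_i) / (p_i^beta_i p_j^beta_j)],

where `p_k` is the posterior of chain `k`'s state.  In log space this is
`min(0, (beta_i - beta_j)(log p_j - log p_i))`, symmetric in the pair
labels.  An accepted exchange is implemented by swapping the chains'
temperature *labels* — rank, per-temperature operator tuning, and logger
binding — rather than their states, so arbitrarily large states never
move and each log file stays at a fixed temperature.

### Temperature ladders

Both ladder schemes are generated by one non-negative scalar, so the
adaptation below only ever tunes a single number:

* incremental: `beta_i = 1 / (1 + (i - 1) dt)`;
* beta-quantile: `beta_i = 1 - F((i - 1) / n)` with `F` the Beta(1, b)
  CDF, i.e. `beta_i = (1 - (i - 1)/n)^b` in closed form (the closed form
  is exact for alpha = 1; no special functions involved).  The division
  is by `n`, so the hottest chain keeps `beta_n = (1/n)^b > 0`.

### Adaptive spacing tuning

After every proposed exchange the spacing is updated toward a target
swap-acceptance probability `p_target` (default 0.234, the classic
optimum for many Metropolis proposals):

    spacing <- max(0, spacing + (p_global - p_target) / n_exchanges)

with `p_global` the accepted fraction over **all** proposed exchanges
since the run started and `n_exchanges` their total count, so steps
shrink like 1/k and the ladder freezes asymptotically (the sampler is
not Markovian but remains ergodic).  Two guards temper the early phase:
the signed step is clamped to `max_step = 0.001`, and the update fires
only after a burn-in of 100 proposed exchanges *and* only when
`p_global` and a local acceptance `p_local` (over the last 100 proposed
exchanges) sit strictly on the same side of the target.  Ties never
fire.  The same rule, including sign convention, is applied to the
beta-quantile parameter `b` (larger `b` = hotter = lower acceptance).
The new spacing applies to all chains simultaneously, not only the
swapped pair.

Spacing exactly 0 (all chains cold) is permitted by the floor; it is not
absorbing in practice because every swap is then accepted, `p_global`
rises above any target, and the next update pushes the spacing back up.

### Reproducibility contract

One master seed spawns `n` chain streams plus a scheduler stream (pair
choice) and a swap-decision stream.  Chains therefore evolve
independently between swap points; `n = 1` coupled runs are
byte-identical to a plain-MCMC loop with the same seed; and checkpoints
(versioned JSON holding states, cached evaluations, ladder, adaptation
counters and all RNG states) resume bit-exactly: a run split in half
reproduces the unbroken run's logs.  Swap proposals are scheduled
deterministically every `swap_interval` iterations; all chains
synchronize at swap points in both swap modes (the sampled process is
the same as letting non-participating chains run ahead, and synchrony is
what makes split-run equality testable).

## Built-in targets

**Multivariate standard normal** (default `dim = 3000`, contiguous
25-coordinate block random-walk updates with per-coordinate scale
2.4/sqrt(25)).  The dimension is deliberately large: swap acceptance is
driven by the fluctuation scale of the log posterior (~sqrt(d/2) for a
Gaussian), and a textbook low-dimensional normal behaves pathologically
under tempering — with four chains and random pair selection its mean
swap acceptance cannot even reach 0.234, because non-adjacent pairs of
heated chains retain order-one acceptance at any spacing.  At d = 3000
the equilibrium spacings for target acceptances 0.468/0.234/0.117 fall
near 0.017/0.033/0.047, inside the 0.0001–0.1 bracket of initial
spacings the adaptation experiments start from, which mirrors how such
brackets are chosen around real phylogenetic posteriors.  States carry a
cached sum of squares so block updates evaluate in O(block).

**Island mixture**: a 1-D chain of `n_islands` narrow normal modes
(sd 0.05) at unit spacing, equal weights (mass exactly 1/n each by
symmetry), with the inter-mode log density floored `barrier_depth`
(default 25) below the peaks via a smooth log-sum-exp bridge.  Local
random-walk proposals (scale 0.1) cannot cross a 25-unit valley, so a
single chain freezes in its start island — the 1-D caricature of "tree
island" posteriors.  Chain starts are drawn uniformly over mode centres
(overdispersed), or pinned with `start_mode`.

**Phylogenetic testbed**: rooted ultrametric trees with node heights in
coalescent units, JC69 likelihood via Felsenstein pruning (uniform root
frequencies, per-node rescaling against underflow, site patterns
compressed once per alignment), a constant-size Kingman coalescent prior
on the genealogy and a log-normal(0, 1) prior on Ne.  Proposals:
nearest-neighbour interchange (rejection sentinel when the incoming
sibling violates the height constraint; log-Hastings 0), a log-uniform
multiplier scaling of all internal heights (log-Hastings
`(n - 1) log m`, the Jacobian of scaling `n - 1` heights with the
symmetric-in-log multiplier), a uniform node-height re-draw within its
bracket, and a log-uniform multiplier on Ne (log-Hastings `log m`).
Data come from the package's own simulators (Kingman genealogy + JC69
site evolution), so ground truth is always known.  A strict clock with
rate 1 and JC69 only: the testbed's job is to exercise the tempering
machinery, not substitution-model breadth.

What the synthetic targets do *not* emulate: real-data features such as
model misspecification, rate heterogeneity, partitioned alignments, or
the heavy-tailed posterior geometry of empirical datasets.  Passing
tests demonstrate the tempering and adaptation machinery behaves as
specified on posteriors of known shape; they do not certify performance
on any particular empirical dataset.

## Diagnostics

* **ESS**: `N / (1 + 2 sum rho_k)` with the autocorrelation sum
  truncated by the initial-positive-sequence rule (stop before the first
  adjacent-lag pair summing <= 0).  This differs slightly from the
  fixed-max-lag dialect of common GUI trace explorers; small numeric
  differences against those tools are expected.  Constant traces return
  a NaN sentinel; results are clipped to (0, N].
* **KS distance**: the supremum distance between two empirical CDFs,
  computed exactly over the pooled sample points; the asymptotic
  two-sample critical value `c(alpha) sqrt((n+m)/nm)` is provided for
  alpha-level comparisons.
* **Clade support**: rooted clades are descendant-taxon sets; tables map
  clade -> fraction of sampled trees containing it, and run-vs-reference
  comparison takes the maximum absolute difference over the union of
  clades (absent = 0).  Reference tables are built by concatenating
  replicate runs, with a leave-one-replicate-out option.
* Default burn-in for diagnostics: discard the first 10% of a trace (a
  documented package default; nothing in the model fixes it).

## Numerical and design choices

* All acceptance computations in log space; -inf log posteriors reject
  proposals rather than erroring (but chains must *start* in support).
* The prior is heated together with the likelihood, as the heated
  acceptance rule is written; heating only the likelihood is
  deliberately not offered.
* Equality ties in the adaptation gate do not update (the rule is
  stated with strict inequalities); `p_global` includes burn-in
  proposals; `p_local` over a partial window uses whatever exists.
* The clamp applies to the signed step before the max(0, ·) floor.
* Per-pair independent temperatures are out of scope by design: one
  scalar keeps tuning as easy as plain MCMC.
* Periodic swap scheduling (every `swap_interval`) is used; whether the
  first swap time should itself be randomly drawn is left as a
  documented ambiguity, and the scheduler draws pair choices from a
  dedicated stream either way.
* Operator auto-tuning (a minimal acceptance-window rescaler on
  proposal scales) is off by default; tuning state is carried with the
  temperature rank across swaps either way.
* Heated-chain logging is off by default; a flag enables it for
  convergence checking of the heated chains themselves.

## Problem sizes used by the shipped experiments

The acceptance-convergence experiments run 4 chains for 1e6 iterations
with a swap proposed every 100 iterations (1e4 proposed exchanges) from
initial spacings {0.0001, 0.001, 0.01, 0.1} at targets 0.234, 0.468 and
0.117.  At this scale the clamped 1/k recursion retains a small residual
transient: after a cold start far below the equilibrium spacing, the
clamp-limited climb overshoots (the local window lags by ~100
exchanges) and the subsequent 1/k recovery is slow, biasing the
cumulative acceptance a few hundredths below very low targets.  Cells of
the half-default-target family can therefore land just outside +-0.02 of
their target at 1e4 exchanges (per-seed scatter ~+-0.01 around the
bias); the transient shrinks with run length and is gone by ~1e5
exchanges.  Stationarity checks use 20
replicate 4-chain runs of 6e4 iterations on a d=100 normal; island
consistency uses 3 replicate 4-chain runs of 1e6 iterations against 4
single-chain runs of 1e5; sampler-correctness checks use prior-only
runs of 1.2–2e5 iterations and an 8-taxon, 2000-site recovery run.

## Known limitations

* Serial execution only; the design reserves room for a parallel
  backend constrained to be seed-deterministic and identical to serial
  execution, but none is shipped.
* JC69/strict-clock/constant-Ne only; no skyline or structured priors.
* The adaptation's desk-scale transient above; nothing in the update
  rule is modified to hide it.
* NEXUS parsing trusts dendropy; trees with polytomies or non-binary
  roots are rejected rather than resolved.
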