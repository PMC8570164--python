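# Methods

## The power posterior pipeline

A power posterior at inverse temperature β is the unnormalized density
f(D|θ)^β · f(θ). The pipeline samples K such distributions ("stones") with
a Metropolis–Hastings chain whose acceptance probability tempers only the
likelihood term:

    α = min(1, exp(β·(ln l′ − ln l) + (ln p′ − ln p) + ln q(θ|θ′) − ln q(θ′|θ))).

At β = 0 the likelihood difference is removed before any arithmetic, so the
chain samples the prior without ever evaluating the likelihood in the
acceptance ratio (and −∞ log-likelihoods cannot produce 0·(−∞) NaNs); at
β > 0 a −∞ proposed likelihood or prior is an immediate rejection.

One *iteration* is a sweep applying every registered move kernel once, in
registration order. This is a deliberate normalization — production MCMC
packages weight and shuffle moves — chosen because a fixed order makes runs
bit-reproducible and the parallel/sequential equivalence checkable.

Each stone runs L sweeps, records the untempered log-likelihood every T-th
sweep, and discards the first `burnin_frac` of the *recorded samples* (not
raw iterations), leaving n = (1 − burnin_frac)·L/T per stone. Defaults
L = 10,000, T = 10, 25% burn-in (n = 750) and a 10,000-sweep pre-burn-in
match common practice for these analyses. Whether the burn-in fraction
counts iterations or samples is ambiguous in the field's descriptions;
discarding recorded samples was chosen and is validated by the conjugate
recovery tests either way (the distinction only changes n).

## Schedule and blocks

Powers sit at the i/(K−1) quantiles of a beta(α, 1.0) distribution,
β_i = (i/(K−1))^(1/α), with α = 0.3 by default: the expected
log-likelihood E_β[ln l] changes fastest near the prior, so that is where
integration error concentrates and where stones are densest. Endpoints are
set exactly to 0.0 and 1.0 (no floating-point residue), and execution order
is decreasing (posterior → prior) so every stone starts from a state
adapted to a slightly sharper distribution.

For M workers the stones are cut into M consecutive blocks, block m
covering ascending indices K − ⌊(m−1)K/M⌋ − 1 down to K − ⌊mK/M⌋; uneven
divisions give some blocks one extra stone, never more than ⌈K/M⌉ total.
Consecutive blocks keep within-block transitions cheap (adjacent powers,
similar distributions) at the cost of one extra pre-burn-in per worker.
When a CPU budget is shared with likelihood-level parallelism, the default
split assigns N = ⌊√M_total⌋ CPUs to each likelihood evaluation and
⌊M_total/N⌋ workers to stone blocks; when M_total is not a perfect square
the leftover CPUs idle, keeping every likelihood evaluation identically
partitioned.

## Estimators

Both estimators consume only the K×n matrix of untempered log-likelihood
samples, re-sorted to ascending powers regardless of execution order.
Path sampling applies the trapezoidal rule to the per-stone means over
the K−1 intervals; stepping-stone computes each adjacent-power importance
ratio in max-shifted (log-sum-exp) form, which is finite for any finite
input — the naive product form is retained as `stepping_stone_naive`
purely as a cross-check oracle at test scale. Per-interval contributions
are recorded on both paths (they sum to the estimate) to support
diagnostic plots of where the integral mass sits; rows with unequal sample
counts are rejected rather than truncated, since silent truncation hides
upstream failures.

## Determinism and parallelism

The root seed s spawns one independent PCG64 stream per (worker w, phase p)
via `SeedSequence([s, w, p])`, phase 0 being the worker's pre-burn-in and
phase j its j-th stone. Per-stone streams (rather than one stream threaded
through a worker's whole block) let `resume` re-run a single failed stone
bit-exactly from its recorded seed and recorded starting state, while still
making the process backend, the in-process serial emulation, and the M=1
sequential runner produce byte-identical sample files.

Pre-burn-in runs at the *block's own first power* (β = 1 for the first
block). For workers starting at low powers this converges to the
distribution actually sampled first, which is the point of pre-burn-in;
the alternative (always β = 1) would waste the adaptation for cold blocks.

Sample files are UTF-8 TSV (`stone, power, iteration, log_likelihood`)
with 17-significant-digit floats, so doubles round-trip losslessly; files
are written once per stone-set at completion, not streamed per iteration.

## The phylogenetic model

GTR exchangeabilities (6-simplex, order AC AG AT CG CT GT) and stationary
frequencies (4-simplex) build the rate matrix q_ij = r_ij·π_j, rescaled to
one expected substitution per unit branch length. Among-site rate variation
uses the mean-of-category discretization of a gamma(shape, shape) density
cut at equal-probability boundaries (4 categories by default), the
conventional choice, renormalized to mean exactly 1. Transition matrices
come from the eigendecomposition of the reversibly symmetrized rate matrix;
tiny negative entries from rounding are clipped and rows renormalized.

The pruning likelihood computes a *per-site* vector of log-likelihood
values over compressed site patterns, with the 4-state transforms unrolled
into elementwise operations, so a pattern's value never depends on which
other patterns share the batch. Site-partitioned evaluation therefore
reassembles per-block per-site vectors in column order and applies the
same final reduction, making the N-block result bit-identical to the
single-block one — the property that lets stone-level and likelihood-level
parallelism compose without changing results. No per-node rescaling is
applied, which bounds usable tree depth/size: at the package's intended
desk scale (tens of taxa, moderate branch lengths) partial likelihoods stay
far from underflow; an underflow raises rather than returning −∞ silently.

Priors are deliberately simple and proper: iid exponential(rate 10) branch
lengths, flat Dirichlets on both simplexes, exponential(1) on the gamma
shape. Tree topology is fixed at input; topology proposals are orthogonal
to the marginal-likelihood machinery and are out of scope, as are clock
models and birth–death tree priors. Moves: a scale move per branch length
and for the gamma shape (multiplicative, Hastings term = log multiplier),
and Dirichlet-centred simplex moves (concentration 300) for the
exchangeabilities and base frequencies. Move scales are fixed — no
adaptation during sampling, which would break detailed balance.

## Validation models and what the synthetic data shows

The normal known-variance model (10 fixed observations, σ² = 1, N(0, 4)
prior on the mean) and the beta-binomial model (4 successes in 10 trials,
Beta(2, 3) prior) have closed-form marginals and closed-form power
posteriors, so the whole pipeline — schedule, tempered kernel, burn-in,
estimators — is checked against truth, not just self-consistency.

The alignment simulator draws root states from π, a rate category per
site, and evolves states down the fixed tree with exact transition
probabilities — i.e. data generated exactly under the model being fit. It
emulates sequence-length-driven information content and site-pattern
structure; it does not emulate model misspecification, alignment error,
selection heterogeneity beyond the gamma, or topology uncertainty. Passing
tests therefore demonstrate the correctness of the estimator machinery
under the model, not robustness of marginal likelihoods on real data.

## Problem sizes and numerical choices

- Conjugate recovery: K = 30, L = 2000, T = 4, 25% burn-in, pre-burn-in
  2000, 10 seeds; tolerance 0.15 log units in ≥ 9/10 seeds. Observed errors
  are typically < 0.07.
- Phylogenetic end-to-end: 5 taxa, 120 sites, K = 20, L = 240 — sized so a
  full pipeline run takes seconds while still exercising every move kernel;
  the two estimators agree within 0.5 and are stable across seeds within
  1 log unit.
- Stepping-stone stability: verified on matrices with log-likelihoods near
  −10⁵, where the naive form overflows.
- Exact oracles: pruning vs exhaustive ancestral-state enumeration on all
  3- and 4-taxon rooted topologies (1e−10); tempered-chain stationarity on
  a 3-state model by exact transition-matrix analysis (1e−10); simplex sums
  maintained to 1e−12.

## Known limitations

- No variance/standard-error estimators for the marginal-likelihood
  estimates, and no generalized stepping-stone (reference distributions).
- The likelihood has no underflow rescaling (desk-scale trees only).
- The process backend is same-machine `multiprocessing`; distributed
  (message-passing) deployment is a deliberate non-goal, as the algorithm
  needs no inter-worker communication anyway.
- `resume` restarts whole stones; there is no mid-stone checkpointing.
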