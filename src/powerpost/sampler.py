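"""Metropolis-Hastings engine for power posterior sampling.

A power posterior at inverse temperature beta is the (unnormalized) density
``likelihood(theta)**beta * prior(theta)``.  A proposal theta' from kernel q
is accepted with probability

    min(1, exp(beta*(ll' - ll) + (lp' - lp) + log q(theta|theta') - log q(theta'|theta)))

so only the likelihood term is tempered.  At beta = 0 the likelihood term is
omitted outright (prior sampling; no 0 * (-inf) arithmetic).

One *iteration* (sweep) applies every registered move once, in registration
order.  A *stone* is a run of L sweeps at a fixed beta, recording the
untempered log-likelihood every T-th sweep and discarding the first
``burnin_frac`` fraction of the recorded samples.  A *block* of stones with
decreasing powers threads the final chain state of each stone into the next,
after a single pre-burn-in phase at the block's first (highest) power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np

__all__ = [
    "ParameterState",
    "MoveKernel",
    "ModelContract",
    "StoneRunConfig",
    "StoneSamples",
    "tempered_acceptance",
    "mcmc_sweep",
    "pre_burnin",
    "run_stone",
    "run_block",
    "SlidingWindowMove",
    "ReflectedSlidingWindowMove",
    "ScaleMove",
    "DirichletSimplexMove",
]

SIMPLEX_TOL = 1e-12


@dataclass
class ParameterState:
    """A point in parameter space with lazily cached densities.

    ``values`` maps parameter names to scalars or numpy vectors (simplexes).
    The cached log-prior/log-likelihood are filled on first request and are
    always equal to a fresh evaluation for the stored values.
    """

    values: dict[str, float | np.ndarray]
    _log_prior: float | None = field(default=None, repr=False)
    _log_likelihood: float | None = field(default=None, repr=False)

    def log_prior(self, model: "ModelContract") -> float:
        if self._log_prior is None:
            self._log_prior = float(model.log_prior(self.values))
        return self._log_prior

    def log_likelihood(self, model: "ModelContract") -> float:
        if self._log_likelihood is None:
            self._log_likelihood = float(model.log_likelihood(self.values))
        return self._log_likelihood

    def with_value(self, name: str, value: float | np.ndarray) -> "ParameterState":
        new_values = dict(self.values)
        new_values[name] = value
        return ParameterState(values=new_values)


class MoveKernel(Protocol):
    """A proposal kernel acting on one named parameter.

    ``propose`` returns the proposed state and the log Hastings ratio
    ``log q(theta | theta') - log q(theta' | theta)``.
    """

    name: str
    param: str

    def propose(
        self, state: ParameterState, rng: np.random.Generator
    ) -> tuple[ParameterState, float]: ...


class ModelContract(Protocol):
    """What a target model must provide to be sampled."""

    def log_prior(self, values: dict) -> float: ...

    def log_likelihood(self, values: dict) -> float: ...

    @property
    def moves(self) -> Sequence[MoveKernel]: ...

    def initial_state(self, rng: np.random.Generator) -> ParameterState: ...


@dataclass(frozen=True)
class StoneRunConfig:
    """Per-stone run lengths and the root seed.

    L sweeps per stone, a log-likelihood sample every T-th sweep, and the
    first ``burnin_frac`` fraction of the recorded samples discarded, so
    ``n = (1 - burnin_frac) * L / T`` samples are retained per stone (750
    with the defaults L=10000, T=10, 25% burn-in).
    """

    L: int = 10_000
    T: int = 10
    burnin_frac: float = 0.25
    preburn_iters: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.T <= 0 or self.L % self.T != 0:
            raise ValueError(f"L={self.L} must be a positive multiple of T={self.T}")
        if not 0 <= self.burnin_frac < 1:
            raise ValueError(f"burnin_frac={self.burnin_frac} must be in [0, 1)")
        raw = self.L // self.T
        retained = raw - int(round(self.burnin_frac * raw))
        if retained <= 0 or not math.isclose(
            raw * (1 - self.burnin_frac), retained, abs_tol=1e-9
        ):
            raise ValueError(
                f"(1 - burnin_frac) * L / T = {(1 - self.burnin_frac) * raw} "
                "must be a positive integer"
            )
        if self.preburn_iters < 0:
            raise ValueError("preburn_iters must be >= 0")

    @property
    def n_samples(self) -> int:
        raw = self.L // self.T
        return raw - int(round(self.burnin_frac * raw))


@dataclass
class StoneSamples:
    """Retained untempered log-likelihood samples from one stone."""

    stone: int
    beta: float
    log_likelihoods: np.ndarray
    iterations: np.ndarray
    final_state: ParameterState
    acceptance_rates: dict[str, float] = field(default_factory=dict)


def tempered_acceptance(
    ll_new: float,
    ll_old: float,
    lp_new: float,
    lp_old: float,
    log_hastings: float,
    beta: float,
) -> float:
    """Acceptance probability of the tempered Metropolis-Hastings step.

    Returns ``min(1, exp(beta*(ll_new - ll_old) + (lp_new - lp_old) +
    log_hastings))``.  At beta = 0 the likelihood difference is dropped
    before any arithmetic, so -inf likelihoods are harmless there; at
    beta > 0 a -inf proposed likelihood yields probability 0.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta={beta} must lie in [0, 1]")
    if lp_new == -np.inf:
        return 0.0
    if beta == 0.0:
        log_ratio = (lp_new - lp_old) + log_hastings
    else:
        if ll_new == -np.inf:
            return 0.0
        log_ratio = beta * (ll_new - ll_old) + (lp_new - lp_old) + log_hastings
    if log_ratio >= 0.0:
        return 1.0
    return math.exp(log_ratio)


def mcmc_sweep(
    model: ModelContract,
    state: ParameterState,
    beta: float,
    rng: np.random.Generator,
    accept_counts: dict[str, list[int]] | None = None,
) -> ParameterState:
    """Apply every registered move once, in registration order."""
    for move in model.moves:
        proposed, log_hastings = move.propose(state, rng)
        lp_new = proposed.log_prior(model)
        lp_old = state.log_prior(model)
        if beta == 0.0:
            ll_new = ll_old = 0.0  # unused; the likelihood term is dropped
        else:
            if lp_new == -np.inf:
                ll_new = ll_old = 0.0  # reject on the prior alone
            else:
                ll_new = proposed.log_likelihood(model)
                ll_old = state.log_likelihood(model)
        if not (math.isfinite(lp_new) or lp_new == -np.inf):
            raise RuntimeError(f"move {move.name!r} produced an invalid state")
        alpha = tempered_acceptance(ll_new, ll_old, lp_new, lp_old, log_hastings, beta)
        accepted = alpha >= 1.0 or rng.random() < alpha
        if accepted:
            state = proposed
        if accept_counts is not None:
            counts = accept_counts.setdefault(move.name, [0, 0])
            counts[0] += int(accepted)
            counts[1] += 1
    return state


def pre_burnin(
    model: ModelContract,
    config: StoneRunConfig,
    beta_target: float,
    rng: np.random.Generator,
) -> tuple[ParameterState, dict[str, float]]:
    """Run the pre-burn-in phase at ``beta_target`` from a fresh initial state.

    Returns the final state and per-move acceptance rates.
    """
    state = model.initial_state(rng)
    counts: dict[str, list[int]] = {}
    for _ in range(config.preburn_iters):
        state = mcmc_sweep(model, state, beta_target, rng, counts)
    rates = {name: (a / t if t else float("nan")) for name, (a, t) in counts.items()}
    return state, rates


def run_stone(
    model: ModelContract,
    beta: float,
    init_state: ParameterState,
    config: StoneRunConfig,
    rng: np.random.Generator,
    stone: int = 0,
) -> StoneSamples:
    """Run one power posterior simulation at a fixed beta.

    L sweeps; the untempered log-likelihood of the current state is recorded
    every T-th sweep; the first ``burnin_frac`` fraction of recorded samples
    is discarded.
    """
    state = init_state
    raw = config.L // config.T
    lls = np.empty(raw)
    iters = np.empty(raw, dtype=np.int64)
    counts: dict[str, list[int]] = {}
    j = 0
    for it in range(1, config.L + 1):
        state = mcmc_sweep(model, state, beta, rng, counts)
        if it % config.T == 0:
            ll = state.log_likelihood(model)
            if not math.isfinite(ll):
                raise RuntimeError(
                    f"non-finite log-likelihood at stone {stone}, iteration {it}"
                )
            lls[j] = ll
            iters[j] = it
            j += 1
    discard = raw - config.n_samples
    rates = {name: (a / t if t else float("nan")) for name, (a, t) in counts.items()}
    return StoneSamples(
        stone=stone,
        beta=beta,
        log_likelihoods=lls[discard:],
        iterations=iters[discard:],
        final_state=state,
        acceptance_rates=rates,
    )


def run_block(
    model: ModelContract,
    stones: Sequence[tuple[int, float]],
    config: StoneRunConfig,
    rng: np.random.Generator | Callable[[int], np.random.Generator],
) -> list[StoneSamples]:
    """Run a block of stones with decreasing powers, threading chain state.

    ``stones`` is a sequence of (stone_index, beta) pairs in decreasing-beta
    order.  Pre-burn-in runs once at the block's first power; the final
    state of each stone seeds the next.  ``rng`` may be a single generator
    or a factory ``position -> Generator`` (position 0 is the pre-burn-in)
    so each phase can use an independently derived stream.
    """
    betas = [b for _, b in stones]
    if not all(b0 > b1 for b0, b1 in zip(betas, betas[1:])):
        raise ValueError("block powers must be strictly decreasing")
    if callable(rng):
        rng_for = rng
    else:
        gen = rng
        rng_for = lambda position: gen  # noqa: E731 - single shared stream
    state, _ = pre_burnin(model, config, betas[0], rng_for(0))
    out: list[StoneSamples] = []
    for pos, (k, beta) in enumerate(stones, start=1):
        samples = run_stone(model, beta, state, config, rng_for(pos), stone=k)
        state = samples.final_state
        out.append(samples)
    return out


# ---------------------------------------------------------------------------
# Move kernels


@dataclass
class SlidingWindowMove:
    """Uniform(-delta, delta) perturbation of a real-line parameter (symmetric)."""

    param: str
    delta: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"slide[{self.param}]"

    def propose(self, state, rng):
        x = state.values[self.param]
        x_new = x + rng.uniform(-self.delta, self.delta)
        return state.with_value(self.param, x_new), 0.0


@dataclass
class ReflectedSlidingWindowMove:
    """Sliding-window move on a bounded interval with reflecting boundaries.

    Reflection keeps the proposal symmetric, so the Hastings term is zero.
    """

    param: str
    delta: float = 0.2
    lo: float = 0.0
    hi: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"slide-reflect[{self.param}]"

    def propose(self, state, rng):
        x = state.values[self.param]
        x_new = x + rng.uniform(-self.delta, self.delta)
        width = self.hi - self.lo
        # fold into [lo, lo + 2*width) then reflect the upper half
        y = (x_new - self.lo) % (2.0 * width)
        if y > width:
            y = 2.0 * width - y
        return state.with_value(self.param, self.lo + y), 0.0


@dataclass
class ScaleMove:
    """Multiply a positive parameter by exp(lambda*(u - 1/2)), u ~ U(0,1).

    The Hastings ratio for this multiplicative kernel is the log of the
    multiplier: q(y|x) has density 1/(lambda*y) on the reachable interval,
    so log q(x|y) - log q(y|x) = log(y/x).
    """

    param: str
    lam: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"scale[{self.param}]"

    def propose(self, state, rng):
        x = state.values[self.param]
        factor = math.exp(self.lam * (rng.random() - 0.5))
        return state.with_value(self.param, x * factor), math.log(factor)


@dataclass
class DirichletSimplexMove:
    """Resample a simplex from a Dirichlet centred on the current value.

    Proposal: x' ~ Dirichlet(c * x + 1).  Larger concentration c makes
    smaller steps.  The Hastings term is the reverse minus the forward
    Dirichlet log-density.
    """

    param: str
    concentration: float = 100.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"dirichlet[{self.param}]"

    @staticmethod
    def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
        from scipy.special import gammaln

        return float(
            gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(x)).sum()
        )

    def propose(self, state, rng):
        x = np.asarray(state.values[self.param], dtype=float)
        alpha_fwd = self.concentration * x + 1.0
        x_new = rng.dirichlet(alpha_fwd)
        # guard against exact zeros from extreme draws
        x_new = np.clip(x_new, 1e-300, None)
        x_new = x_new / x_new.sum()
        alpha_rev = self.concentration * x_new + 1.0
        log_h = self._dirichlet_logpdf(x, alpha_rev) - self._dirichlet_logpdf(
            x_new, alpha_fwd
        )
        return state.with_value(self.param, x_new), log_h
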