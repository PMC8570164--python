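"""Tempering schedules and their division into per-worker blocks.

The powers beta interpolate between the prior (beta=0) and the posterior
(beta=1).  Following common practice, the K powers are placed at the
quantiles of a beta(alpha, 1.0) distribution, i.e. in ascending order

    beta_i = (i / (K - 1)) ** (1 / alpha),    i = 0 .. K-1,

with the default alpha = 0.3 concentrating most powers near the prior,
where the expected log-likelihood changes fastest.  Execution order is
posterior -> prior (decreasing powers), so that each power posterior chain
can start from the final state of the previous, slightly hotter, one.

For a parallel analysis the K stones are split into M consecutive blocks of
near-equal size; consecutive powers keep the within-block burn-in short
because adjacent power posteriors are similar distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PowerSchedule",
    "BlockPlan",
    "make_powers",
    "partition_blocks",
    "allocate_cpus",
]


@dataclass(frozen=True)
class PowerSchedule:
    """An ordered tempering schedule.

    Attributes
    ----------
    powers:
        The K powers in *decreasing* (execution) order: ``powers[0] == 1.0``
        (posterior) and ``powers[-1] == 0.0`` (prior).
    K:
        Number of stones.
    alpha_sched:
        Shape of the beta(alpha_sched, 1.0) quantile rule that generated
        the schedule.
    """

    powers: np.ndarray
    K: int
    alpha_sched: float = 0.3

    def __post_init__(self) -> None:
        p = np.asarray(self.powers, dtype=float)
        object.__setattr__(self, "powers", p)
        if self.K != p.size or self.K < 2:
            raise ValueError(f"K={self.K} inconsistent with {p.size} powers (need K >= 2)")
        if p[0] != 1.0 or p[-1] != 0.0:
            raise ValueError("schedule must run from 1.0 (posterior) down to 0.0 (prior)")
        if not np.all(np.diff(p) < 0):
            raise ValueError("powers must be strictly decreasing")

    @property
    def ascending(self) -> np.ndarray:
        """Powers sorted prior -> posterior (the estimators' convention)."""
        return self.powers[::-1].copy()


@dataclass(frozen=True)
class BlockPlan:
    """Assignment of consecutive stone indices to M workers.

    ``blocks[m]`` lists stone indices (into the decreasing-order schedule)
    handled by worker m, themselves in decreasing-power order.  ``N`` is the
    number of CPUs teamed up on each single likelihood evaluation when
    stone-level and likelihood-level parallelism are combined.
    """

    blocks: list[np.ndarray]
    M: int
    N: int = 1
    K: int = field(default=0)

    def __post_init__(self) -> None:
        if self.K == 0:
            object.__setattr__(self, "K", sum(len(b) for b in self.blocks))


def make_powers(K: int, alpha_sched: float = 0.3) -> PowerSchedule:
    """Generate the beta-quantile tempering schedule.

    In ascending order the i-th power is ``(i/(K-1)) ** (1/alpha_sched)``,
    the i/(K-1) quantile of a beta(alpha_sched, 1.0) distribution.  The
    returned schedule stores the powers in decreasing (execution) order with
    exact 1.0 and 0.0 endpoints.
    """
    if not isinstance(K, (int, np.integer)) or K < 2:
        raise ValueError(f"K must be an integer >= 2, got {K!r}")
    if not alpha_sched > 0:
        raise ValueError(f"alpha_sched must be positive, got {alpha_sched!r}")
    i = np.arange(K, dtype=float)
    ascending = (i / (K - 1)) ** (1.0 / alpha_sched)
    ascending[0] = 0.0
    ascending[-1] = 1.0
    return PowerSchedule(powers=ascending[::-1].copy(), K=int(K), alpha_sched=float(alpha_sched))


def partition_blocks(schedule: PowerSchedule, M: int) -> BlockPlan:
    """Split the schedule into M consecutive blocks of near-equal size.

    Block m (1-based) covers stone indices ``K - floor((m-1)K/M) - 1`` down
    to ``K - floor(mK/M)`` inclusive, indices referring to the *ascending*
    power order; e.g. K=128, M=4 gives {127..96}, {95..64}, {63..32},
    {31..0}.  Uneven divisions give some blocks one extra stone, never more.
    """
    K = schedule.K
    if not 1 <= M <= K:
        raise ValueError(f"worker count M={M} must satisfy 1 <= M <= K={K}")
    blocks: list[np.ndarray] = []
    for m in range(1, M + 1):
        hi = K - (m - 1) * K // M - 1  # highest ascending index in block m
        lo = K - m * K // M            # lowest ascending index in block m
        blocks.append(np.arange(hi, lo - 1, -1))
    return BlockPlan(blocks=blocks, M=M, N=1, K=K)


def allocate_cpus(M_total: int, N_override: int | None = None) -> tuple[int, int]:
    """Split a CPU budget between stone blocks and likelihood evaluation.

    Returns ``(workers, N)`` where N CPUs team up on each likelihood and
    ``workers`` blocks run concurrently.  The default N = floor(sqrt(M_total))
    is the allocation found to give the best overall runtime; leftover CPUs
    (M_total - workers*N) idle rather than forming unequal teams.
    """
    if M_total < 1:
        raise ValueError(f"M_total must be >= 1, got {M_total}")
    if N_override is not None:
        if not 1 <= N_override <= M_total:
            raise ValueError(
                f"N_override={N_override} must satisfy 1 <= N <= M_total={M_total}"
            )
        N = int(N_override)
    else:
        N = math.isqrt(M_total)
    workers = max(1, M_total // N)
    return workers, N
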