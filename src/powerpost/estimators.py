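"""Marginal-likelihood estimators from power posterior samples.

Both estimators consume the same object: a K x n matrix of untempered
log-likelihood samples, one row per power beta_k (ascending, beta_0 = 0 is
the prior, beta_{K-1} = 1 the posterior).

Path sampling (thermodynamic integration) integrates the expected
log-likelihood over beta with the trapezoidal rule:

    ln f(D|M) ~= sum_{k=0}^{K-2} (mean_k + mean_{k+1}) * (beta_{k+1} - beta_k) / 2

Stepping-stone sampling writes the marginal likelihood as a product of
importance ratios between adjacent powers and stabilizes each ratio by
shifting with the row maximum max_k:

    ln f(D|M) ~= sum_{k=0}^{K-2} [ ln( (1/n) sum_i exp((ln l_{k,i} - max_k) * d_k) )
                                   + d_k * max_k ],      d_k = beta_{k+1} - beta_k.

The unstabilized product form is kept as ``stepping_stone_naive``; it serves
as an oracle on well-scaled inputs and overflows where the stable form does
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampleMatrix",
    "MarginalLikelihoodEstimate",
    "path_sampling",
    "stepping_stone",
    "stepping_stone_naive",
    "estimate_both",
]


@dataclass
class SampleMatrix:
    """Per-stone untempered log-likelihood samples.

    Rows are sorted so ``powers`` ascends from 0 to 1; construction re-sorts
    if the stones were executed in another (e.g. decreasing) order.
    """

    powers: np.ndarray
    samples: np.ndarray  # shape (K, n)
    row_max: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        powers = np.asarray(self.powers, dtype=float)
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if powers.ndim != 1 or samples.shape[0] != powers.size:
            raise ValueError("samples must have one row per power")
        order = np.argsort(powers, kind="stable")
        powers = powers[order]
        samples = samples[order]
        if powers.size < 2:
            raise ValueError("need at least 2 powers")
        if np.any(np.diff(powers) <= 0):
            raise ValueError("powers must be distinct")
        if powers[0] != 0.0 or powers[-1] != 1.0:
            raise ValueError("powers must span [0, 1] with exact endpoints")
        if not np.all(np.isfinite(samples)):
            raise ValueError("all log-likelihood samples must be finite")
        self.powers = powers
        self.samples = samples
        self.row_max = samples.max(axis=1)

    @property
    def K(self) -> int:
        return self.powers.size

    @property
    def n(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class MarginalLikelihoodEstimate:
    """A log marginal likelihood with per-interval additive contributions."""

    log_ml: float
    method: str  # "path-sampling" | "stepping-stone"
    per_interval: np.ndarray  # K-1 terms summing to log_ml
    K: int
    n: int


def path_sampling(sm: SampleMatrix) -> MarginalLikelihoodEstimate:
    """Trapezoidal-rule estimate of ln f(D|M) from the per-stone means."""
    means = sm.samples.mean(axis=1)
    d = np.diff(sm.powers)
    per_interval = (means[:-1] + means[1:]) * d / 2.0
    return MarginalLikelihoodEstimate(
        log_ml=float(per_interval.sum()),
        method="path-sampling",
        per_interval=per_interval,
        K=sm.K,
        n=sm.n,
    )


def stepping_stone(sm: SampleMatrix) -> MarginalLikelihoodEstimate:
    """Numerically stable stepping-stone estimate of ln f(D|M).

    Finite for any finite sample matrix: each ratio term is shifted by the
    highest log-likelihood sample of its stone before exponentiation.
    """
    d = np.diff(sm.powers)  # K-1 interval widths
    shifted = sm.samples[:-1] - sm.row_max[:-1, None]  # rows k = 0..K-2
    terms = np.log(np.exp(shifted * d[:, None]).mean(axis=1)) + d * sm.row_max[:-1]
    return MarginalLikelihoodEstimate(
        log_ml=float(terms.sum()),
        method="stepping-stone",
        per_interval=terms,
        K=sm.K,
        n=sm.n,
    )


def stepping_stone_naive(sm: SampleMatrix) -> float:
    """Direct (unstabilized) stepping-stone product, for well-scaled inputs.

    log of prod_k (1/n) sum_i l_{k,i} ** (beta_{k+1} - beta_k), exponentiating
    the raw likelihoods.  Oracle for :func:`stepping_stone`; overflows for
    large-magnitude log-likelihoods.
    """
    d = np.diff(sm.powers)
    lik = np.exp(sm.samples[:-1])
    ratios = (lik ** d[:, None]).mean(axis=1)
    return float(np.log(ratios).sum())


def estimate_both(
    sm: SampleMatrix,
) -> tuple[MarginalLikelihoodEstimate, MarginalLikelihoodEstimate, float]:
    """Path-sampling and stepping-stone estimates plus their absolute gap.

    The gap is the usual cheap consistency diagnostic: both estimators share
    the samples, so a large discrepancy flags too few stones or samples.
    """
    ps = path_sampling(sm)
    ss = stepping_stone(sm)
    return ps, ss, abs(ps.log_ml - ss.log_ml)
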