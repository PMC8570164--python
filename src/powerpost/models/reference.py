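"""Conjugate validation models with closed-form marginal likelihoods.

These two models exist to validate the whole power posterior pipeline: the
analytic log marginal likelihood is known exactly, so the path-sampling and
stepping-stone estimates can be compared against truth rather than against
each other.

* ``NormalKnownVarModel`` - iid normal observations with known variance and
  a normal prior on the mean.  The marginal is a multivariate normal (the
  prior adds a rank-one term to the covariance), and every power posterior
  is itself normal with known moments, which lets the sampler's per-stone
  output be checked in closed form too.
* ``BetaBinomialModel`` - a binomial count with a beta prior on the success
  probability; the marginal is the beta-binomial pmf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

from ..sampler import (
    ModelContract,
    ParameterState,
    ReflectedSlidingWindowMove,
    SlidingWindowMove,
)

__all__ = [
    "NormalKnownVarModel",
    "BetaBinomialModel",
    "normal_log_marginal",
    "betabinom_log_marginal",
    "default_normal_model",
    "default_betabinom_model",
]


@dataclass
class NormalKnownVarModel:
    """y_i ~ N(theta, sigma2) iid, theta ~ N(mu0, tau2); parameter theta."""

    observations: np.ndarray
    sigma2: float
    mu0: float = 0.0
    tau2: float = 1.0
    window: float = 1.0

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        if self.sigma2 <= 0 or self.tau2 <= 0:
            raise ValueError("sigma2 and tau2 must be positive")
        # sufficient statistics for fast repeated likelihood evaluation
        y = self.observations
        self._n = y.size
        self._sum_y = float(y.sum())
        self._sum_y2 = float((y * y).sum())
        self._ll_const = -0.5 * self._n * math.log(2.0 * math.pi * self.sigma2)
        self._moves = [SlidingWindowMove("theta", delta=self.window)]

    def log_prior(self, values: dict) -> float:
        theta = values["theta"]
        return -0.5 * math.log(2.0 * math.pi * self.tau2) - 0.5 * (
            theta - self.mu0
        ) ** 2 / self.tau2

    def log_likelihood(self, values: dict) -> float:
        theta = values["theta"]
        ss = self._sum_y2 - 2.0 * theta * self._sum_y + self._n * theta * theta
        return self._ll_const - 0.5 * ss / self.sigma2

    @property
    def moves(self):
        return self._moves

    def initial_state(self, rng: np.random.Generator) -> ParameterState:
        theta = self.mu0 + math.sqrt(self.tau2) * rng.standard_normal()
        return ParameterState(values={"theta": theta})

    def power_posterior_moments(self, beta: float) -> tuple[float, float]:
        """Mean and variance of theta under likelihood^beta * prior (both normal)."""
        prec = beta * self._n / self.sigma2 + 1.0 / self.tau2
        mean = (beta * self._sum_y / self.sigma2 + self.mu0 / self.tau2) / prec
        return mean, 1.0 / prec


@dataclass
class BetaBinomialModel:
    """k_obs successes in n_obs trials, p ~ Beta(a, b); parameter p."""

    k_obs: int
    n_obs: int
    a: float = 1.0
    b: float = 1.0
    window: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.k_obs <= self.n_obs:
            raise ValueError("need 0 <= k_obs <= n_obs")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior shapes a, b must be positive")
        self._log_binom = float(
            gammaln(self.n_obs + 1) - gammaln(self.k_obs + 1) - gammaln(self.n_obs - self.k_obs + 1)
        )
        self._moves = [ReflectedSlidingWindowMove("p", delta=self.window, lo=0.0, hi=1.0)]

    def log_prior(self, values: dict) -> float:
        p = values["p"]
        if not 0.0 < p < 1.0:
            return -np.inf
        return float(
            (self.a - 1.0) * math.log(p)
            + (self.b - 1.0) * math.log1p(-p)
            - betaln(self.a, self.b)
        )

    def log_likelihood(self, values: dict) -> float:
        p = values["p"]
        if not 0.0 < p < 1.0:
            return -np.inf
        return self._log_binom + self.k_obs * math.log(p) + (
            self.n_obs - self.k_obs
        ) * math.log1p(-p)

    @property
    def moves(self):
        return self._moves

    def initial_state(self, rng: np.random.Generator) -> ParameterState:
        return ParameterState(values={"p": float(rng.beta(self.a, self.b))})

    @property
    def prior_mean(self) -> float:
        return self.a / (self.a + self.b)


def normal_log_marginal(model: NormalKnownVarModel) -> float:
    """Closed-form log marginal likelihood of the normal known-variance model.

    Marginally y ~ N(mu0 * 1, sigma2 * I + tau2 * J); with the matrix
    determinant/inversion lemma the log density reduces to the product-of-
    normals form evaluated here.
    """
    y = model.observations
    n = y.size
    s2, t2 = model.sigma2, model.tau2
    r = y - model.mu0
    # |Sigma| = sigma2^n * (1 + n tau2/sigma2);  Sigma^{-1} via Sherman-Morrison
    logdet = n * math.log(s2) + math.log1p(n * t2 / s2)
    quad = float(r @ r) / s2 - (t2 / (s2 * (s2 + n * t2))) * float(r.sum()) ** 2
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


def betabinom_log_marginal(model: BetaBinomialModel) -> float:
    """log[ C(n, k) * B(a + k, b + n - k) / B(a, b) ] — the beta-binomial pmf."""
    return float(
        model._log_binom
        + betaln(model.a + model.k_obs, model.b + model.n_obs - model.k_obs)
        - betaln(model.a, model.b)
    )


def default_normal_model() -> NormalKnownVarModel:
    """The fixed validation instance used by the examples and acceptance runs.

    Ten fixed observations (they stand in for any dataset; the values were
    drawn once from N(0.5, 1) and frozen), known sigma2 = 1, prior N(0, 4).
    """
    y = np.array(
        [0.9417, -0.2127, 1.1457, 2.0219, -0.4257, 0.7875, 0.3331, 0.0844, 1.3410, 0.5822]
    )
    return NormalKnownVarModel(observations=y, sigma2=1.0, mu0=0.0, tau2=4.0, window=1.5)


def default_betabinom_model() -> BetaBinomialModel:
    """Fixed validation instance: 4 successes in 10 trials, Beta(2, 3) prior."""
    return BetaBinomialModel(k_obs=4, n_obs=10, a=2.0, b=3.0, window=0.25)
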