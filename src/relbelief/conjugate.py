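"""Closed-form conjugate backends: Bernoulli–beta and normal–normal.

These two model/prior bundles admit exact posteriors, exact prior
predictives of the minimal sufficient statistic, and an exact relative
belief ratio, so every downstream quantity (evidence, strength, bias,
prior-data conflict) can be computed without simulation.  The relative
belief ratio of a parameter value is the ratio of its posterior to its
prior density; all ratios here are evaluated as differences of
log-densities (log-gamma algebra for the beta case) and exponentiated at
the end, so they remain finite for sample sizes in the hundreds where the
individual gamma factors overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "BetaBernoulli",
    "NormalNormal",
    "SufficientStatisticDistribution",
    "sufficient_statistic",
]


class InvalidDataError(ValueError):
    """Raised when observed data violates the model's sample space."""


def sufficient_statistic(data: Sequence[float], family: str) -> float:
    """Reduce raw data to the minimal sufficient statistic.

    For the Bernoulli family this is the success count ``s``; for the
    normal family (known variance) it is the sample mean.

    Parameters
    ----------
    data : sequence of numbers
        Raw observations.  Bernoulli data must be exactly 0/1 valued.
    family : {"bernoulli", "normal"}

    Raises
    ------
    InvalidDataError
        If ``data`` is empty, or a Bernoulli observation is not 0 or 1
        (the error message names the offending index).
    """
    arr = np.asarray(data, dtype=float)
    if arr.size == 0:
        raise InvalidDataError("data must be nonempty")
    if family == "bernoulli":
        bad = np.nonzero((arr != 0.0) & (arr != 1.0))[0]
        if bad.size:
            raise InvalidDataError(
                f"non-binary value {arr[bad[0]]!r} at index {bad[0]} "
                "in Bernoulli data"
            )
        return float(arr.sum())
    if family == "normal":
        return float(arr.mean())
    raise ValueError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class SufficientStatisticDistribution:
    """Distribution of the minimal sufficient statistic T.

    For discrete T, ``weights`` are probability masses on ``support`` and
    sum to 1.  For continuous T, ``weights`` are density values on a grid
    and ``dist`` holds the underlying frozen scipy distribution for exact
    tail computations.
    """

    support: np.ndarray
    weights: np.ndarray
    kind: Literal["discrete", "continuous"]
    dist: object | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights)
        if support.shape != weights.shape:
            raise ValueError("support and weights must have matching shapes")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.kind == "discrete" and abs(weights.sum() - 1.0) > 1e-6:
            raise ValueError("discrete masses must sum to 1")


@dataclass(frozen=True)
class BetaBernoulli:
    """Bernoulli sampling model with a beta(alpha0, beta0) prior.

    ``n`` observations with success count ``s`` (the minimal sufficient
    statistic).  ``n = 0`` is the no-data identity case: the posterior is
    the prior and RB is identically 1.
    """

    alpha0: float
    beta0: float
    n: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0 and self.beta0 > 0):
            raise ValueError("prior shapes alpha0, beta0 must be positive")
        if self.n < 0 or not (0 <= self.s <= self.n):
            raise ValueError("need 0 <= s <= n with n >= 0")

    @classmethod
    def from_data(
        cls, data: Sequence[float], alpha0: float, beta0: float
    ) -> "BetaBernoulli":
        s = sufficient_statistic(data, "bernoulli")
        return cls(alpha0=alpha0, beta0=beta0, n=len(data), s=int(s))

    @property
    def family(self) -> str:
        return "bernoulli"

    def posterior_shapes(self) -> tuple[float, float]:
        """Posterior beta shapes (alpha0 + s, beta0 + n - s)."""
        return (self.alpha0 + self.s, self.beta0 + self.n - self.s)

    def prior_dist(self):
        return stats.beta(self.alpha0, self.beta0)

    def posterior_dist(self):
        a, b = self.posterior_shapes()
        return stats.beta(a, b)

    def log_rb(self, theta):
        """log RB(theta | x) via log-gamma algebra.

        RB is the posterior beta(s+a0, n-s+b0) density over the prior
        beta(a0, b0) density.  The normalising-constant ratio is assembled
        from gammaln so that it stays finite for large n.
        """
        theta = np.asarray(theta, dtype=float)
        if np.any((theta <= 0) | (theta >= 1)):
            raise ValueError("theta must lie in the open interval (0, 1)")
        a0, b0, n, s = self.alpha0, self.beta0, self.n, self.s
        log_const = (
            gammaln(a0)
            + gammaln(b0)
            - gammaln(a0 + b0)
            + gammaln(n + a0 + b0)
            - gammaln(s + a0)
            - gammaln(n - s + b0)
        )
        return log_const + s * np.log(theta) + (n - s) * np.log1p(-theta)

    def rb(self, theta):
        """Relative belief ratio RB(theta | x), elementwise."""
        return np.exp(self.log_rb(theta))

    def prior_predictive(self) -> SufficientStatisticDistribution:
        """Beta-binomial prior predictive of the success count s."""
        support = np.arange(self.n + 1)
        pmf = stats.betabinom(self.n, self.alpha0, self.beta0).pmf(support)
        return SufficientStatisticDistribution(
            support=support,
            weights=pmf,
            kind="discrete",
            dist=stats.betabinom(self.n, self.alpha0, self.beta0),
        )

    def conditional_predictive(self, psi0: float) -> SufficientStatisticDistribution:
        """Sampling distribution of s at theta = psi0: Binomial(n, psi0)."""
        if not (0 <= psi0 <= 1):
            raise ValueError("psi0 must lie in [0, 1]")
        support = np.arange(self.n + 1)
        pmf = stats.binom(self.n, psi0).pmf(support)
        return SufficientStatisticDistribution(
            support=support,
            weights=pmf,
            kind="discrete",
            dist=stats.binom(self.n, psi0),
        )

    def with_data(self, n: int, s: int) -> "BetaBernoulli":
        return BetaBernoulli(self.alpha0, self.beta0, n, s)


@dataclass(frozen=True)
class NormalNormal:
    """Normal sampling model (known variance) with a normal prior.

    Data are n i.i.d. N(mu, sigma_sq) observations with sample mean
    ``xbar`` (the minimal sufficient statistic); the prior on mu is
    N(mu0, tau0_sq).  ``n = 0`` is the no-data identity case.
    """

    mu0: float
    tau0_sq: float
    sigma_sq: float
    n: int = 0
    xbar: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau0_sq > 0 and self.sigma_sq > 0):
            raise ValueError("tau0_sq and sigma_sq must be positive")
        if self.n < 0:
            raise ValueError("n must be nonnegative")

    @classmethod
    def from_data(
        cls, data: Sequence[float], mu0: float, tau0_sq: float, sigma_sq: float
    ) -> "NormalNormal":
        xbar = sufficient_statistic(data, "normal")
        return cls(mu0=mu0, tau0_sq=tau0_sq, sigma_sq=sigma_sq, n=len(data), xbar=xbar)

    @property
    def family(self) -> str:
        return "normal"

    def posterior_moments(self) -> tuple[float, float]:
        """Posterior mean and variance of mu.

        Precision-weighted: var = (1/tau0_sq + n/sigma_sq)^-1 and
        mean = var * (mu0/tau0_sq + n*xbar/sigma_sq).
        """
        if self.n == 0:
            return (self.mu0, self.tau0_sq)
        prec = 1.0 / self.tau0_sq + self.n / self.sigma_sq
        var = 1.0 / prec
        mean = var * (self.mu0 / self.tau0_sq + self.n * self.xbar / self.sigma_sq)
        return (mean, var)

    def prior_dist(self):
        return stats.norm(self.mu0, math.sqrt(self.tau0_sq))

    def posterior_dist(self):
        m, v = self.posterior_moments()
        return stats.norm(m, math.sqrt(v))

    def log_rb(self, mu):
        mu = np.asarray(mu, dtype=float)
        m, v = self.posterior_moments()
        log_post = -0.5 * np.log(2 * np.pi * v) - (mu - m) ** 2 / (2 * v)
        log_prior = (
            -0.5 * np.log(2 * np.pi * self.tau0_sq)
            - (mu - self.mu0) ** 2 / (2 * self.tau0_sq)
        )
        return log_post - log_prior

    def rb(self, mu):
        """Relative belief ratio RB(mu | x), elementwise."""
        return np.exp(self.log_rb(mu))

    def prior_predictive(self, grid_size: int = 512) -> SufficientStatisticDistribution:
        """Prior predictive of xbar: N(mu0, tau0_sq + sigma_sq/n)."""
        if self.n == 0:
            raise ValueError("prior predictive of xbar requires n >= 1")
        var = self.tau0_sq + self.sigma_sq / self.n
        dist = stats.norm(self.mu0, math.sqrt(var))
        grid = np.linspace(dist.ppf(1e-6), dist.ppf(1 - 1e-6), grid_size)
        return SufficientStatisticDistribution(
            support=grid, weights=dist.pdf(grid), kind="continuous", dist=dist
        )

    def conditional_predictive(
        self, psi0: float, grid_size: int = 512
    ) -> SufficientStatisticDistribution:
        """Sampling distribution of xbar at mu = psi0: N(psi0, sigma_sq/n)."""
        if self.n == 0:
            raise ValueError("conditional predictive of xbar requires n >= 1")
        dist = stats.norm(psi0, math.sqrt(self.sigma_sq / self.n))
        grid = np.linspace(dist.ppf(1e-6), dist.ppf(1 - 1e-6), grid_size)
        return SufficientStatisticDistribution(
            support=grid, weights=dist.pdf(grid), kind="continuous", dist=dist
        )

    def with_data(self, n: int, xbar: float) -> "NormalNormal":
        return NormalNormal(self.mu0, self.tau0_sq, self.sigma_sq, n, xbar)
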