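"""A priori bias in the prior, measured before the data are seen.

Whether a prior is loaded for or against a hypothesis psi0 is a property
of the model/prior pair alone.  Via the Savage–Dickey identity the
relative belief ratio of psi0 depends on the data only through the
minimal sufficient statistic t:

    RB(psi0 | x) = m(t | psi0) / m(t),

the conditional prior predictive of t given psi0 over its marginal prior
predictive.  Bias against psi0 is the probability, with t generated at
psi0, that this ratio fails to exceed 1 (evidence for a true psi0 is not
obtained); bias in favor is the probability, with t generated at a
meaningfully different psi0', that the ratio still exceeds 1 (evidence
against a false psi0 is not obtained).  Both shrink as n grows, so they
double as sample-size design criteria.

For the Bernoulli family both quantities are exact 21-term-style sums
over the success count.  For the normal family the event {RB >= 1} is an
interval in the sample mean, found by solving the quadratic log-density
difference, so the probabilities are again exact; a seeded Monte Carlo
fallback covers degenerate interval algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .conjugate import BetaBernoulli, NormalNormal

__all__ = [
    "BiasReport",
    "DesignResult",
    "rb_of_sufficient_statistic",
    "bias_against",
    "bias_in_favor",
    "bias_report",
    "design_sample_size",
]


@dataclass
class BiasReport:
    """Pre-experimental bias probabilities for a hypothesis psi0."""

    psi0: float
    bias_against: float
    deviations: list[float]
    bias_in_favor: list[float]
    n: int
    method: str = "exact-sum"
    mc_draws: int | None = None
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "psi0": self.psi0,
            "bias_against": self.bias_against,
            "deviations": list(self.deviations),
            "bias_in_favor": list(self.bias_in_favor),
            "n": self.n,
            "method": self.method,
            "mc_draws": self.mc_draws,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


@dataclass
class DesignResult:
    """Outcome of a sample-size scan controlling both bias probabilities."""

    n: int | None  # smallest qualifying n, or None if none <= n_max
    trace: "object"  # pandas DataFrame: n, bias_against, bias_in_favor columns

    @property
    def found(self) -> bool:
        return self.n is not None


def _with_n(model, n: int):
    if isinstance(model, BetaBernoulli):
        return BetaBernoulli(model.alpha0, model.beta0, n=n, s=0)
    if isinstance(model, NormalNormal):
        return NormalNormal(model.mu0, model.tau0_sq, model.sigma_sq, n=n, xbar=0.0)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def rb_of_sufficient_statistic(model, psi0: float, t) -> np.ndarray | float:
    """RB(psi0 | t) via the Savage–Dickey predictive ratio.

    Bernoulli family: Binomial(n, psi0) pmf at t over beta-binomial pmf at
    t, exact.  Normal family: N(psi0, sigma_sq/n) density over the
    marginal N(mu0, tau0_sq + sigma_sq/n) density at t = xbar.  With n = 0
    the ratio is identically 1 (no data, no belief change).
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if model.n == 0:
        out = np.ones_like(t_arr)
        return float(out[0]) if scalar else out
    if isinstance(model, BetaBernoulli):
        num = stats.binom(model.n, psi0).logpmf(t_arr)
        den = stats.betabinom(model.n, model.alpha0, model.beta0).logpmf(t_arr)
        if np.any(np.isneginf(den) & ~np.isneginf(num)):
            raise ValueError("zero marginal predictive mass at t")
        out = np.exp(num - den)
    elif isinstance(model, NormalNormal):
        vc = model.sigma_sq / model.n
        vm = model.tau0_sq + vc
        num = stats.norm(psi0, math.sqrt(vc)).logpdf(t_arr)
        den = stats.norm(model.mu0, math.sqrt(vm)).logpdf(t_arr)
        out = np.exp(num - den)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return float(out[0]) if scalar else out


def _normal_rb_ge1_interval(model: NormalNormal, psi0: float):
    """Interval of xbar values where RB(psi0 | xbar) >= 1, or None if empty.

    log RB is a concave quadratic in xbar (the conditional predictive
    variance sigma_sq/n is strictly smaller than the marginal variance
    tau0_sq + sigma_sq/n), so {RB >= 1} is a closed interval.
    """
    vc = model.sigma_sq / model.n
    vm = model.tau0_sq + vc
    # log RB = A*xbar^2 + B*xbar + C with A < 0
    a = -0.5 / vc + 0.5 / vm
    b = psi0 / vc - model.mu0 / vm
    c = (
        -0.5 * psi0**2 / vc
        + 0.5 * model.mu0**2 / vm
        + 0.5 * math.log(vm / vc)
    )
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    r = math.sqrt(disc)
    x1 = (-b + r) / (2 * a)
    x2 = (-b - r) / (2 * a)
    return (min(x1, x2), max(x1, x2))


def bias_against(
    model,
    psi0: float,
    n: int | None = None,
    mc_draws: int = 100_000,
    seed: int | None = None,
) -> float:
    """Prior probability that evidence FOR psi0 is not obtained when true.

    The probability, under the conditional prior predictive of the
    sufficient statistic given psi0, of the event {RB(psi0 | t) <= 1}.
    With n = 0 the event is certain (RB is identically 1).
    """
    m = _with_n(model, model.n if n is None else n)
    if m.n == 0:
        return 1.0
    if isinstance(m, BetaBernoulli):
        t = np.arange(m.n + 1)
        rb = rb_of_sufficient_statistic(m, psi0, t)
        gen = stats.binom(m.n, psi0).pmf(t)
        return float(gen[rb <= 1.0].sum())
    interval = _normal_rb_ge1_interval(m, psi0)
    gen = stats.norm(psi0, math.sqrt(m.sigma_sq / m.n))
    if interval is None:
        # negative discriminant: log RB is below 0 everywhere, so the
        # event {RB <= 1} is certain
        return 1.0
    lo, hi = interval
    if not (math.isfinite(lo) and math.isfinite(hi)):
        # degenerate interval algebra: fall back to seeded Monte Carlo
        rng = np.random.default_rng(seed if seed is not None else 0)
        xb = gen.rvs(size=mc_draws, random_state=rng)
        rb = rb_of_sufficient_statistic(m, psi0, xb)
        return float(np.mean(rb <= 1.0))
    return float(1.0 - (gen.cdf(hi) - gen.cdf(lo)))


def bias_in_favor(
    model,
    psi0: float,
    deviations: Sequence[float],
    n: int | None = None,
    mc_draws: int = 100_000,
    seed: int | None = None,
) -> list[float]:
    """Prior probability that evidence AGAINST psi0 is not obtained when
    psi0 is false by each stated deviation.

    For each alternative psi0' the probability, under the conditional
    prior predictive given psi0', of the event {RB(psi0 | t) > 1}
    (strict, so bias_against + P(RB > 1 | psi0) = 1 exactly at psi0).
    """
    deviations = list(deviations)
    if not deviations:
        raise ValueError("deviations must be nonempty")
    if any(d == psi0 for d in deviations):
        raise ValueError("deviations must differ from psi0")
    m = _with_n(model, model.n if n is None else n)
    out: list[float] = []
    for psi_alt in deviations:
        if m.n == 0:
            out.append(0.0)  # RB === 1, the strict event {RB > 1} is empty
            continue
        if isinstance(m, BetaBernoulli):
            t = np.arange(m.n + 1)
            rb = rb_of_sufficient_statistic(m, psi0, t)
            gen = stats.binom(m.n, psi_alt).pmf(t)
            out.append(float(gen[rb > 1.0].sum()))
        else:
            interval = _normal_rb_ge1_interval(m, psi0)
            gen = stats.norm(psi_alt, math.sqrt(m.sigma_sq / m.n))
            if interval is None:
                out.append(0.0)  # {RB > 1} is empty
            elif not all(math.isfinite(v) for v in interval):
                rng = np.random.default_rng(seed if seed is not None else 0)
                xb = gen.rvs(size=mc_draws, random_state=rng)
                rb = rb_of_sufficient_statistic(m, psi0, xb)
                out.append(float(np.mean(rb > 1.0)))
            else:
                lo, hi = interval
                out.append(float(gen.cdf(hi) - gen.cdf(lo)))
    return out


def bias_report(
    model,
    psi0: float,
    deviations: Sequence[float],
    n: int | None = None,
    seed: int | None = None,
) -> BiasReport:
    """Assemble the full pre-experimental bias report for psi0."""
    n_used = model.n if n is None else n
    method = "exact-sum" if isinstance(model, BetaBernoulli) else "exact-interval"
    return BiasReport(
        psi0=psi0,
        bias_against=bias_against(model, psi0, n=n_used, seed=seed),
        deviations=list(deviations),
        bias_in_favor=bias_in_favor(model, psi0, deviations, n=n_used, seed=seed),
        n=n_used,
        method=method,
        seed=seed,
    )


def design_sample_size(
    model,
    psi0: float,
    delta: float,
    max_bias_against: float,
    max_bias_in_favor: float,
    n_max: int,
    n_min: int = 0,
) -> DesignResult:
    """Smallest n <= n_max meeting both bias targets, by linear scan.

    Bias is not exactly monotone in n on a discrete sufficient-statistic
    lattice, so every n from n_min upward is evaluated; the full trace is
    returned either way.  bias_in_favor is evaluated at both psi0 - delta
    and psi0 + delta (clipped alternatives are dropped) and the larger
    value must meet the target.
    """
    import pandas as pd

    if delta <= 0:
        raise ValueError("delta must be positive")
    deviations = []
    for alt in (psi0 - delta, psi0 + delta):
        if isinstance(model, BetaBernoulli) and not (0 < alt < 1):
            continue
        deviations.append(alt)
    if not deviations:
        raise ValueError("psi0 +/- delta fall outside the parameter space")
    rows = []
    found: int | None = None
    for n in range(n_min, n_max + 1):
        ba = bias_against(model, psi0, n=n)
        bf = bias_in_favor(model, psi0, deviations, n=n)
        rows.append({"n": n, "bias_against": ba, "bias_in_favor": max(bf)})
        if found is None and ba <= max_bias_against and max(bf) <= max_bias_in_favor:
            found = n
            break
    return DesignResult(n=found, trace=pd.DataFrame(rows))
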