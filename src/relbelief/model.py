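"""Model/Results interface for relative belief inference.

Usage follows the familiar build-model-then-fit pattern::

    import relbelief as rb
    model = rb.BernoulliEvidence(data, alpha0=4, beta0=4)
    res = model.fit(psi0=0.5, gamma=0.95)
    print(res.summary())

``fit`` runs the whole pipeline: sufficient statistic, prior-data
conflict check (a warning, never an abort — checking and inference use
different factors of the joint and the check is assumed passed before
inference proceeds), grid discretization from exact distribution
functions, then the relative belief ratio at the hypothesized value, its
direction and strength, the least relative surprise estimate, the
evidence-ordered credible region and the companion cell-level Bayes
factor.  The returned :class:`RelativeBeliefResults` serializes to JSON
and renders a summary table rounded to three decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import evidence as ev
from .checking import ConflictReport, check_prior
from .conjugate import BetaBernoulli, NormalNormal

__all__ = ["BernoulliEvidence", "NormalEvidence", "RelativeBeliefResults"]

#: |RB - 1| below this reads as "no evidence either way"
NEUTRAL_TOL = 1e-9


@dataclass
class RelativeBeliefResults:
    """Container for a fitted relative belief analysis."""

    model: object  # the conjugate model bundle used
    psi0: float | None
    rb_at_psi0: float | None
    rb_exact: float | None  # closed-form conjugate value, when available
    direction: str | None
    strength: float | None
    tie_mass: float | None
    lrse: float
    lrse_tied: bool
    region: ev.CredibleRegion
    gamma: float
    bayes_factor: float | None
    conflict: ConflictReport | None
    belief: ev.DiscretizedBelief
    rbf: ev.RelativeBeliefFunction
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "psi0": self.psi0,
            "rb": self.rb_at_psi0,
            "direction": self.direction,
            "strength": self.strength,
            "tie_mass": self.tie_mass,
            "lrse": self.lrse,
            "region": [[lo, hi] for lo, hi in self.region.intervals],
            "gamma": self.gamma,
            "attained_content": self.region.content,
            "bayes_factor": self.bayes_factor,
            "warnings": list(self.warnings),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def summary(self) -> str:
        """Human-readable summary, values rounded to three decimals."""
        lines = ["Relative belief analysis", "=" * 40]
        if self.psi0 is not None:
            lines += [
                f"hypothesis psi0          {self.psi0:.3f}",
                f"RB(psi0 | x)             {self.rb_at_psi0:.3f}",
                f"direction                {self.direction}",
                f"strength                 {self.strength:.3f}",
                f"exact-tie mass           {self.tie_mass:.3f}",
            ]
            if self.bayes_factor is not None and np.isfinite(self.bayes_factor):
                lines.append(f"Bayes factor (cell)      {self.bayes_factor:.3f}")
        lines.append(f"LRSE                     {self.lrse:.3f}")
        reg = ", ".join(f"({lo:.3f}, {hi:.3f})" for lo, hi in self.region.intervals)
        lines += [
            f"{self.gamma:.2f}-credible region     {reg}",
            f"attained content         {self.region.content:.3f}",
        ]
        if self.conflict is not None:
            lines.append(
                f"prior-data conflict tail {self.conflict.tail_probability:.3f}"
                f" ({self.conflict.verdict})"
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot_rb(self, ax=None, show_strength: bool = True):
        """Plot the RB curve; optionally the strength construction.

        The horizontal line sits at RB(psi0 | x); the posterior mass of
        the grid cells at or below it is the strength.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mask = self.rbf.defined_mask
        ax.plot(self.rbf.grid[mask], self.rbf.rb[mask], lw=1.5, label="RB")
        ax.axhline(1.0, color="grey", lw=0.8, ls=":")
        if show_strength and self.psi0 is not None:
            ax.axhline(self.rb_at_psi0, color="C3", lw=1.0, ls="--")
            below = mask & (self.rbf.rb <= self.rb_at_psi0)
            ax.fill_between(
                self.rbf.grid,
                0,
                np.where(below, self.rbf.rb, 0.0),
                alpha=0.3,
                color="C3",
                label=f"strength = {self.strength:.3f}",
            )
            ax.plot([self.psi0], [self.rb_at_psi0], "o", color="C3")
        ax.set_xlabel("parameter")
        ax.set_ylabel("relative belief ratio")
        ax.legend()
        return ax


class _EvidenceModel:
    """Shared fit pipeline over a conjugate model bundle."""

    _conjugate: BetaBernoulli | NormalNormal

    def fit(
        self,
        psi0: float | None = None,
        gamma: float = 0.95,
        grid_size: int = ev.DEFAULT_GRID_SIZE,
        bounds: tuple[float, float] | None = None,
        check: bool = True,
        conflict_threshold: float = 0.05,
    ) -> RelativeBeliefResults:
        m = self._conjugate
        warnings: list[str] = []
        conflict = None
        if check and m.n > 0:
            t_obs = m.s if isinstance(m, BetaBernoulli) else m.xbar
            conflict = check_prior(
                m.prior_predictive(), t_obs, threshold=conflict_threshold
            )
            warnings.extend(conflict.warnings)
            if conflict.verdict == "conflict":
                warnings.append(
                    "prior-data conflict detected (tail probability "
                    f"{conflict.tail_probability:.4f} < {conflict_threshold}); "
                    "inference proceeds but the prior deserves scrutiny"
                )
        if bounds is None and psi0 is not None:
            # widen the default mass-covering bounds so a hypothesized
            # value in the deep tails still lands on the grid
            lo, hi = ev.default_bounds(m)
            pad = 4 * (hi - lo) / grid_size
            lo, hi = min(lo, psi0 - pad), max(hi, psi0 + pad)
            if isinstance(m, BetaBernoulli):
                lo, hi = max(lo, 0.0), min(hi, 1.0)
            bounds = (lo, hi)
        belief = ev.discretize(m, grid_size=grid_size, bounds=bounds)
        warnings.extend(belief.warnings)
        rbf = ev.relative_belief(belief)
        est = ev.lrse(rbf)
        region = ev.credible_region(rbf, belief, gamma)
        rb0 = rb_exact = direction = st = tie = bf = None
        if psi0 is not None:
            rb_exact = float(m.rb(psi0))
            rb0 = rbf.at(psi0)
            st, tie = ev.strength(rbf, belief, psi0, rb_at_psi0=rb0)
            if abs(rb0 - 1.0) <= NEUTRAL_TOL:
                direction = "neutral"
            elif rb0 > 1.0:
                direction = "favor"
            else:
                direction = "against"
            cell = belief.cell_index(psi0)
            mask = np.zeros(belief.n_cells, dtype=bool)
            mask[cell] = True
            bf = ev.bayes_factor(belief, mask)
        return RelativeBeliefResults(
            model=m,
            psi0=psi0,
            rb_at_psi0=rb0,
            rb_exact=rb_exact,
            direction=direction,
            strength=st,
            tie_mass=tie,
            lrse=est.psi,
            lrse_tied=est.tied,
            region=region,
            gamma=gamma,
            bayes_factor=bf,
            conflict=conflict,
            belief=belief,
            rbf=rbf,
            warnings=warnings,
        )


class BernoulliEvidence(_EvidenceModel):
    """Bernoulli observations with a beta(alpha0, beta0) prior on theta.

    Parameters
    ----------
    data : 0/1 sequence, or None when (n, s) are given directly
    alpha0, beta0 : prior beta shapes (both positive)
    n, s : observation count and success count, alternative to data
    """

    def __init__(
        self,
        data: Sequence[float] | None = None,
        alpha0: float = 1.0,
        beta0: float = 1.0,
        *,
        n: int | None = None,
        s: int | None = None,
    ) -> None:
        if data is not None:
            self._conjugate = BetaBernoulli.from_data(data, alpha0, beta0)
        else:
            self._conjugate = BetaBernoulli(
                alpha0, beta0, n=int(n or 0), s=int(s or 0)
            )

    @property
    def conjugate(self) -> BetaBernoulli:
        return self._conjugate


class NormalEvidence(_EvidenceModel):
    """Normal observations (known variance) with a normal prior on the mean.

    Parameters
    ----------
    data : real-valued sequence, or None when (n, xbar) are given
    mu0, tau0_sq : prior mean and variance
    sigma_sq : known sampling variance
    n, xbar : sample size and mean, alternative to data
    """

    def __init__(
        self,
        data: Sequence[float] | None = None,
        mu0: float = 0.0,
        tau0_sq: float = 1.0,
        sigma_sq: float = 1.0,
        *,
        n: int | None = None,
        xbar: float | None = None,
    ) -> None:
        if data is not None:
            self._conjugate = NormalNormal.from_data(data, mu0, tau0_sq, sigma_sq)
        else:
            self._conjugate = NormalNormal(
                mu0, tau0_sq, sigma_sq, n=int(n or 0), xbar=float(xbar or 0.0)
            )

    @property
    def conjugate(self) -> NormalNormal:
        return self._conjugate
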