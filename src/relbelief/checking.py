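"""Checking the prior against the data: prior-data conflict.

Every subjectively chosen ingredient of an analysis should be checkable
against the observed data.  The joint distribution of (theta, data)
factors through any minimal sufficient statistic T as

    prior x model  =  posterior  x  (prior predictive of T)  x  P(data | T),

and the three factors serve three distinct activities — inference, prior
checking and model checking — without confounding them.  The prior check
implemented here asks whether the observed T is surprising under M_T,
the prior predictive of T: the reported tail probability is the total
predictive probability of statistic values no more probable than the
observed one (the "lowest predictive density" tail).  Values near 0 mean
the data arose in a region where the prior places little belief — a
prior-data conflict; 1 means T_obs is maximally typical.

The model-checking factor P(data | T) is recorded in the factorization
bookkeeping but no model-checking procedure is provided here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conjugate import SufficientStatisticDistribution

__all__ = ["ConflictReport", "prior_data_conflict", "check_prior"]

#: which factor of the joint each activity uses; recorded on every report
FACTORIZATION = {
    "inference": "posterior Pi(. | T)",
    "prior_check": "prior predictive M_T (used here)",
    "model_check": "conditional P(. | T) (out of scope)",
}

#: relative tolerance for "no more probable than": masses within this
#: of the observed mass count as ties and are included
_MASS_TIE_RTOL = 1e-12


@dataclass
class ConflictReport:
    t_obs: float
    tail_probability: float
    threshold: float = 0.05
    warnings: list[str] = field(default_factory=list)
    factorization: dict = field(default_factory=lambda: dict(FACTORIZATION))

    @property
    def verdict(self) -> str:
        """Advisory verdict; the tail probability is the primary output."""
        return (
            "conflict" if self.tail_probability < self.threshold else "no-conflict"
        )

    def to_dict(self) -> dict:
        return {
            "t_obs": self.t_obs,
            "tail_probability": self.tail_probability,
            "threshold": self.threshold,
            "verdict": self.verdict,
            "warnings": list(self.warnings),
            "factorization": dict(self.factorization),
        }


def prior_data_conflict(
    predictive: SufficientStatisticDistribution, t_obs: float
) -> float:
    """Lowest-predictive-density tail probability of t_obs under M_T.

    Discrete T: sort the masses and sum those no greater than the mass of
    t_obs (ties included, so a unique or tied mode returns exactly 1).
    The result depends only on the multiset of masses and the observed
    mass, not on any labeling or ordering of the support.

    Continuous T (normal predictive): the equivalent density-based tail
    P(m_T(t) <= m_T(t_obs)) is the symmetric two-sided normal tail,
    computed in closed form from the attached distribution.

    A discrete t_obs outside the support has tail probability 0 (maximal
    surprise); callers receive a warning through :func:`check_prior`.
    """
    if predictive.kind == "discrete":
        support = predictive.support
        masses = predictive.weights
        hit = np.nonzero(np.isclose(support, t_obs, rtol=0, atol=1e-9))[0]
        if hit.size == 0:
            return 0.0
        m_obs = masses[hit[0]]
        return float(masses[masses <= m_obs * (1 + _MASS_TIE_RTOL)].sum())
    dist = predictive.dist
    if dist is None:
        raise ValueError("continuous predictive requires an attached distribution")
    # normal m_T: density at t decreases with |t - mean|, so the
    # lowest-density tail is the symmetric two-sided tail
    mean = dist.mean()
    return float(2 * dist.sf(mean + abs(t_obs - mean)))


def check_prior(
    predictive: SufficientStatisticDistribution,
    t_obs: float,
    threshold: float = 0.05,
) -> ConflictReport:
    """Run the prior-data conflict check and assemble the report."""
    warnings: list[str] = []
    if predictive.kind == "discrete":
        in_support = bool(
            np.any(np.isclose(predictive.support, t_obs, rtol=0, atol=1e-9))
        )
        if not in_support:
            warnings.append(
                f"t_obs={t_obs} outside the predictive support; "
                "tail probability set to 0"
            )
    tail = prior_data_conflict(predictive, t_obs)
    return ConflictReport(
        t_obs=float(t_obs),
        tail_probability=tail,
        threshold=threshold,
        warnings=warnings,
    )
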