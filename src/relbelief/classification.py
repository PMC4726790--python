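"""Two-state evidence: binary class, binary trait, in closed form.

The textbook setting behind the prosecutor's fallacy and diagnostic
screening alike: a proportion ``epsilon`` of a population is
class-positive (guilty, infected), a trait (matching evidence, positive
test) occurs at rate ``psi1`` among class-negatives and ``psi2`` among
class-positives.  Observing the trait multiplies belief in each class by
its relative belief ratio; with ``psi2 > psi1`` there is always evidence
FOR the positive class — the protection against fallacious conviction
comes from the accompanying strength assessment, which collapses as
``epsilon`` shrinks: the credible region grows to contain both classes
and the posterior probability of the positive class tends to 0.  The
MAP estimate, by contrast, simply declares the negative class for small
``epsilon``, discarding the evidence entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TraitClassification",
    "TwoPointEvidence",
    "marginal_trait_probability",
    "posterior_class_probability",
    "rb_class",
]


@dataclass(frozen=True)
class TraitClassification:
    """Prior class proportion and per-class trait rates.

    epsilon : prior proportion of the positive class
    psi1    : trait rate among class-negatives
    psi2    : trait rate among class-positives
    labels  : (negative, positive) display labels
    """

    epsilon: float
    psi1: float
    psi2: float
    labels: tuple[str, str] = ("negative", "positive")

    def __post_init__(self) -> None:
        for name in ("epsilon", "psi1", "psi2"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in the open interval (0, 1)")


def marginal_trait_probability(setup: TraitClassification) -> float:
    """Overall trait rate in the population: (1-eps)*psi1 + eps*psi2."""
    return (1 - setup.epsilon) * setup.psi1 + setup.epsilon * setup.psi2


def posterior_class_probability(setup: TraitClassification) -> float:
    """P(positive class | trait) = eps*psi2 / ((1-eps)*psi1 + eps*psi2)."""
    return setup.epsilon * setup.psi2 / marginal_trait_probability(setup)


def rb_class(setup: TraitClassification, positive: bool = True) -> float:
    """Relative belief ratio of a class given the trait.

    psi2 / marginal for the positive class, psi1 / marginal for the
    negative; the positive ratio exceeds 1 exactly when psi2 > psi1, and
    then the negative ratio is below 1.
    """
    num = setup.psi2 if positive else setup.psi1
    return num / marginal_trait_probability(setup)


@dataclass
class TwoPointEvidence:
    """Evidence report on the two-point class space.

    ``strength_rb`` is the calibration by the posterior probability of
    {class : RB <= RB(estimate's complement... hypothesized class)} and
    ``strength_posterior`` the posterior probability of the hypothesized
    class itself — on a two-point space the latter is the more direct
    strength reading, so both are reported.
    """

    setup: TraitClassification
    gamma: float
    estimate: str
    rb_positive: float
    rb_negative: float
    posterior_positive: float
    region: list[str]
    region_content: float
    threshold: float
    strength_rb: float
    strength_posterior: float

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "rb_positive": self.rb_positive,
            "rb_negative": self.rb_negative,
            "posterior_positive": self.posterior_positive,
            "gamma": self.gamma,
            "region": list(self.region),
            "region_content": self.region_content,
            "threshold": self.threshold,
            "strength_rb": self.strength_rb,
            "strength_posterior": self.strength_posterior,
        }


def evidence_with_accuracy(
    setup: TraitClassification, gamma: float, hypothesis_positive: bool = True
) -> TwoPointEvidence:
    """Full relative belief inference on the two-point class space.

    The point estimate is the class with the larger RB; the gamma-region
    applies the threshold rule c = inf{k : Pi(RB <= k | trait) >= 1-gamma}
    to the two atoms, so for small epsilon (at any fixed gamma) it
    contains both classes and the estimate carries no accuracy.  Strength
    is reported both as the RB-calibration and as the plain posterior
    probability of the hypothesized class.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    neg_label, pos_label = setup.labels
    rb_pos = rb_class(setup, positive=True)
    rb_neg = rb_class(setup, positive=False)
    post_pos = posterior_class_probability(setup)
    post = {pos_label: post_pos, neg_label: 1 - post_pos}
    rb = {pos_label: rb_pos, neg_label: rb_neg}
    estimate = pos_label if rb_pos >= rb_neg else neg_label
    other = neg_label if estimate == pos_label else pos_label
    # threshold rule on two atoms: the region always contains the
    # higher-RB class; it also contains the other iff dropping it would
    # leave posterior content below gamma
    if post[estimate] >= gamma:
        region = [estimate]
        threshold = rb[estimate]
    else:
        region = [lbl for lbl in (neg_label, pos_label) if lbl in (estimate, other)]
        threshold = min(rb_pos, rb_neg)
    content = sum(post[lbl] for lbl in region)
    hyp = pos_label if hypothesis_positive else neg_label
    # strength of the hypothesis per the RB calibration: posterior mass
    # of classes whose RB does not exceed the hypothesized class's RB
    strength_rb = sum(p for lbl, p in post.items() if rb[lbl] <= rb[hyp] * (1 + 1e-12))
    return TwoPointEvidence(
        setup=setup,
        gamma=gamma,
        estimate=estimate,
        rb_positive=rb_pos,
        rb_negative=rb_neg,
        posterior_positive=post_pos,
        region=region,
        region_content=content,
        threshold=threshold,
        strength_rb=strength_rb,
        strength_posterior=post[hyp],
    )
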