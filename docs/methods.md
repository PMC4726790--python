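# Methods

## The evidence measure

All inference in this package flows from one principle: observing data
`x` is evidence for a hypothesis exactly when it raises the
hypothesis's probability.  For an event A with P(A) > 0 the quantity of
evidence carried by conditioning on C is the relative belief ratio
RB(A|C) = P(A|C)/P(A).  For a continuous parameter of interest
ψ = Ψ(θ) the same ratio is taken as a limit of shrinking neighbourhoods
and becomes the density ratio RB_Ψ(ψ|x) = π_Ψ(ψ|x)/π_Ψ(ψ).  The
companion Bayes factor BF(A|C) = RB(A|C)/RB(Aᶜ|C) compares the evidence
for A with the evidence for its negation; it is reported as a companion
quantity where both sides of the split carry positive prior mass
(cell-level, on the grid), never as the primary measure.

Three inferential outputs are derived from the ratio:

* **Estimation.** The least relative surprise estimator (LRSE) is the ψ
  maximizing RB_Ψ(·|x); its accuracy is the size of the γ-relative
  belief credible region C_γ = {ψ : RB_Ψ(ψ|x) ≥ c_γ}, where c_γ is the
  largest threshold whose region holds posterior content at least γ.
  Regions are evidence-ordered by construction, hence nested in γ and
  always contain the LRSE.
* **Hypothesis assessment.** The evidence about H₀: ψ = ψ₀ is
  RB_Ψ(ψ₀|x) itself (direction: favor / against / neutral); its
  strength is Π_Ψ(RB_Ψ(ψ|x) ≤ RB_Ψ(ψ₀|x) | x).  The chain
  tie-mass ≤ strength ≤ RB(ψ₀|x) (a Markov-type bound) is asserted
  property-style in the tests.
* **Bias.** Whether the prior was loaded for or against ψ₀ is
  measurable before data collection; see below.

## Discretization

The engine works on finite probability masses, not symbolic densities:
a `DiscretizedBelief` holds matched prior and posterior masses on a
grid of cells, obtained as differences of the exact distribution
functions at the cell edges and renormalized.  Statistical problems are
finitely resolved in practice, and cellwise mass ratios converge to the
density ratio as the grid refines, so the grid is both an honest and a
convergent implementation.  Defaults and numerical choices:

* `grid_size` = 4096 cells over the central 1 − 1e-8 combined
  prior/posterior mass region (union of the two central intervals);
  bounds are widened to include a hypothesized ψ₀ in the tails, and a
  warning is recorded whenever the requested bounds capture less than
  1 − 1e-6 of either distribution.
* Pointwise RB values at arbitrary ψ are linear interpolations between
  cell-midpoint ratios.  Midpoint ratios are second-order accurate in
  the cell width; the raw containing-cell value is only first-order at
  off-midpoint points, which is visibly worse where the RB curve is
  steep (slope ≈ 12 at ψ = 1/2 in the packaged example).
* RB comparisons for the events {RB ≤ RB(ψ₀)} and {RB = RB(ψ₀)} use a
  relative tie tolerance of 1e-9 so exact-symmetry inputs do not flip
  the strength on floating-point noise; the direction is "neutral" iff
  |RB − 1| ≤ 1e-9.
* LRSE ties break to the smallest grid value and are flagged.
* Region thresholds are inclusive (RB ≥ c); reported endpoints are the
  outer edges of the boundary cells, and the attained posterior content
  (always ≥ γ on a finite grid) is reported next to the requested γ.
* Zero-prior cells are flagged undefined, never treated as RB = 0;
  posterior mass on a zero-prior cell is an invariant violation.

The conjugate backends evaluate everything in log space (log-gamma
algebra for beta ratios, log-density differences for normals): the
closed-form gamma-ratio constant overflows naive evaluation once n
reaches the hundreds, while the log-space route is exact to machine
precision at any practical n.

The Monte-Carlo path (`mc_marginal_belief`) serves arbitrary marginal
parameters Ψ(θ): prior draws of θ are mapped to ψ and binned for the
prior masses; the *same* draws, importance-weighted by the likelihood
of the fixed observed data, give the posterior masses.  Every
stochastic operation takes an explicit integer seed; there is no global
random state.  An effective sample size below 50 triggers a warning.

## Bias and design

By the Savage–Dickey identity, RB_Ψ(ψ₀|x) = m(x|ψ₀)/m(x) — the
conditional prior predictive of the data given ψ₀ over the marginal
prior predictive — and both predictives are functions of the minimal
sufficient statistic t.  Bias computations therefore run over t, which
turns a 2²⁰-term sum over Bernoulli data vectors into a 21-term sum
over the success count:

* bias against ψ₀ = P(RB(ψ₀|t) ≤ 1) with t generated at ψ₀,
* bias in favor of ψ₀ at ψ₀′ = P(RB(ψ₀|t) > 1) with t generated at ψ₀′.

The boundary conventions — non-strict for bias against, strict for bias
in favor — make the two events partition the support exactly at
ψ₀′ → ψ₀, and make the no-data case n = 0 (where RB ≡ 1) resolve to
bias-against 1 and bias-in-favor 0.  For the Bernoulli family both are
exact finite sums (binomial pmf over beta-binomial pmf).  For the
normal family log RB is a concave quadratic in the sample mean, so
{RB ≥ 1} is an interval found in closed form and both probabilities are
exact normal tail differences; a seeded Monte-Carlo fallback covers
degenerate root algebra.

Bias against decreases with n throughout.  Bias in favor at a fixed
deviation δ is *not* monotone from the start: in the packaged
configuration (beta(4,4), ψ₀ = 1/2, δ = 0.05) it rises from 0.690 at
n = 20 to a peak near 0.78 around n = 80 and only then decays (0.017 by
n = 2000), because evidence against a false ψ₀ cannot accumulate until
the sampling standard deviation of the statistic falls below δ.  The
tests assert this verified shape rather than blanket monotonicity.
`design_sample_size` therefore uses a linear scan, not bisection, and
returns the whole bias trace.

## Prior-data conflict

A prior is checkable against data through the prior predictive M_T of a
minimal sufficient statistic T: the joint factors as
prior × model = posterior × M_T × P(data|T), whose three factors feed
inference, prior checking and model checking separately.  The check
statistic is the lowest-predictive-density tail
M_T(m_T(t) ≤ m_T(t_obs)): for discrete T, sort the masses and sum those
no greater than the observed one (ties included, so a modal observation
scores exactly 1); for the normal (continuous) predictive the
density-based tail is the symmetric two-sided tail, computed in closed
form — a density tail is intrinsically two-sided, which is the
documented choice for continuous T.  The tail probability is the
primary output; the conflict verdict at the configurable default cutoff
0.05 is advisory, and a detected conflict warns but never blocks
inference.  Model checking against P(data|T) is out of scope; the
report's factorization field records the bookkeeping.

## Two-state classification

With class proportion ε and trait rates ψ₁ (class-negative) and ψ₂
(class-positive), everything is closed-form: marginal trait rate
(1−ε)ψ₁ + εψ₂, posterior class probability εψ₂/marginal, class RBs
ψ₂/marginal and ψ₁/marginal.  On a two-point space the strength of a
hypothesis is reported both as the RB-calibration and as the plain
posterior probability of the hypothesized class — the latter is the
natural reading when only two values exist — and neither is suppressed.
The module exhibits the package's answer to the prosecutor's fallacy:
for ψ₂ > ψ₁ there is always evidence for the positive class, but as
ε → 0 the γ-region grows to contain both classes and the posterior
probability of the positive class vanishes, so the evidence is reported
as arbitrarily weak; the MAP estimate, by contrast, silently discards
the evidence.

## Scope and defaults

Ψ is the identity map in the conjugate backends; marginal Ψ goes
through the Monte-Carlo path.  ψ is one-dimensional.  Parameter-space
endpoints θ ∈ {0, 1} are excluded from RB evaluation (the prior density
is 0 or ∞ there for general shapes).  No improper priors: diffuse-prior
behaviour (the Jeffreys–Lindley phenomenon, where inflating τ₀² sends
RB at any fixed μ to infinity) is exercised through large finite τ₀²,
and is the reason the strength calibration and the bias-in-favor
measurement exist.  No decision-theoretic loss layer is provided, by
design: the package reports evidence and its strength, not decisions.

## Synthetic data and what the tests show

The packaged 20-flip dataset (8 successes) was generated from a
Bernoulli(1/2); with the beta(4, 4) prior it is the package's reference
configuration, chosen so every headline quantity is recomputable
exactly in milliseconds.  The generator draws i.i.d. Bernoulli(θ) or
N(μ, σ²) samples from an explicit seed — it emulates exactly the
sampling models the backends assume, so passing tests demonstrate
correctness of the inferential machinery, not robustness to model
misspecification, dependence, or elicitation error in real data.  Test
problem sizes (grids of 256–4096 cells, Monte Carlo up to 10⁶ draws,
design scans to n = 2000) were chosen so the full suite completes in a
few seconds while leaving discretization error an order of magnitude
below every asserted tolerance.

## Known limitations

* Continuous-predictive conflict checking is implemented for the normal
  family only (the two-sided tail relies on unimodal symmetry).
* The beta-binomial predictive underflows for extreme shapes
  (α₀, β₀ ≫ 10³ with discordant data); bias sums there inherit scipy's
  pmf precision.
* `mc_marginal_belief` uses plain importance sampling from the prior;
  it degrades (and warns) when the posterior concentrates far from the
  prior bulk.
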