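# relbelief

Measuring statistical evidence by change in belief.

Evidence is what moves beliefs: if observing the data raises the
probability of a hypothesis, the data are evidence *for* it; if it lowers
the probability, evidence *against*.  `relbelief` turns that principle
into a working inference engine.  For a parameter of interest ψ = Ψ(θ)
with prior density π_Ψ and posterior density π_Ψ(·|x), the **relative
belief ratio**

    RB_Ψ(ψ | x) = π_Ψ(ψ | x) / π_Ψ(ψ)

measures the evidence that ψ is the true value: RB > 1 is evidence in
favor, RB < 1 evidence against, RB = 1 no evidence either way.  Because
a raw ratio has no absolute calibration, its **strength** is the
posterior probability that the true value has a ratio no greater than
the hypothesized one,

    Π_Ψ( RB_Ψ(ψ | x) ≤ RB_Ψ(ψ₀ | x) | x ),

so "evidence in favor, but weak" and "evidence in favor, and strong" are
distinct, reportable outcomes.  The package is aimed at statisticians
and quantitative scientists (the worked examples are a coin-flip
proportion and a diagnostic-screening / forensic two-class problem) who
want evidence-based Bayesian reports rather than bare posterior
summaries.

It provides:

* **Exact conjugate backends** — Bernoulli data with a beta(α₀, β₀)
  prior, and normal data (known variance σ²) with a N(μ₀, τ₀²) prior —
  with log-space density ratios, prior predictives of the minimal
  sufficient statistic, and the Savage–Dickey identity
  RB(ψ₀|x) = m(x|ψ₀)/m(x) available as an exact cross-check.
* **A generic grid engine**: discretized prior/posterior mass pairs,
  the least relative surprise estimator (LRSE) ψ̂ = argmax RB, γ-relative
  belief credible regions C_γ = {ψ : RB(ψ|x) ≥ c_γ} (evidence-ordered:
  anything with more evidence than a member is also a member), strength,
  and a seeded importance-sampling path for arbitrary marginal
  parameters.
* **A priori bias measurement**: the prior probability of failing to
  obtain evidence for a true ψ₀ (bias against) and of failing to obtain
  evidence against a meaningfully false ψ₀ (bias in favor), both exact
  sums over the sufficient statistic, plus sample-size design to control
  both.
* **Prior-data conflict checking**: a lowest-predictive-density tail
  probability of the observed sufficient statistic under its prior
  predictive — small values mean the data arose where the prior put
  little belief.
* **A closed-form two-state module** (the prosecutor's-fallacy /
  diagnostic-test setting) showing how strength protects against
  convicting on weak evidence.

## Worked example

Twenty Bernoulli observations (8 successes, packaged as
`relbelief.coin_flips()`) with a beta(4, 4) prior, assessing
H₀: θ = 1/2:

```python
import relbelief as rb

model = rb.BernoulliEvidence(rb.coin_flips(), alpha0=4, beta0=4)
res = model.fit(psi0=0.5, gamma=0.95)
print(res.summary())
```

```
Relative belief analysis
========================================
hypothesis psi0          0.500
RB(psi0 | x)             1.421
direction                favor
strength                 0.311
exact-tie mass           0.000
Bayes factor (cell)      1.420
LRSE                     0.400
0.95-credible region     (0.227, 0.593)
attained content         0.950
prior-data conflict tail 0.728 (no-conflict)
```

Reading the report: the data multiplied belief in θ = 1/2 by 1.421, so
there is evidence *in favor* of H₀ — but the strength 0.311 says there
is posterior probability 0.689 that the true θ has an even larger
ratio, so the evidence is only moderate.  The best estimate (LRSE) is
0.400 (= the sample mean here), with 0.95-credible region
(0.227, 0.593); the region's length 0.366 quantifies the estimate's
accuracy.  The conflict tail 0.728 says 8 successes in 20 is entirely
typical under the prior predictive: no prior-data conflict.

Was the prior itself loaded for or against H₀?  Before seeing data:

```python
rep = rb.bias_report(model.conjugate, 0.5, deviations=[0.45, 0.55], n=20)
print(rep.bias_against, rep.bias_in_favor)
# 0.2631759643554687 [0.6899600404793075, 0.6899600404793078]
```

There is modest bias against H₀ (probability 0.263 that evidence for a
true θ = 1/2 would not be obtained) and substantial bias in favor
(probability 0.690 of still reporting evidence for 1/2 when the truth
is 0.45 or 0.55) — at n = 20 this prior cannot reliably distinguish a
deviation of 0.05.  Both probabilities can be driven down by design:
`rb.design_sample_size` scans n until stated targets are met.

The same pipeline runs from the shell:

```sh
relbelief assess --family bernoulli --alpha0 4 --beta0 4 \
    --example --psi0 0.5 --gamma 0.95 --out report.json
relbelief bias --alpha0 4 --beta0 4 --psi0 0.5 --delta 0.05 --n 20
```

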