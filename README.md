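# hopit

Hierarchical ordered probit (HOPIT) modelling of reporting heterogeneity
in ordinal health outcomes, with group threshold contrasts and
parametric-bootstrap inference.

## The problem

Self-rated ordinal health measures — for example the five EQ-5D-5L
dimensions, each rated 1 ("no problems") to 5 (most severe) — confound
two things: how healthy a respondent actually is, and how they map that
health onto the response scale. If two population groups place the
boundary between "slight" and "moderate" problems at different points of
the latent health scale, their raw response distributions differ even at
identical health. This package separates the two using semi-objective
health indicators (diagnosed long-term conditions) to anchor latent
health, and lets the category cut-points depend on covariates that
plausibly shape reporting (ethnic group, age–sex, area deprivation,
healthcare use, survey wave).

## The model

For respondent *i* with condition indicators *x&#8205;ᵢ* and reporting
covariates *zᵢ* (the two sets are disjoint — that disjointness is the
identifying restriction):

```
h*ᵢ = β′xᵢ + εᵢ,          εᵢ ~ N(0, 1)
τᵢ₁ = λ₁ + γ₁′zᵢ
τᵢⱼ = τᵢ,ⱼ₋₁ + exp(λⱼ + γⱼ′zᵢ),   j = 2..4
yᵢ = j  iff  τᵢ,ⱼ₋₁ ≤ h*ᵢ < τᵢⱼ      (τᵢ₀ = −∞, τᵢ₅ = +∞)
```

The exponential increments keep the four cut-points ordered for every
parameter value. Estimation maximizes the survey-weighted log-likelihood

```
lnL = Σᵢ wᵢ ln[ Φ(τᵢ,ʲ⁽ⁱ⁾ − β′xᵢ) − Φ(τᵢ,ʲ⁽ⁱ⁾⁻¹ − β′xᵢ) ]
```

with an analytic gradient and a quasi-Newton optimizer followed by a
Newton polish. The headline statistic is the cut-point contrast between a
focal group and the baseline at a common covariate profile,

```
Δτ₁ = γ₁′(z¹ − z⁰),    Δτⱼ = Δτⱼ₋₁ + e^{λⱼ+γⱼ′z¹} − e^{λⱼ+γⱼ′z⁰}
```

where z⁰ holds every covariate at its weighted sample proportion with the
group dummies zeroed, and z¹ switches one group dummy on. A positive Δτⱼ
means the focal group rates the same latent health less severely at
boundary *j*. Uncertainty comes from a parametric bootstrap: coefficient
vectors drawn from N(θ̂, V̂), the contrast recomputed per draw, and 95%
intervals formed both from percentiles and from the bootstrap SE.

Because suitable respondent-level survey microdata are access-restricted,
the package ships a synthetic survey generator (`hopit.simulate`) with a
one-factor Gaussian copula for correlated sparse comorbidities, realistic
group shares, and known ground-truth reporting shifts, so every part of
the pipeline is testable by parameter recovery.

## Worked example

```python
import numpy as np
from hopit import (SyntheticConfig, generate, fit, build_profiles,
                   bootstrap_contrasts, likelihood_ratio_index, count_r2)

synth = generate(SyntheticConfig(n=20_000, seed=3))   # known truth inside
f = fit(synth.latent, synth.threshold,
        synth.table.outcome("Anxiety/Depression"), synth.table.weights,
        dimension="Anxiety/Depression")
print(f"lnL {f.loglik:.1f}  LR index {likelihood_ratio_index(f):.3f}  "
      f"Count R2 {count_r2(f, synth.latent, synth.threshold, synth.table.outcome('Anxiety/Depression'), synth.table.weights):.3f}")

profiles = build_profiles(synth.threshold, synth.table.weights)
for c in bootstrap_contrasts(f, profiles, n_draws=1000, seed=0):
    print(f"{c.group:12s} dtau1 = {c.delta[0]:+.3f} (se {c.se[0]:.3f})")
```

prints (exact values depend on the seed):

```
lnL -16394.5  LR index 0.071  Count R2 0.737
group_asian  dtau1 = +0.140 (se 0.041)
group_black  dtau1 = +0.330 (se 0.067)
group_mixed  dtau1 = +0.148 (se 0.121)
group_other  dtau1 = +0.111 (se 0.067)
```

The generator's truth puts first-cut shifts of +0.2, +0.3, 0 and +0.15 on
the four non-baseline groups, so each estimate sits within a couple of
bootstrap standard errors of its target (the smaller groups are noisy at
this sample size): the model recovers group-specific reporting behaviour
from the ordinal responses alone.

The command line mirrors the library: `hopit simulate`, `hopit fit
config.yaml`, `hopit contrast`, `hopit report`, `hopit compare` (see
`hopit --help`).

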