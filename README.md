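# icweibull

Weibull inference from **interval-censored** survival data: maximum-likelihood
and Lindley-approximation Bayes estimation of the scale and shape parameters,
with symmetric (squared-error) and asymmetric (LINEX, general-entropy) loss
functions, a clinic-visit censoring simulator, a Monte-Carlo
estimator-comparison driver, and a direct-quadrature posterior engine.

## The problem

In periodic-follow-up studies (clinical trials, longitudinal cohorts) the
event of interest is never observed exactly: a subject is seen at inspection
times and the event is only known to have happened between two visits.  Each
observation is an interval (L, R] containing the latent event time T, with
R = ∞ when the event had not occurred by the last visit (right censoring) and
L = 0 when it preceded the first visit (left censoring).

Assuming T ~ Weibull with scale α > 0 and shape β > 0,

    S(t) = exp[−(t/α)^β],

the likelihood of n independent inspection intervals is

    L(α, β) = ∏ᵢ [S(Lᵢ) − S(Rᵢ)],    ℓ(α, β) = Σᵢ ln[S(Lᵢ) − S(Rᵢ)].

**MLE.**  ℓ is maximized numerically over (ln α, ln β) with an analytic
gradient; standard errors come from the observed information at the maximum
(diagonal convention σᵢᵢ = (−ℓᵢᵢ)⁻¹ by default, full 2×2 inverse on request)
and 95% Wald intervals are θ̂ ± 1.96·se.

**Bayes.**  With independent Gamma priors α ~ Gamma(a, b), β ~ Gamma(c, d)
(all-zero hyperparameters give the noninformative 1/(αβ) default), posterior
expectations E[u(α, β) | data] are approximated by the two-parameter Lindley
expansion about the MLE,

    E[u] ≈ u + ½(u₁₁σ₁₁ + u₂₂σ₂₂) + u₁ρ₁σ₁₁ + u₂ρ₂σ₂₂
             + ½(ℓ₃₀u₁σ₁₁² + ℓ₀₃u₂σ₂₂²),

using analytic second/third log-likelihood derivatives.  Point estimators:

| loss | u | estimator |
|---|---|---|
| squared error (SELF) | θ | E[θ] |
| LINEX, parameter c ≠ 0 | e^{−cθ} | −(1/c)·ln E[e^{−cθ}] |
| general entropy (GELF), k ≠ 0 | θ^{−k} | E[θ^{−k}]^{−1/k} |

GELF at k = −1 reduces exactly to SELF; LINEX tends to SELF as c → 0.  A slow
"exact" engine evaluates the same expectations by adaptive double quadrature
of the posterior and backs the tests.

## Worked example

The packaged dataset is the classic breast-cosmesis study: 48 women treated
with radiotherapy plus adjuvant chemotherapy, inspected at irregular clinic
visits for moderate/severe breast retraction; 13 are right-censored.
Times are months.

```python
import icweibull as icw

data = icw.cosmesis_fixture()
mle  = icw.fit_mle(data)
bs   = icw.bayes_estimate(data)                                  # SELF
bl   = icw.bayes_estimate(data, loss=icw.LossSpec("linex", 0.6)) # LINEX
print(mle.params, mle.se_scale, mle.se_shape)
print(bs.params)
print(bl.params)
```

prints

```
WeibullParams(scale=28.04247401141564, shape=2.0302384151274646) 2.3884608432205865 0.2851811168167231
WeibullParams(scale=28.337596273473693, shape=2.0210651925547287)
WeibullParams(scale=27.01736212130747, shape=1.9970003565497472)
```

So the characteristic time to retraction is about 28 months with an
increasing hazard (β̂ ≈ 2.03 > 1; 95% CI 1.47–2.59, excluding constant
hazard).  The Bayes posterior-mean estimates sit close to the MLE, as the
Lindley expansion implies at this sample size, and the LINEX estimate with
c = 0.6 is pulled low because that loss penalizes overestimation.  The same
numbers are available from the shell:

```sh
icweibull fixture -o cosmesis.csv
icweibull fit --method mle cosmesis.csv
icweibull fit --method bayes --loss linex --loss-param 0.6 cosmesis.csv
icweibull simulate --n 100 --alpha 2 --beta 1.2 --seed 7 -o sim.csv
```

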