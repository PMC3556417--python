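# Methods

## Model and likelihood

Event times are assumed Weibull: survival S(t) = exp[−(t/α)^β] with scale
α > 0 (time units; the 63.2nd percentile) and dimensionless shape β > 0
(hazard decreasing for β < 1, constant at 1, increasing for β > 1).
Censoring is assumed noninformative.  Each subject contributes an inspection
interval (L, R] and the likelihood term S(L) − S(R); right censoring is the
case R = ∞ (contribution S(L)) and left censoring the case L = 0
(contribution 1 − S(R)).  No endpoint-type flag is carried: for a continuous
model, open versus closed endpoints do not change the probabilities.  Exact
(uncensored) observation times and truncation are out of scope.

## Maximum likelihood

The log-likelihood is maximized over (ln α, ln β) — the log parameterization
enforces positivity — by BFGS with the analytic score, polished by
Nelder-Mead and a final BFGS pass, from five deterministic multistart points
around a Weibull-probability-plot least-squares start (finite intervals
imputed at midpoints, right-censored subjects at L plus the median finite
width).  A fit is declared converged when the scaled score is below
1e−5·max(1, n/100) and both diagonal curvatures are negative.  Data with all
observations right-censored, or fewer than two distinct intervals, are
rejected as non-identifiable.

Standard errors default to the diagonal observed-information convention
se(θ̂ᵢ) = sqrt[(−ℓᵢᵢ)⁻¹] evaluated with analytic second derivatives at the
MLE; `full_information=True` uses the full 2×2 inverse instead (the mixed
derivative ℓ₁₁ is also analytic).  Intervals are Wald: θ̂ ± 1.96·se.

All first/second/third derivatives of ℓ are derived afresh from the
likelihood (per-endpoint chain rule on z = (t/α)^β, with the t = 0 and
t = ∞ limits handled exactly) rather than transcribed from any printed
per-term expansion, and are validated in the test suite against central
finite differences of ℓ and of the analytic score to relative 1e−5.

## Lindley approximation

For priors α ~ Gamma(a, b), β ~ Gamma(c, d) (independent), posterior
expectations are expanded about the MLE:

E[u] ≈ u + ½(u₁₁σ₁₁ + u₂₂σ₂₂) + u₁ρ₁σ₁₁ + u₂ρ₂σ₂₂ + ½(ℓ₃₀u₁σ₁₁² + ℓ₀₃u₂σ₂₂²),

with σ₁₁ = (−ℓ₂₀)⁻¹, σ₂₂ = (−ℓ₀₂)⁻¹, ρ₁ = (a−1)/α − b, ρ₂ = (c−1)/β − d.
Notes on deliberately fixed conventions:

- **Diagonal form.**  The full two-parameter expansion carries σ₁₂ and the
  mixed third derivatives ℓ₂₁, ℓ₁₂; they are omitted here by design, so the
  approximation treats the parameters as posterior-orthogonal.  This is the
  form this estimator family is usually quoted in, and it keeps every
  quantity a scalar recursion off the two diagonal curvatures.
- **ρ assignment.**  ρ₁ always takes the hyperparameters of the prior placed
  on α and ρ₂ those of the prior on β.  At the noninformative default
  a = b = c = d = 0 (prior ∝ 1/(αβ)) both reduce to ρ = −1/θ, so the choice
  is only visible with informative priors.
- **Loss parameters.**  Default grid c = k ∈ {±0.6, ±1.4}; the SELF/LINEX/
  GELF u-functions and their partials are closed-form, and each parameter's
  estimator zeroes the other parameter's partials.
- **Bayes standard errors** are posterior standard deviations obtained from a
  second Lindley pass with u = θ² (falling back to sqrt(σᵢᵢ) with a warning
  if the approximated variance loses positivity); credible intervals are
  point ± 1.96·sd.

Expansion requires a proper interior maximum; non-negative diagonal
curvature raises a curvature error rather than returning garbage.

## Quadrature engine ("exact" posterior)

`posterior_expectation` integrates u·π and π over (ln α, ln β) with
tensor-product composite-Simpson quadrature (uniform grid in the log coordinates), centered at the MLE with
half-widths of 10 asymptotic standard deviations, expanded by factors of 1.5
until the boundary integrand falls below 1e−12 of the peak (node count grows
with the window so spacing stays constant, capped at 1024 per axis; the
reported error is the change under node refinement).  The integrand is
scaled by its peak before exponentiation, since the unnormalized posterior
underflows already at n ≈ 50.

A caveat discovered while validating: with the improper all-zero
hyperparameter prior, extreme-tail posterior moments can be *divergent* —
along the ridge β ≲ 1/n the conditional scale integral ∫α·α^(−nβ−1)dα
diverges, so E[α] is strictly infinite for any n, even though the offending
region carries essentially no mass at realistic n.  The quadrature engine
therefore reports expectations of the posterior restricted to its
integration box (recorded on the result), i.e. under the prior truncated to
a huge compact set; boundary mass up to 1e−6 of the peak is tolerated at the
widest window.  For bounded functionals (LINEX) and for moderate n this
truncation is numerically irrelevant, and the Monte-Carlo cross-check in the
tests compares quadrature and importance sampling on the *same* truncated
posterior.

## Simulator

The clinic-visit mechanism: each subject draws a latent Weibull time and an
increasing visit schedule v₁ < … < v_m built from cumulative independent
Unif(0, w) gaps (m = 5 visits by default), and reports the bracketing
interval — (0, v₁] if the event precedes the first visit, (vⱼ, vⱼ₊₁] in the
interior, (v_m, ∞) past the last visit, with the censoring indicator 0 in
that last case.  The gap bound w defaults to α/m, which places the expected
last visit at α/2 and yields a substantial right-censored fraction (≈ 50–65%
across the default scenarios) — deliberately harsh inspection, matching the
mixed interior/censored datasets the estimators are meant for; pass
`window=` to calibrate lighter censoring.  Latent times and schedules are
retained on the result for testing but excluded from the estimator-facing
dataset.

What the generator emulates: irregular per-subject inspection, left and
right censoring, reproducibility from a seed.  What it does not: visit
nonattendance correlated with disease state (informative censoring),
covariates, staggered entry or calendar-time effects.  Passing tests on this
generator therefore demonstrate correctness of the estimators under
noninformative inspection, not robustness to informative follow-up.

A second, diagnostic generator (`narrow_interval_dataset`) brackets each
latent time in an interval of width 0.01·α with no censoring; it is used for
parameter-recovery checks where the censoring mechanism would confound the
question.

## Monte-Carlo study driver

`run_study` repeats simulate → fit for a design grid, with common random
numbers (every estimator sees the same dataset, and all Bayes estimators
reuse the single MLE and derivative computation).  Metrics per design point
and estimator: MSE = mean of squared errors, absolute bias = mean of
|error| (not |mean error|, so MSE ≥ bias² is *not* an invariant), and the
between-replication standard deviation of the estimates.  Replications whose
MLE fails to converge are dropped and counted into a reported
non-convergence rate; an estimator failing on every replication is an error.
The acceptance-level run uses 200 replications at n ∈ {25, 100} — sized so
the full comparison completes in a couple of minutes while the qualitative
orderings (MSE shrinking with n; squared-error Bayes at or below the MLE for
the shape at n = 100) are stable.

## Relation to previously published figures for the cosmesis data

The package's estimates for the packaged 48-interval chemotherapy arm are
α̂ = 28.042, β̂ = 2.030 (MLE), cross-validated to six significant figures
against an independent implementation (R `survival::survreg`, interval2
coding) and, for the Bayes quantities, against direct posterior quadrature
(posterior mean 28.40 / 1.983 vs Lindley 28.34 / 2.021).  Published figures
for this worked example differ from all of these oracles by 1–4% on the
point estimates and ~15% on the scale standard error, and could not be
reproduced under any data treatment we probed (finite right-censoring
sentinels, dropped or imputed observations, alternative score equations);
the test suite asserts the published values as printed and reports the
discrepancy rather than adjusting toward either side.

## Known limitations

- Single-sample inference only: no covariates, no regression, no
  profile-likelihood intervals, no joint credible regions.
- The Lindley engine is an asymptotic expansion; at n ≲ 30 with heavy
  censoring its error is visible (the tests quantify it against quadrature)
  and the quadrature engine should be preferred.
- Credible intervals are normal-approximation (point ± 1.96·sd), not
  posterior quantiles.
- The improper noninformative prior's tail pathology (above) means "exact"
  posterior moments of unbounded functions are truncation-defined at very
  small n.
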