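# Methods

## Model and censoring scheme

Lifetimes are i.i.d. Chen(λ, β): `F(x) = 1 − exp{λ(1 − e^{x^β})}`.  The
transform `Y = e^{X^β} − 1` is Exponential(λ); every closed form in the
package flows from this single fact.  The hazard is bathtub-shaped for
β < 1 (diverging at 0+, interior minimum) and increasing for β ≥ 1; β = 1
is the exponential-power special case.

Generalized Type-I hybrid censoring `(n, k, r, T)` stops the test at
`T* = max(X_{k:n}, min(X_{r:n}, T))` with `0 < k < r ≤ n`, `T > 0`.  The
three stopping cases (I: `D < k`, II: `k ≤ D < r`, III: `D ≥ r`, where `D`
counts failures with `x ≤ T` — closed boundary, ties kept, zero lifetimes
rejected) yield `m` observed order statistics.  The sufficient statistic at
a given β is

```
Q(β) = Σ_{i=1}^{m} (e^{x_i^β} − 1) + (n − m)(e^{T*^β} − 1).
```

The censored-tail term `(n − m)(e^{T*^β} − 1)` is always included: without
it the likelihood, the posterior and every closed-form estimator would be
mutually inconsistent.  `Q` equals the exponential total time on test of
the transformed data, which the tests verify as an independent derivation.

## Estimators

With β known and a Gamma(a, b) prior on λ, the posterior is
Gamma(m + a, Q + b).  Under squared-error (SE) loss the estimates are the
posterior means; under LINEX loss with shape h ≠ 0 the Bayes rule is
`−(1/h) ln E[e^{−hθ}]`.  All λ estimates are closed-form gamma moments.
`R̂_BL(t)` uses the alternating series
`Σ_j ((−h)^j/j!)((Q+b)/(Q+b+jP*))^{m+a}` truncated when the next term falls
below 1e−14 (quadrature fallback after 200 terms); the series was derived
directly from the Taylor expansion of `e^{−hR}` under the gamma posterior
and is unit-tested against adaptive quadrature for positive and negative h.

The MLE of λ is `m/Q` — the exponent is the *observed* failure count, not
n, for consistency with the likelihood's per-case form.  β̂ maximises the
profile log-likelihood `m ln(m/Q(β)) + m ln β + Σ[(β−1)ln x_i + x_i^β] − m`;
the analytic profile score is bracketed on a 200-point log grid over
[1e−2, 20] and refined by Brent's method.  This avoids the ill-defined
middle case of the printed score equation while agreeing with it where it
is well-formed (checked by finite differences).

## E-Bayesian estimation

Hyperpriors on (a, b): `a ~ Beta(u, v)` on (0, 1) — preserving the
decreasing-prior regime `0 < a < 1` when u ≤ v — and `b` on (0, c) with
density constant (variant 1), `2(c−b)/c²` (variant 2, decreasing) or
`2b/c²` (variant 3, increasing).  Default u = v = 1 gives the flat
`π(a,b) = 1/c` used throughout the replicate study.

The λ estimators are linear in a, so only `ā = u/(u+v)` enters.  Closed
forms (all re-derived analytically and verified against brute-force nested
quadrature to 1e−8; the publication-quality typography of such formulas is
unreliable, so the quadrature oracle is authoritative):

* SE: variant 1 `((m+ā)/c)·ln(1+c/Q)`; variant 2
  `(2(m+ā)/c)[(1+Q/c)ln(1+c/Q) − 1]`; variant 3
  `(2(m+ā)/c)[1 − (Q/c)ln(1+c/Q)]`.
* LINEX: `((m+ā)/h)` times the b-average of `ln(1 + h/(Q+b))`, expressed
  through the antiderivatives `I1(s) = ∫₀^c ln(s+b) db` and
  `I2(s) = ∫₀^c b·ln(s+b) db`.

Because the variant-1 density is the average of the other two, every
E-Bayes quantity satisfies `2·v1 = v2 + v3` to machine precision — a
structural identity the tests assert at 1e−12.  For λ the estimate
decreases as mass moves to larger b (v3 ≤ v1 ≤ v2); for R(t) the ordering
reverses (v2 ≤ v1 ≤ v3) since `R̂_BS` is increasing in b.

`R(t)` E-Bayes averages have no simple closed form and use nested adaptive
quadrature (absolute tolerance 1e−8); for u = v = 1 the inner a-integral is
the closed form `z^m(z−1)/ln z`.  Confluent-hypergeometric representations
exist but add nothing over direct quadrature and were not used.

**E-MSE** is the hyperprior-averaged quadratic posterior risk.  Under SE
loss and the flat hyperprior it is `(2m+1)/(2Q(Q+c))` — the average of the
posterior variance `(m+a)/(Q+b)²`; under LINEX the risk adds the squared
offset of the LINEX estimate from the posterior mean and is evaluated by
2-D adaptive quadrature.

## MCMC

The single-parameter chain is a random-walk Metropolis sampler on the exact
log kernel `(m+a−1)ln λ − (Q+b)λ`, started at the MLE, with proposal sd
defaulting to the MLE's asymptotic sd `√m/Q` and negative proposals
auto-rejected (−inf kernel).  A centred random walk is used rather than an
independence proposal because the plain posterior-ratio acceptance rule is
only correct for a symmetric proposal; an independence proposal accepted by
that rule does not leave the posterior invariant and biases the chain
toward the proposal's centre.  One normal and one uniform are consumed per
iteration in fixed order, so chains are bit-reproducible under a seed.
Burn-in defaults to N/10; credible intervals are equal-tail chain
quantiles.  The sampler exists as a cross-check of the closed forms (chain
mean/variance vs gamma moments, histogram chi-square) and as the template
for the two-parameter model.

With both parameters unknown (independent gamma priors), λ's full
conditional is exactly Gamma(m + a1, Q(β) + b1) and is drawn directly; β
moves by a log-scale random walk (Jacobian included), with the step size
tuned by a short deterministic pilot run to a 20–50% acceptance rate.
`R(t)` estimates come from the per-draw transform, not from any approximate
integral representation.  Two-parameter E-Bayes averages posterior point
estimates over Monte-Carlo hyperparameter draws, reporting the Monte-Carlo
standard error of the average; Lindley-type analytic approximations are out
of scope.

## Simulation study

Each replicate draws n uniforms, transforms them through the inverse CDF
`X = [ln(1 − ln(1−U)/λ)]^{1/β}` (one uniform per variate), sorts, censors,
and evaluates every closed-form estimator.  Replicate datasets and chain
length are deliberately separate knobs: the study's point estimates need no
chains, and the MCMC cross-check runs on a configurable subsample of
replicates.  Default study conditions mirror the published configurations:
λ ∈ {4.37, 2.5}, β = 1, designs (n, (r,k)) ∈ {(50,(40,30)), (80,(60,40)),
(120,(90,60))}, T ∈ {0.2, 0.4}, prior (a, b) = (0.6119, 0.1523), h = 1.5,
c ∈ {0.5, 1, 1.5}, t = 0.07, with 2000 replicates as the desk-scale default
(estimator means then carry Monte-Carlo standard errors of ~0.01–0.02,
small against the quantities compared).

Two distinct "MSE" notions are reported side by side, because both appear
in practice and they answer different questions:

* `MSE_*`: the empirical mean squared error of the point estimate against
  the true parameter across replicate datasets (frequentist risk at the
  truth);
* `risk_*`: the mean quadratic *posterior* risk `E[(λ̂ − λ)² | data]` —
  the posterior variance for the SE rule, variance plus squared offset for
  LINEX.

The two disagree in ordering: empirically the LINEX estimator can beat the
SE estimator at the truth (its shrinkage outweighs its bias at these sample
sizes), whereas in posterior risk the SE rule always wins because the
posterior mean minimises quadratic risk, and hyperprior averaging (E-MSE)
shrinks it further.  The directional conclusions usually quoted for this
methodology — SE beats LINEX, E-Bayes beats Bayes — are statements about
posterior risk, and the package's acceptance checks assert them on the
`risk_*` columns.

### What the generator does and does not emulate

The generator produces exactly the study conditions above: i.i.d. Chen
lifetimes, exact measurement, independent censoring by the three-case rule.
Real life-test data add features it does not model — rounding/interval
censoring, batch effects, covariates, non-identical units — so passing
tests demonstrate correctness of the inference machinery under the model,
not robustness to model misspecification.

## Numerical choices and degenerate inputs

* Densities are computed on the log scale; `e^{x^β}` never overflows before
  the enclosing exponential cancels it.
* x = 0 with β < 1: pdf and hazard return +inf, cdf returns 0 (documented
  rather than raised, since the inverse-CDF transform can emit U ≈ 0).
* m = 0 is impossible under GHCS (m ≥ k ≥ 1) and is rejected at the type
  level; b = 0 (improper prior) requires an explicit flag.
* LINEX requires `h > −(Q+b)` (single prior) or `h > −Q` (E-Bayes) for the
  expectation to exist; violations raise with the admissible bound.
* Equal-tail credible intervals use the gamma quantile function on the
  closed-form path and order statistics on the chain path; the two agree to
  Monte-Carlo error (tested).

## Known limitations

* The shape β is treated as known for all closed-form Bayes/E-Bayes work;
  joint uncertainty requires the two-parameter sampler.
* The real-data fixture ships exactly as printed in its source table.  Note
  that the worked-example narrative that usually accompanies this dataset
  quotes order statistics (x_{15} = 0.917, x_{18} = 1.064) that match the
  printed values only if the two smallest observations are discarded; this
  package computes from the full printed data, giving T* = x_{18} = 0.969.
* No progressive or Type-II hybrid censoring; no Fisher-information
  confidence intervals; no adaptive MCMC or multi-chain diagnostics.
* Plotting is limited to what the examples print; no figure styling.
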