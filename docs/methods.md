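# Methods

## Model

Stress X and strength Y are independent, positive, and both follow the
exponentiated generalized Marshall-Olkin G (EGMO-G) distribution

F(x) = {1 − [ϑḠ(x;λ)/(1 − ϑ̄Ḡ(x;λ))]^a}^b,  ϑ̄ = 1 − ϑ,

with a common baseline G, common inner power a > 0, common tilt ϑ > 0 and
common baseline parameters λ, but sample-specific outer powers b₁ (stress)
and b₂ (strength).  Because both cdfs are then powers of the same parent
cdf H(x) = {1 − [ϑḠ/(1−ϑ̄Ḡ)]^a}, namely F_X = H^{b₁} and F_Y = H^{b₂},
the reliability reduces to the proportional-reversed-hazards identity
R = P(Y < X) = b₁/(b₁+b₂): it depends on the two samples only through the
outer powers.  Everything in the package leans on that identity.

Baselines shipped: Weibull with shape γ and scale β (Ḡ = exp(−(x/β)^γ))
and exponential with rate λ (Ḡ = exp(−λx)).  A baseline is a small object
contract — cdf/pdf/survival/quantile plus the analytic partials ∂Ḡ/∂λk
and ∂log g/∂λk — so further baselines are user-addable.  ϑ > 1 (negative
ϑ̄) is allowed throughout; the denominator 1 − ϑ̄Ḡ is then > 1.

## Numerical representation

Let G, Ḡ be the baseline cdf/survival and w = G + ϑḠ ( = 1 − ϑ̄Ḡ, computed
in this cancellation-free form).  The Marshall-Olkin log-ratio is evaluated
in two regimes: log r = log1p(−G/w) where G < 1/2 (accurate as r → 1) and
log r = log ϑ + log Ḡ − log w otherwise (accurate as r → 0, using the
baseline's exact log-survival).  Powers are kept in log space:
1 − r^a = −expm1(a·log r), and the log-density uses the identity

a·logϑ + (a−1)·logḠ − (a+1)·log w ≡ a·log r − logḠ − log w,

which preserves an analytic cancellation that the left-hand side loses
catastrophically when a or ϑ is extreme (the failure mode produces phantom
likelihood spikes of order 10⁶ that a global optimizer will find).

The quantile function is closed-form: t = (1 − u^{1/b})^{1/a}, baseline
survival target Ḡ* = t/(ϑ + ϑ̄t) (denominator computed as t + ϑ(1−t)),
x = Ḡ⁻¹(Ḡ*) via the baseline's inverse survival.  Sampling is inverse
transform with uniforms clipped to [1e−15, 1−1e−15].

## Maximum likelihood

Given the shared parameters, the outer powers have closed-form profile
maximizers b̂₁ = −n/Σ log{1−r(xᵢ)^a}, b̂₂ = −m/Σ log{1−r(yⱼ)^a}, so the
numerical search runs over ψ = log(ϑ, a, λ) only, with the envelope
theorem supplying the exact gradient of the profiled log-likelihood from
the analytic score.

**Weak identifiability is the dominant design constraint.**  The family
contains limiting sub-families on the parameter boundary — a → 0 with
ϑ → ∞ at fixed ϑ^a, and ϑ → 0 with b → ∞ at fixed bϑ^a — along which the
likelihood of real datasets increases without attaining a maximum, and
even at moderate sample sizes distant parameter points reproduce nearly
the same distribution (on simulated data with n = m = 2000 the fitted
(ϑ, a, λ) can sit far from the generating values while matching their
log-likelihood to a few units; b₁, b₂ and R remain well identified).
The fitter therefore:

1. runs L-BFGS-B on ψ inside the compact box |ψᵢ| ≤ 15, from a
   data-driven start (baseline fitted alone, a = ϑ = 1) plus 20
   log-uniform random starts in [10⁻², 10²] per coordinate (seeded), with
   tight tolerances (ftol 1e−14, gtol 1e−9, ≤ 2000 iterations);
2. accepts a candidate only if it is strictly interior to the box and
   stationary, ‖∇ψ log L‖∞ < 10⁻³·max(1, |log L|) — boundary/ridge
   points are precisely the non-maxima above;
3. reports the best accepted candidate; if none is accepted it returns
   the best point found with `converged=False` rather than failing
   silently.

Standard errors come from the observed information: the negative Hessian
of the full (b₁, b₂, ϑ, a, λ) log-likelihood by central differences with
relative step 10⁻⁴ at the optimum, symmetrized and inverted.  Because of
the flat directions the per-parameter standard errors of (ϑ, a, λ) should
be read as local curvature only.

The delta-method interval for R uses the closed form
R̂ ± z_{1−δ/2}·b̂₁b̂₂/(b̂₁+b̂₂)²·√(1/n + 1/m), clipped to [0,1] (the
variance treats b̂ᵢ as asymptotically independent with CV 1/√n, which is
exact when the shared parameters are known).  The percentile bootstrap
resamples both samples independently with replacement, refits each
resample warm-started at the full-data optimum (speed and stability), and
returns the empirical (δ/2, 1−δ/2) quantiles of the R̂* draws; resamples
whose refit fails are redrawn and counted, with > 20% failures an error.

## Bayesian estimation

All parameters carry independent Gamma(shape η, rate ξ) priors; (0, 0)
denotes the improper limit π ∝ 1/·.  Conditional on the shared
parameters, the outer powers have exact gamma posteriors
b₁ | · ~ Gamma(n+η₁, H₁), b₂ | · ~ Gamma(m+η₂, H₂), with
H₁ = ξ₁ − Σ log{1−r(xᵢ)^a} and H₂ likewise — the Bayesian counterparts of
the profile formulas (at ξ = η = 0, the conditional mean n/H₁ is exactly
b̂₁).

Two sampler modes:

* `paper-conditionals` (default): the literal published scheme — gamma
  draws for b₁, b₂, then ϑ | · ~ Gamma(a(n+m)+η₃, ξ₃),
  a | · ~ Gamma(n+m+η₄, H₃), and a Gaussian random-walk
  Metropolis-Hastings step per baseline parameter targeting
  λ^{η₅−1}e^{−ξ₅λ+H₄}.  These ϑ- and a-conditionals drop the likelihood
  factors [1−ϑ̄Ḡ]^{−(a+1)} and {1−r^a}^{b−1}, and the λ pseudo-target
  fixes their exponents at −1, so the scheme is *not* invariant for the
  true posterior; it exists to reproduce published numbers and warns on
  use.  Two consequences are handled explicitly: ξ₃ = 0 makes the printed
  ϑ-conditional improper, so ϑ is then held at its initial (MLE) value;
  and when the baseline prior pair is the improper (0, 0) the λ
  pseudo-target drifts without bound, so the baseline parameters are
  likewise held at their MLE (`fix_baseline`, auto-resolved) — the
  "baseline handled separately" reading of a non-informative prior list
  that covers only (b₁, b₂, ϑ, a).
* `exact-mh`: b₁, b₂ as above (their gamma conditionals are exact), and
  random-walk MH for ϑ, a and each λk on their exact full conditionals
  (joint log-likelihood plus log-prior).  This is the mode to use when
  the posterior itself is the object of interest, and the Monte-Carlo
  study driver uses it for its Case-I chains.

Chains start at the joint MLE; proposal scales default to the MLE
standard errors (fallback 10% of the current value), optionally tuned
during a warm-up fraction toward 20–45% acceptance; all T draws are
averaged (no burn-in) with a configurable discard available downstream.
The squared-error-loss estimate is the chain mean of R^(t) = b₁/(b₁+b₂);
credible intervals are empirical chain quantiles (numpy linear
interpolation of order statistics).

With the shared parameters known (Case II), R = [1 + (α₂H₁/(α₁H₂))·F]⁻¹
exactly, with F ~ F(2α₂, 2α₁), α₁ = n+η₁, α₂ = m+η₂ — giving a
closed-form credible interval — and the posterior mean of R is

E[R] = (1−ψ)^{α₁}·(α₁/c)·₂F₁(c, α₁+1; c+1; ψ),  c = α₁+α₂,  ψ = 1 − H₁/H₂,

derived from the Euler integral of b₁/(b₁+b₂) over the product-gamma
posterior (the substitution w = b₁/(b₁+b₂), v = b₁+b₂ reduces it to
∫ w^{α₁}(1−w)^{α₂−1}(1−ψw)^{−c} dw).  For ψ < 0 the Pfaff transform
(1−ψ)^{−α₂}·(α₁/c)·₂F₁(c, α₂; c+1; ψ/(ψ−1)) is the numerically safe
branch; a log-space quadrature of the w-density is the fallback (and the
test oracle).  Since H₁, H₂ > 0, ψ < 1 always.

## Monte-Carlo study driver

`SimConfig` fixes the truth (a, b₁, b₂, ϑ, baseline parameters), the
(n, m) grid, and per-method effort; `run_mc_study` simulates by inversion,
fits every replicate, and tabulates mean estimate, MSE = Σ(R̂ᵢ−R)²/N and
mean interval lengths per cell.  Defaults are desk-scale — 200
replicates, B = 200 bootstrap resamples, T = 1000 sweeps — chosen so a
full grid runs on one CPU in minutes; published-scale effort
(1000/1000/1000) is a parameter change.  Replicate fits warm-start at the
true shared parameters with reduced polish (the replicate's task is
evaluation at scale, not global search); replicate seeds derive from the
master seed by a counter-based SeedSequence so any cell reruns in
isolation; failed fits are excluded and counted.  Bayes effort is
sub-sampled (`bayes_replicates`, `bootstrap_replicates`) because chains
and bootstrap refits dominate runtime; the regression tests use a
(10, 30, 100) grid with 200 MLE replicates, 50 Bayes replicates at
T = 300 and 6 bootstrap replicates at B = 100.

What the generator emulates: i.i.d. sampling from the exact model with
shared nuisance parameters, the setting in which R = b₁/(b₁+b₂) holds.
What it does not emulate: model misspecification, dependence between
stress and strength, censoring, rounding/ties, or covariate drift — so
passing tests certify the estimators under the model's own assumptions,
not robustness on real data.

## Goodness of fit

Sub-families are obtained by pinning shapes: EG (ϑ=1), GMO (a=1),
EMO (b=1), G (a=ϑ=1, the exponentiated baseline), MO (a=b=1), and the
baseline itself; each is fitted by the same stationarity-filtered
multi-start MLE (b profiled where free).  Reported per model: estimates
with observed-information standard errors, logL, AIC = 2k − 2logL,
BIC = k·log(n) − 2logL, and the two-sided Kolmogorov-Smirnov distance at
the order statistics with the asymptotic Kolmogorov p-value (parameters
plugged in, no small-sample or estimation correction — the convention the
published tables' p-values imply).  Ties in the data are handled by the
cumulative empirical steps.  The comparison table sorts by AIC and flags
the minimum; nesting guarantees logL(super) ≥ logL(sub) up to optimizer
tolerance, which the tests assert.

## Reproducibility of published values

The regression suite pins this package's results against the published
analysis of the same datasets.  Four findings, established empirically
and recorded here because they determine which published numbers this
implementation can and cannot return:

1. The published per-model estimates are not stationary points of the
   likelihood (score components of order 1–10 at the printed values);
   they are premature optimizer stops.  Our stationarity-filtered MLE
   finds strictly better interior optima for the 20 mm-gauge fibre sample
   (logL −48.08 vs −48.57; KS improves to 0.038) and the death-rate
   sample (200.86 vs 200.51); the 10 mm-gauge fit is reproduced exactly
   (logL −55.0768, AIC 120.154).
2. The published application R̂ values (0.458 fibre, 0.5175 COVID) equal
   b̂₁/(b̂₁+b̂₂) assembled from two *separate* single-sample fits with
   different shared parameters — not the shared-parameter joint MLE that
   the closed form R = b₁/(b₁+b₂) requires.  The joint MLE gives
   R̂ = 0.611 for the fibre data, and for the COVID rates drives R̂ → 0,
   which is also the empirically correct P(recovery < death): every
   recovery rate in the table exceeds every death rate.
3. For the COVID rates, Bayes estimates above 0.5 are impossible under
   the shared-parameter model: Ḡ(yⱼ) < Ḡ(xᵢ) pointwise for any shared
   parameters, hence H₂ < H₁ under equal priors and the posterior mean of
   b₁/(b₁+b₂) sits below 1/2 up to Monte-Carlo noise.  The package
   reports the sampler's actual output (≈ 0.45 under both priors).
4. With honestly converged sub-model fits, the plain Weibull (2
   parameters, logL −49.00) beats the full 5-parameter family on AIC for
   the fibre data, and the 3-parameter GMO-E beats EGMO-E on the death
   rates; the published "full family wins" ranking rests on sub-model
   fits that did not converge (e.g. a printed Weibull fit with KS 0.83 on
   data that plain Weibull fits with KS 0.044).

## Known limitations

* The stationarity filter's thresholds (box ±15 in log-parameters,
  gradient tolerance 10⁻³ relative) are pragmatic; data whose only
  likelihood maxima are boundary limits yield `converged=False` fits
  whose reported values depend on optimizer effort.
* The observed information is finite-difference, not analytic; in flat
  directions its inverse is a local statement only.
* The literal-conditionals sampler is not a correct posterior sampler
  (documented above); its output is meaningful only for comparison with
  published numbers.
* KS p-values are asymptotic and ignore parameter estimation; they are
  comparative, not calibrated.
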