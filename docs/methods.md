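# Methods

`countqr` implements two routes to quantile regression when the response is
a count, together with the model-comparison and goodness-of-fit machinery
needed to use them in practice. The motivating application is the analysis
of university credits earned by first-year students (one observation per
student; credits divided by 3 give a count on {0, …, 21}), with the
enrollment-cohort dummy measuring the effect of a switch to remote teaching,
but nothing in the package is specific to that dataset.

## The two estimators

**Pointwise quantile regression with jittering.** A count Y has a step
cdf, so the usual linear quantile regression theory does not apply to it
directly. Adding independent noise U ~ Uniform[0, 1) yields a continuous
working variable Z = Y + U whose conditional quantiles are in one-to-one
correspondence with those of Y. For each quantile order p the model
Q_{T(Z)}(p | x) = x′β(p) is fitted by minimising the check (pinball) loss

    L(β) = Σᵢ (p − ωᵢ)(tᵢ − xᵢ′β),   ωᵢ = 1{tᵢ ≤ xᵢ′β},

with T either the linear transform T(Z, p) = Z − p (the default here: the
quantile function of Z is bounded below by p, and a linear model is easiest
to interpret) or the classical log transform log(Z − p) with floor log(ζ),
ζ = 1e−5 by default. Because one fit depends on the realised noise,
estimation is repeated over m independent jitterings (m = 100 by default;
one working sample per replication, reused across all orders in the grid)
and the estimates averaged. Count quantiles are recovered by
Q̂_Y(p | x) = ⌈T⁻¹(x′β̂(p)) − 1⌉; negative predictions possible under the
linear transform are reported, not clamped. Standard errors come from a
nonparametric bootstrap over rows (B = 100 by default), re-jittering with
fresh noise inside every resample — the method itself does not say whether
to re-jitter, and re-jittering is the conservative choice since it
propagates both sources of randomness.

The single-quantile solver wraps the iteratively-reweighted-least-squares
routine of `statsmodels.QuantReg`; its contract is loss-optimality, which
the test suite verifies against an independent linear-programming
reformulation solved by HiGHS (agreement to ~1e−8 relative).

**Quantile-regression-coefficients modelling (QRCM).** Instead of one fit
per order, every coefficient is a parametric curve in p,
β_c(p | θ) = Σⱼ θ_cj bⱼ(p), over a small set of known basis functions, and
the full matrix θ is estimated jointly by minimising the pinball loss
integrated over p ∈ (0, 1). For a count response the model is fitted to the
offset working variable Y° = Y + 0.5 (the mean of the jittering noise): the
parametric structure smooths across the mass points, and fits to Y° and to
an actual jittered sample are nearly identical (the test suite checks this:
averaged over jitter draws, every θ entry moves by well under one SE).
Entries of θ can be restricted to zero, so each coefficient uses only its
own basis subset. Count quantiles use the same ceiling rule as above with
the identity transform.

## Numerical choices

* **Basis.** Polynomial curves use shifted Legendre polynomials
  (orthogonal on [0, 1]; same span as raw monomials, better conditioned).
  Exact integer monomial coefficients are exposed for reporting. The tail
  basis −log(1−p), the left-tail log(p) and power roots are available.
* **Quadrature.** The integral over p is a fixed 199-node Gauss–Legendre
  rule mapped to (0, 1). All nodes are interior, so −log(1−p) stays finite;
  refining to 999 nodes moves the objective by under 1e−4 relative.
* **Optimisation.** The integrated loss is convex in θ (an integral of
  convex check losses composed with a linear map). It is minimised over the
  free entries by L-BFGS-B with the analytic almost-everywhere gradient
  −Σᵢ Σₖ wₖ (pₖ − ωᵢₖ) x_ic bⱼ(pₖ); the indicator's dependence on θ is
  ignored, the standard subgradient choice. Initialisation puts the median
  of the working response on the intercept's constant basis entry and zeros
  elsewhere; the fit is deterministic given data and init. Convergence
  requires optimiser success and a gradient norm below 1e−2·(1 + |loss|);
  local optimality is additionally property-tested by coordinate
  perturbation, and on small instances the optimum is checked against an
  exact LP solution of the same quadrature objective.
* **Covariance.** Standard M-estimation sandwich H⁻¹GH⁻¹ over the free
  parameters: G is the outer-product sum of per-observation integrated
  gradients; H is a central finite-difference Hessian of the analytic
  gradient. Because the pointwise loss is kinked, the difference step is a
  smoothing bandwidth, not a rounding compromise: it must span enough
  residual sign changes to estimate the local curvature (a density, in
  effect). The default step 0.5·sd(t)·n^(−1/3) follows the usual
  nonsmooth-M-estimation rate; with it, nominal 95% intervals cover at
  ≈0.97–0.99 in the recovery simulations and the 5% global Wald test has
  empirical size ≈0.06 under the null. A fixed small step (1e−3) was
  measurably wrong — it halved some SEs at n = 300.
* **Wald tests.** The global test for one covariate is the quadratic form
  of its free θ entries against their covariance block, referred to
  chi-square with df = number of entries.
* **Confidence bands** for β_c(p) are pointwise ±1.96 delta-method SEs of
  b(p)′θ_c.
* **PIT and goodness of fit.** F(y | x, θ̂) is computed by inverting the
  fitted quantile curve at y° = y + 0.5 over the node grid (linear
  interpolation between nodes; if the curve is non-monotone the first
  upward crossing is used; results are clamped to [1e−4, 1 − 1e−4]). The
  KS or Cramér–von Mises distance of the empirical PIT from Uniform(0, 1)
  is calibrated by a parametric Monte Carlo: each replicate simulates
  continuous working responses from the fitted model (p ~ Uniform,
  y° = x′β(p | θ̂)), refits the same specification warm-started at θ̂, and
  recomputes the statistic; the p-value is the fraction of replicate
  statistics at least as large as observed. Refitting per replicate is the
  conservative choice (fixing θ̂ would ignore estimation noise). The test
  is exact only for a continuous response; for counts the observed PIT is
  discrete-valued and the test can over-reject when covariate variation is
  too weak to mix the discretisation phase — the calibration simulations
  here use a continuous covariate, where the empirical size at the 5% level
  stays within [0.01, 0.12].

## Model grid and selection

Five candidate specifications are built for the 11-coefficient credits
design. `poly(p, r)` means shifted Legendre degrees 0..r (r + 1 terms);
the school-type dummies keep a constant coefficient outside the baseline
model — free-parameter counts are 22, 25, 26, 32 and 32. The minimised
integrated loss compares models of equal complexity (it always improves
under nesting and carries no complexity penalty; no information criterion
exists for this estimator), Wald tests assess restrictions, and the
decisive diagnostic is the overlay of the parametric cohort-effect curve
with its 95% band on the pointwise jittering estimates at the percentiles
0.01–0.99. The package exports these diagnostics as plain tables; it does
not auto-select a model, because the published selection procedure is
partly visual and no numeric rule reproduces it.

## The synthetic generator

The real records live in an administrative archive and are not available,
so the generator emulates their structure with covariates drawn
independently (only marginals are published): 79.5% female; seven
high-school types with the published shares; high-school grade a truncated
normal on [60, 100] whose parent parameters are solved numerically so the
*truncated* mean and SD are 81.17 and 11.0; first-semester credits positive
multiples of 3 with mean ≈21.6 and SD ≈6.6; a 50/50 cohort split. The
response comes from a known Model-2-structured θ by inversion — p ~
Uniform(0, 1), y° = x′β(p | θ_true), y = ⌈y° − 1⌉ clamped to [0, 21] —
exactly the ceiling rule the estimators invert, so true count quantiles are
recoverable by construction. Strict monotonicity of the implied quantile
function is validated on the sampled covariate hull before any draw, and
the support clamp is hit in well under 1% of draws.

The default true intercept curve is 8.1 + 5p + 7⁄3(2p−1)³ − 0.3·log(1−p):
steep in both tails and flat in the middle, spanning ≈7.4–14.5 across p.
The shape matters: it makes the conditional density thin in the tails, the
sparse-tail regime in which pointwise quantile regression loses precision
and the parametric smoothing of QRCM gains it (the QRCM/jittering average-SE
ratio at p = 0.10 is below 1 under this generator). A near-linear intercept
would produce the opposite, unrealistic pattern — tails *easier* than the
median — because with constant density the p(1−p) numerator of the QR
variance dominates. The cohort effect is a parabola −0.6 + 2.4p − 2.4p²
(null at the median, negative in both tails); controls have gentle linear
curves and school contrasts are constants, all sized so that monotonicity
holds over the realistic covariate hull with a safety margin.

What the generator does **not** emulate: the spiky, gap-ridden empirical
pmf of real credit totals (exams worth 6, 9 or 12 credits induce
within-student structure), dependence between covariates, and cohort-level
covariate shifts. Passing tests therefore demonstrate correctness of the
estimators and their inference under a smooth, correctly specified truth —
not robustness to the irregularities of real administrative data.

## Problem sizes used by tests and the acceptance script

Simulation sizes are chosen to make Monte-Carlo noise small relative to the
tested effect while keeping runs desk-scale: parameter recovery uses 50
seeds at n = 5000 (tests) or 20 seeds (script); goodness-of-fit calibration
100 datasets × 200 Monte-Carlo replicates at n = 150 (tests) or 30 × 100
(script); the pipeline demonstrations use the case-study size n = 649 with
m = 20 jitterings, B = 50 bootstrap resamples (m = 10 inside resamples) and
100 GOF replicates. Every random stream is derived from a single seed via
`numpy.random.SeedSequence`, and the pipeline manifest logs each consumed
seed, so all reported numbers are exactly reproducible.

## Known limitations

* Quantile crossing is not prevented; fitted non-monotone curves produce a
  warning and the PIT uses the first-crossing rule.
* The intercept estimands of the two estimators can differ by up to the
  discretisation quantum (one count) where the quantile function is flat:
  pointwise jittering targets the staircase Q_Z(p), the parametric fit a
  smooth interpolant. Covariate effects are phase-free and agree within
  sampling error.
* Inference relies on asymptotic M-estimation theory; no small-sample
  correction is applied.
* The bootstrap for jittering SEs is over rows only (no clustering), and
  censored/truncated or longitudinal extensions of coefficient modelling
  are out of scope.
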