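# countqr — quantile regression for count responses

`countqr` is for analysts who want conditional quantiles of a count outcome
— credits earned by students, doctor visits, accident counts — where
ordinary linear quantile regression breaks down because the response is
discrete. It implements, side by side, the two standard ways around the
problem:

* **Average jittering.** Add U ~ Uniform[0, 1) noise to the count,
  fit Q_{T(Z)}(p | x) = x′β(p) on the continuous working variable
  Z = Y + U by minimising the check loss
  L(β) = Σᵢ (p − ωᵢ)(tᵢ − xᵢ′β) at each quantile order p, average the
  estimates over m independent jitterings, and recover count quantiles with
  Q̂_Y(p | x) = ⌈T⁻¹(x′β̂(p)) − 1⌉. Bootstrap standard errors.

* **Quantile-regression-coefficients modelling (QRCM).** Write every
  coefficient as a parametric curve β_c(p | θ) = Σⱼ θ_cj bⱼ(p) over known
  basis functions (shifted Legendre polynomials, −log(1−p), …, with zero
  restrictions on θ) and estimate all parameters jointly by minimising the
  integrated loss L̄(θ) = ∫₀¹ L(β(p | θ)) dp, applied to the offset working
  variable Y° = Y + 0.5. Inference comes from the M-estimation sandwich:
  SEs, confidence bands, global Wald tests per covariate, and a PIT
  goodness-of-fit test with Monte-Carlo p-values.

Around the two estimators the package provides the candidate-model grid of
the university-credits case study (free-parameter counts 22, 25, 26, 32,
32), overlay diagnostics of parametric curves on pointwise estimates, a
synthetic student-credits generator with a known true quantile model (the
original administrative records are not public), and an end-to-end
reporting pipeline, also available as the `countqr` command
(`simulate` / `fit` / `report`).

## Worked example

```bash
python examples/01_average_jittering.py
```

generates a cohort of 649 synthetic students, fits the average-jittering
estimator at five quantile orders and inverts the fits to count quantiles
for the reference student profile:

```
quantile order | intercept beta0(p) | predicted count, reference profile | true count
     0.10      |       6.912        |               7                   |     7
     0.25      |       8.574        |               8                   |     9
     0.50      |      10.085        |              10                   |    10
     0.75      |      12.078        |              12                   |    12
     0.90      |      13.696        |              14                   |    14
```

The first column is the fitted working-scale intercept β̂₀(p); the ceiling
rule turns it into a count quantile, which matches the generator's true
quantile up to sampling error at this n (the p = 0.25 row sits one count
low because the true quantile is near an integer boundary).

`examples/02_qrcm_fit_and_inference.py` fits the 26-parameter selected
specification by integrated-loss minimisation and prints the cohort-effect
curve with 95% bands, its global Wald test (chi²(7) = 8.76, p = 0.27 on
that draw — the simulated remote-teaching effect is small and not
significant at n = 649) and the PIT goodness of fit (KS = 0.018,
Monte-Carlo p = 0.20: no evidence of misfit, as expected under a correctly
specified truth). `examples/03_model_grid_and_pipeline.py` runs the whole
pipeline and prints the loss table and the average-SE comparison; the
QRCM/jittering ratio is below 1 in both tails, the precision gain that
motivates coefficient modelling.

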