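"""Average-jittering quantile regression on a synthetic student cohort.

Generates a cohort with a known conditional quantile model, fits the
jittering estimator on a few quantile orders, and recovers count quantiles
for the reference student profile.
"""

import numpy as np

import countqr as cq

data = cq.generate_dataset(n=649, seed=1)
cfg = cq.JitterConfig(m=20, transform="linear", seed=2)
p_grid = [0.10, 0.25, 0.50, 0.75, 0.90]
fit = cq.average_jittering_fit(data.dataset, p_grid, cfg)

print("quantile order | intercept beta0(p) | predicted count, reference profile | true count")
x_ref = np.r_[1.0, np.zeros(10)]
for j, p in enumerate(p_grid):
    pred = cq.invert_to_count(fit.beta_avg[j] @ x_ref, p, cfg)
    truth = data.model.quantile_count(x_ref, [p])[0]
    print(f"     {p:.2f}      |      {fit.beta_avg[j, 0]:6.3f}        |"
          f"              {pred:2d}                   |    {truth:2d}")

print("\nEach row shows the fitted working-scale intercept at order p and the")
print("count quantile recovered with the ceiling rule; up to sampling error")
print("at n=649 it matches the true quantile implied by the generator's theta.")
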