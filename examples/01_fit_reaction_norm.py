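"""Fit a thermal reaction norm to one replicate and derive its traits.

Builds a small synthetic assay (six temperatures, Gaussian noise), fits the
left-skewed growth model by maximum likelihood, and prints the fitted
parameters and the derived thermal traits.
"""

import numpy as np

import thermnorm as tn

# a plausible truth: thermal limits 4-28 degC, optimum 21.3, peak 1.0/day
truth = tn.params_from_traits(t_min=4.0, t_max=28.0, t_opt=21.3, mu_peak=1.0)
temps = np.array([15.0, 18.0, 22.0, 24.0, 26.0, 27.0])
rng = np.random.default_rng(42)
rates = np.maximum(tn.eval_reaction_norm(truth, temps) + rng.normal(0, 0.05, 6), 0)

fit = tn.fit_reaction_norm((temps, rates))
traits = tn.derive_traits(fit)

print(f"fitted params: z={fit.params.z:.2f} w={fit.params.w:.2f} "
      f"a={fit.params.a:.3f} b={fit.params.b:.3f} sigma={fit.params.sigma:.3f}")
print(f"T_opt = {traits.t_opt:.2f} degC   (truth {tn.derive_topt(truth):.2f})")
print(f"T_max = {traits.t_max:.2f} degC   (truth {truth.t_max_analytic:.2f})")
print(f"mu_max = {traits.mu_max:.3f}/day at {traits.mu_max_temp:.0f} degC")
print("T_opt is the temperature maximizing growth; T_max the upper limit of "
      "positive growth; mu_max the highest measured rate.")
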