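# thermnorm

Thermal reaction norm analysis for experimental-evolution growth assays:
fit a left-skewed unimodal growth–temperature curve to replicate
phytoplankton populations, derive thermal traits, propagate uncertainty
with a residual bootstrap, and test treatment effects with per-bootstrap
linear models.

## The problem

Long-term selection experiments with asexual phytoplankton (e.g. the
coccolithophore *Emiliania huxleyi*) ask whether thermal tolerance evolves
on decadal-relevant timescales. The endpoint measurement is a growth assay:
each replicate population, evolved under one of 2 selection temperatures
(15.0 / 26.3 °C) crossed with 3 pCO₂ levels (400 / 1100 / 2200 μatm,
5 replicates per cell), is grown at six assay temperatures
(15, 18, 22, 24, 26, 27 °C) and its specific daily growth rate
μ = (ln N_d − ln N₀)/d recorded. This package turns those 30 × 6 records
into trait estimates and treatment-effect tests.

The growth–temperature relationship is modelled as

    f(T) = a · e^{bT} · [ 1 − ((T − z) / (w/2))² ]

whose derived traits are **T_opt** (temperature of maximal growth, the
argmax), **T_max** (upper temperature limit of positive growth, the upper
zero `z + w/2`) and **μ_max** (highest *measured* growth rate). Parameters
are estimated per replicate by maximum likelihood (Gaussian errors →
multi-start nonlinear least squares). Trait uncertainty comes from a
1000-iteration residual bootstrap (residuals rescaled, reassigned to the
fitted values, curve refitted, traits rederived). Treatment effects are
tested by fitting, per bootstrap iteration,

    trait ~ selection_temp + pCO₂* + selection_temp : pCO₂*

where pCO₂* is standardized by two standard deviations; a coefficient is
significant when its 95% percentile interval excludes zero, and significant
interactions veto interpretation of main effects. μ_max uses a single OLS
fit with t-based intervals (no bootstrap). See `docs/methods.md` for the
full statistical account.

## Worked example

```python
import numpy as np
import thermnorm as tn

truth = tn.params_from_traits(t_min=4.0, t_max=28.0, t_opt=21.3, mu_peak=1.0)
temps = np.array([15.0, 18.0, 22.0, 24.0, 26.0, 27.0])
rng = np.random.default_rng(7)
rates = np.maximum(tn.eval_reaction_norm(truth, temps) + rng.normal(0, 0.05, 6), 0)

fit = tn.fit_reaction_norm((temps, rates))
dist = tn.residual_bootstrap(fit, n_iter=1000, seed=7, replicate_id="demo")
print(tn.derive_topt(fit.params), tn.trait_ci(dist.t_opt_draws, 0.95))
```

prints (from `examples/02_bootstrap_uncertainty.py`):

```
T_opt = 20.98 degC, 95% CI [20.57, 21.37] (1000 successful refits)
T_max = 27.93 degC, 95% CI [27.76, 28.17]
```

i.e. with noise sd 0.05/day on six points, the estimated optimum (truth
21.3 °C) carries roughly a ±0.4 °C interval, while the upper thermal limit
is pinned more tightly. The `examples/` directory has one short script per
capability: fitting, bootstrap uncertainty, treatment-effect inference, and
the file-writing pipeline.

A thin CLI wraps the same stages:

```sh
thermnorm simulate --seed 3 --out assay.csv
thermnorm run --input assay.csv --n-iter 1000 --seed 3 --outdir results/
```

writing per-replicate fits (JSON), bootstrap draws, coefficient and
treatment-mean tables (CSV) and a manifest that reproduces the run
bit for bit.

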