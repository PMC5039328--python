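# Methods

## The model

Growth rate as a function of assay temperature `T` is modelled with the
left-skewed unimodal thermal performance curve

    f(T) = a · e^{bT} · [ 1 − ( (T − z) / (w/2) )² ]

The bracket is a downward parabola with zeros at `z − w/2` and `z + w/2`, so
`w` is the **thermal niche width** — the range of temperatures over which
growth is positive — and the exponential factor tilts the parabola so that,
for `b > 0`, growth rises slowly with temperature and collapses quickly
above the optimum, the shape characteristic of phytoplankton growth.
`z`, `a` and `b` have no individual biological reading; they jointly set the
curve's position, height and skew.

Derived traits:

* **T_opt** — the temperature maximizing `f`, found by bounded scalar
  optimization on `[z − w/2, z + w/2]` and validated on every call against
  the stationarity condition `b·u² + (4/w)·u − b = 0`, `u = (T − z)/(w/2)`
  (agreement demanded to 1e-4 °C; the optimizer tolerance is 1e-6 °C).
* **T_max** — the upper zero of `f`, found by bracketed root finding on
  `(T_opt, z + w/2]` and validated against the closed form `z + w/2`.
* **μ_max** — deliberately *not* read off the fitted curve: it is the
  highest measured growth rate, with its assay temperature; ties report the
  lowest qualifying temperature. Curve height near the peak is the least
  reliable feature of a four-parameter fit to six points.

## Estimation

The likelihood is Gaussian with constant variance, so the maximum-likelihood
point estimates are nonlinear least squares; `sigma` is the residual MLE
`sqrt(SSE/n)`. The objective is multimodal in `(z, w, b)`, so fitting is
multi-start: `z` over five points spanning the observed temperatures,
`w ∈ {10, 20, 30}` °C, `b ∈ {0.01, 0.05, 0.1, 0.2}` per °C, with `a` seeded
from the maximum observed rate. The 60 grid points are ranked by their
initial sum of squares and the optimizer (trust-region reflective, with the
analytic Jacobian) is run from the best 12; the best converged likelihood
wins, ties broken by the smaller parameter norm. Running from the full grid
(`max_starts=None`) is supported and changes nothing in the recovery tests.
Bounds keep the optimizer in a biologically meaningful region:
`w ∈ (1, 60)` °C, `a ∈ (1e-6, 10)` per day, `b ∈ (−1, 1)` per °C, `z` within
the observed range ± 20 °C. Unbounded fits can reach slightly lower sums of
squares in degenerate corners (e.g. effectively-linear curves with
`w ≈ 3000` °C); we verified against an independent R `minpack.lm` fit that
wherever the solution is interior, both optimizers agree to six digits.

Warm-started refits (bootstrap iterations) first try unconstrained
Levenberg–Marquardt and keep its solution when it lands inside the bounds,
falling back to the bounded solver and then to the full start grid.

Fits require at least 5 observations at 4 distinct temperatures (four curve
parameters plus a noise scale).

## Censoring rule

Where a replicate shows no growth (rate ≤ 0) at either 26 or 27 °C, the
27 °C record is flagged censored and excluded from fitting: a measured zero
there stands in for an unmeasurable negative rate and would otherwise bias
the fitted upper limb. The "either … or" is implemented as a logical OR
(the literal reading); an AND mode is available via configuration, because
removing a 27 °C record that itself shows growth (when 26 °C does not) is a
defensible alternative reading. Temperatures match the rule within a
configurable ±0.5 °C to absorb setpoint drift. Records are never deleted —
the flag is set, both views can be written, and each censoring event is
logged.

## Residual bootstrap

Per replicate, 1000 iterations (default): the fit's residuals are randomly
reassigned to the fitted values and added to them, the curve is refitted,
and T_opt and T_max are rederived. "Reassigned" is read as a permutation
without replacement (default mode); classic with-replacement resampling is
provided as `mode="resample"`, and outputs record the mode. μ_max is not
bootstrapped — it is a direct measurement, not a fit derivative.

Raw residuals from a 4-parameter fit to ~6 points underestimate the noise:
their expected sum of squares is `(n − p)·σ²`, a factor 3 short at `n = 6`,
`p = 4`. Residuals are therefore inflated by `sqrt(n/(n − p))` before
reassignment (`scale_residuals=True`), the standard degrees-of-freedom
correction for residual bootstraps. Without it the percentile intervals are
drastically anti-conservative. Even with it, intervals at `n − p = 2`
residual degrees of freedom remain somewhat anti-conservative — the realized
residual spread of any one fit is χ²₂-distributed around σ², so interval
widths fluctuate strongly, and units whose residuals happen to be small get
too-narrow intervals. In our simulations (200 units, noise sd 0.05/day,
6 assay temperatures) the 95% T_opt interval covers the truth for ≈ 85–88%
of units. This is a structural small-sample property of the procedure, not
an implementation artifact; it should be kept in mind when reading the
per-replicate intervals. Coefficient intervals in the treatment models are
much better calibrated because they aggregate 30 independent units (the
type-I error of the CI-exclusion rule is ≈ 5–6% in our null simulations).

Failed refits are dropped and counted, never retried; a distribution with
more than 5% failures is flagged unreliable. Seeding is counter-based per
(replicate, iteration), so serial and parallel execution agree bitwise.

Confidence intervals are percentile intervals with type-7 (linear
order-statistic interpolation) quantiles; no BCa correction.

## Treatment-effect models

Each trait is modelled as

    trait ~ 1 + temp_high + pco2_std + temp_high : pco2_std

with `temp_high` an indicator for selection at 26.3 °C (15.0 °C is the
reference, so `temp_effect` is the warm-minus-cold difference at mean pCO₂)
and `pco2_std` the pCO₂ level standardized by subtracting the mean and
dividing by **two** sample standard deviations over the 30 units
(Gelman's convention; the standardized predictor has SD 0.5, making its
coefficient comparable to the binary contrast).

For T_opt and T_max the model is fitted once per bootstrap iteration,
assembling iteration `k`'s 30 trait values from each unit's `k`-th draw;
iterations in which any unit's refit failed are dropped listwise, keeping
the design balanced. Coefficient CIs are percentile intervals of the
coefficient draws. A coefficient is significant when its 95% interval
excludes zero (with a 1e-10 absolute guard against floating-point residue);
when the interaction is significant, the main effects are reported but
flagged non-interpretable. Point coefficients and adjusted R² come from the
single LM on the per-unit point-estimate traits.

μ_max uses one OLS fit (statsmodels) on the highest measured rates, with
normal-theory t intervals on `n − 4` degrees of freedom; no bootstrap.

Treatment-cell summaries report, per (selection temperature × pCO₂) cell,
the mean trait over its replicates; for T_opt/T_max the interval is the
percentile spread of per-iteration cell means, for μ_max a t interval
across the replicates (assuming normality of the measured rates).

## Synthetic data

The generator reproduces the factorial design: 2 selection temperatures
(15.0 / 26.3 °C) × 3 pCO₂ levels (400 / 1100 / 2200 μatm) × 5 replicates,
each assayed at 15, 18, 22, 24, 26, 27 °C → 180 records. Each treatment
cell has a true curve, specified by trait targets (lower/upper limit,
optimum, peak rate) and converted exactly to `(z, w, a, b)`. Replicates
jitter around their cell (sd 0.1 °C on `z`, 2% multiplicative on `a`, both
configurable — chosen to mimic a modest within-treatment spread), noise is
homoscedastic Gaussian on the rate scale (default sd 0.05/day), and
negative observations are floored at zero, mirroring the batch-culture
measurement limit. The truth table returned alongside the units carries
per-unit parameters and derived traits.

`paper_like_scenario()` plants the headline pattern of the study the design
emulates: cold-selected lines at T_opt 21.3 °C with T_max 28 / 27 / 26 °C
across the pCO₂ gradient and steeply declining peak rates
(1.00 / 0.93 / 0.81 per day); warm-selected lines at T_opt 22.0 °C
(a planted shift of exactly +0.7 °C), T_max 28.7 °C flat in pCO₂, and
gently declining peaks (0.87 / 0.83 / 0.78 per day). The lower thermal
limit is fixed at 4 °C in every cell: the assay design carries no
information below 15 °C, which is also why fitted niche widths are not
interpreted. The generator emulates the noise structure the analysis
assumes — it does not simulate biology (no evolution, no carbonate
chemistry, no cell-size dynamics), so passing tests certify the statistical
machinery, not conclusions about real cultures.

What the scenario does *not* plant: the relative-fitness quotients at the
26 °C assay. Given the trait targets above, the implied quotients are
≈ 1.1 (400 μatm) and ≈ 1.7 (1100 μatm), and at 2200 μatm the cold-adapted
lines stop growing at 26 °C, making the quotient undefined — the reported
values are whatever the planted curves imply.

## Numerical choices and degenerate inputs

* Quantiles: numpy type-7 everywhere, stated for reproducibility.
* μ_max ties: lowest qualifying temperature.
* Observed-rate validation: negative rates are rejected at parse time
  (zeros are kept; they carry information).
* `trait_ci` requires ≥ 20 draws; `bootstrap_trait_inference` requires
  ≥ 20 listwise-complete iterations.
* Constant pCO₂ designs cannot be standardized (zero SD) and error out.
* Rank-deficient LM designs raise an error naming the collinear column.
* Perfect interpolation (zero residual variance) reports `sigma = 0` and an
  infinite log-likelihood sentinel; bootstrap draws then reproduce the
  point traits exactly.

## Simulation sizes

Simulation studies scale the 1000-iteration bootstrap down to 200
iterations per unit (coverage and power studies; intervals change
negligibly beyond ~200 draws), and the full pipeline retains 1000 as its
default. The power study uses 50 pipeline repeats; the type-I study uses
1000 repeats of the inference layer driven by Gaussian draws with matched
sampling spread, which isolates the CI-exclusion rule itself.

## Known limitations

* Per-replicate bootstrap intervals are anti-conservative at six
  observations (see above); between-treatment inference is the robust layer.
* T_opt point estimates at noise sd 0.05/day have a sampling sd of
  ≈ 0.45 °C per unit — curve-derived traits from six points are noisy, and
  small planted contrasts (0.7 °C) sit near the detection limit of the
  30-unit design.
* The fitted `w` (niche width) is reported but should not be interpreted
  when, as here, the data do not cover the lower thermal limb.
* The Gaussian, homoscedastic error model is the analysis' assumption; rate
  variance in real assays may grow with the rate.
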