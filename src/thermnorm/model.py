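"""The thermal reaction norm model and per-replicate maximum-likelihood fits.

Growth rate as a function of temperature T is modelled with the left-skewed
unimodal form

    f(T) = a * exp(b*T) * [1 - ((T - z) / (w/2))**2]

where w is the thermal niche width (distance between the curve's two zeros,
the range of positive growth), and z, a, b jointly set the position and
height of the peak and the skew.  The curve is zero exactly at z - w/2 and
z + w/2; for b > 0 it rises slowly and crashes quickly above the optimum,
the canonical shape of phytoplankton thermal performance curves.

Derived traits:

* T_opt — argmax of f on [z - w/2, z + w/2], located numerically and
  validated each call against the stationarity condition
  b*u**2 + (4/w)*u - b = 0 with u = (T - z)/(w/2).
* T_max — upper zero of f, located by bracketed root finding and validated
  against the closed form z + w/2.
* mu_max — the highest *measured* growth rate (the fitted maximum is less
  trustworthy near the peak), with its assay temperature.

Fitting maximizes a Gaussian likelihood with constant variance, i.e. the
point estimates are nonlinear least squares; sigma is the residual MLE
sqrt(SSE/n).  The objective is multimodal, so a multi-start grid is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .data import GrowthRecord
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NonConvergenceError,
)

__all__ = [
    "ReactionNormParams",
    "ReactionNormFit",
    "ThermalTraits",
    "FitConfig",
    "eval_reaction_norm",
    "fit_reaction_norm",
    "derive_topt",
    "derive_tmax",
    "observed_mu_max",
    "derive_traits",
]


@dataclass(frozen=True)
class ReactionNormParams:
    """Parameters of the reaction norm plus the residual noise scale."""

    z: float  # deg C, location (midpoint of the two zeros)
    w: float  # deg C, thermal niche width, > 0
    a: float  # per day, scale, > 0
    b: float  # per deg C, exponential shape (skew)
    sigma: float = float("nan")  # per day, residual noise MLE

    def __post_init__(self):
        if not self.w > 0:
            raise InvalidParameterError(f"niche width w must be > 0, got {self.w}")
        if not self.a > 0:
            raise InvalidParameterError(f"scale a must be > 0, got {self.a}")
        if np.isfinite(self.sigma) and self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def t_min(self) -> float:
        """Lower zero of the curve, z - w/2."""
        return self.z - self.w / 2.0

    @property
    def t_max_analytic(self) -> float:
        """Upper zero of the curve, z + w/2."""
        return self.z + self.w / 2.0

    def as_array(self) -> np.ndarray:
        return np.array([self.z, self.w, self.a, self.b])


def eval_reaction_norm(params: ReactionNormParams, temp) -> np.ndarray | float:
    """Evaluate f(T); negative outside (z - w/2, z + w/2).

    ``temp`` may be a scalar or array (deg C); the return matches its shape.
    """
    return _eval(params.z, params.w, params.a, params.b, temp)


def _eval(z, w, a, b, temp):
    t = np.asarray(temp, dtype=float)
    u = (t - z) / (w / 2.0)
    out = a * np.exp(b * t) * (1.0 - u * u)
    return out if out.ndim else float(out)


def _jac(theta, t):
    """Jacobian of residuals wrt (z, w, a, b); rows are observations."""
    z, w, a, b = theta
    u = (t - z) / (w / 2.0)
    e = np.exp(b * t)
    bracket = 1.0 - u * u
    return np.column_stack(
        [
            4.0 * a * e * u / w,  # d/dz
            2.0 * a * e * u * u / w,  # d/dw
            e * bracket,  # d/da
            a * t * e * bracket,  # d/db
        ]
    )


@dataclass
class ThermalTraits:
    """Derived thermal traits for one replicate (or one bootstrap draw)."""

    t_opt: float  # deg C
    t_max: float  # deg C
    mu_max: float = float("nan")  # per day, highest measured rate
    mu_max_temp: float = float("nan")  # deg C, assay temp attaining it


@dataclass
class ReactionNormFit:
    """Maximum-likelihood fit of the reaction norm to one replicate."""

    params: ReactionNormParams
    temps: np.ndarray  # assay temperatures entering the fit
    observed: np.ndarray  # observed rates
    fitted_values: np.ndarray
    residuals: np.ndarray  # observed - fitted
    log_likelihood: float
    converged: bool
    n_obs: int
    start_points_tried: int

    def predict(self, temp):
        return eval_reaction_norm(self.params, temp)


@dataclass
class FitConfig:
    """Multi-start nonlinear least-squares settings.

    The start grid spans z over the observed temperature range (5 points),
    w in {10, 20, 30} deg C and b in {0.01, 0.05, 0.1, 0.2} per deg C, with a
    seeded from the maximum observed rate.  Starts are ranked by their initial
    sum of squares and the optimizer is run from the best ``max_starts``; set
    ``max_starts=None`` to run from the full grid.  Bounds keep the optimizer
    in a biologically meaningful region and are configurable.
    """

    w_starts: Sequence[float] = (10.0, 20.0, 30.0)
    b_starts: Sequence[float] = (0.01, 0.05, 0.1, 0.2)
    n_z_starts: int = 5
    max_starts: int | None = 12
    w_bounds: tuple[float, float] = (1.0, 60.0)
    a_bounds: tuple[float, float] = (1e-6, 10.0)
    b_bounds: tuple[float, float] = (-1.0, 1.0)
    z_margin: float = 20.0  # z bounds: observed range +/- margin
    extra_starts: tuple = field(default_factory=tuple)  # warm starts, tried first
    # try unconstrained Levenberg-Marquardt first and keep its solution when it
    # lands inside the bounds; much faster for warm starts near the optimum
    prefer_lm: bool = False


def _as_xy(records) -> tuple[np.ndarray, np.ndarray]:
    if records and isinstance(records[0], GrowthRecord):
        recs = [r for r in records if not r.censored]
        t = np.array([r.assay_temp for r in recs], float)
        y = np.array([r.growth_rate for r in recs], float)
    else:
        t, y = (np.asarray(v, float) for v in records)
    return t, y


def fit_reaction_norm(records, config: FitConfig | None = None) -> ReactionNormFit:
    """Fit the reaction norm to one replicate's (temperature, rate) data.

    ``records`` is either a sequence of :class:`GrowthRecord` (censored ones
    are skipped) or a ``(temps, rates)`` pair of arrays.

    Raises
    ------
    InsufficientDataError
        Fewer than 5 observations or fewer than 4 distinct temperatures.
    NonConvergenceError
        No start converged; diagnostics attached.
    """
    cfg = config or FitConfig()
    t, y = _as_xy(records)
    if t.size < 5:
        raise InsufficientDataError(
            f"need >= 5 observations to fit 4 curve parameters + noise, got {t.size}"
        )
    if np.unique(t).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct assay temperatures, got {np.unique(t).size}"
        )

    t_lo, t_hi = t.min(), t.max()
    lb = np.array([t_lo - cfg.z_margin, cfg.w_bounds[0], cfg.a_bounds[0], cfg.b_bounds[0]])
    ub = np.array([t_hi + cfg.z_margin, cfg.w_bounds[1], cfg.a_bounds[1], cfg.b_bounds[1]])
    y_max = max(float(y.max()), 1e-3)

    starts = [np.clip(np.asarray(s, float), lb, ub) for s in cfg.extra_starts]
    if cfg.max_starts is None or len(starts) < cfg.max_starts:
        for z0 in np.linspace(t_lo, t_hi, cfg.n_z_starts):
            for w0 in cfg.w_starts:
                for b0 in cfg.b_starts:
                    a0 = np.clip(y_max * np.exp(-b0 * z0), *cfg.a_bounds)
                    starts.append(np.clip([z0, w0, a0, b0], lb, ub))

    def sse(theta):
        r = _eval(*theta, t) - y
        return float(r @ r)

    if cfg.max_starts is not None and len(starts) > cfg.max_starts:
        keep = min(len(cfg.extra_starts), cfg.max_starts)
        grid = sorted(starts[keep:], key=sse)
        starts = starts[:keep] + grid[: max(cfg.max_starts - keep, 0)]

    def _solve(x0):
        if cfg.prefer_lm and np.all(x0 > lb) and np.all(x0 < ub):
            # unconstrained MINPACK Levenberg-Marquardt: cheap, and valid
            # whenever its solution stays inside the bounds
            x, _, _, _, ier = optimize.leastsq(
                lambda th: _eval(*th, t) - y, x0,
                Dfun=lambda th: _jac(th, t), full_output=True,
            )
            if ier in (1, 2, 3, 4) and np.all(np.isfinite(x)) and np.all(
                x >= lb
            ) and np.all(x <= ub):
                r = _eval(*x, t) - y
                return optimize.OptimizeResult(
                    x=x, cost=0.5 * float(r @ r), success=True, message="lm"
                )
        return optimize.least_squares(
            lambda th: _eval(*th, t) - y,
            x0,
            jac=lambda th: _jac(th, t),
            bounds=(lb, ub),
            method="trf",
            x_scale=[10.0, 10.0, max(y_max, 1e-2), 0.1],
        )

    best = None
    diagnostics = []
    for x0 in starts:
        try:
            sol = _solve(x0)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append((list(x0), repr(exc)))
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            diagnostics.append((list(x0), sol.message))
            continue
        cost = float(sol.cost)
        if (
            best is None
            or cost < best[0] - 1e-12
            or (abs(cost - best[0]) <= 1e-12
                and np.linalg.norm(sol.x) < np.linalg.norm(best[1]))
        ):
            best = (cost, sol.x)

    if best is None:
        raise NonConvergenceError(
            f"no start converged out of {len(starts)}", diagnostics
        )

    z, w, a, b = best[1]
    fitted = _eval(z, w, a, b, t)
    resid = y - fitted
    n = t.size
    sigma2 = float(resid @ resid) / n
    sigma = float(np.sqrt(sigma2))
    if sigma2 > 0:
        ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    else:
        ll = float("inf")  # perfect interpolation
    return ReactionNormFit(
        params=ReactionNormParams(float(z), float(w), float(a), float(b), sigma),
        temps=t,
        observed=y,
        fitted_values=fitted,
        residuals=resid,
        log_likelihood=ll,
        converged=True,
        n_obs=n,
        start_points_tried=len(starts),
    )


def topt_closed_form(params: ReactionNormParams) -> float:
    """Stationary point from the quadratic b*u^2 + (4/w)*u - b = 0.

    The root with the sign of b is the maximum inside the niche; b = 0 gives
    the symmetric-parabola limit T_opt = z.
    """
    b, w = params.b, params.w
    if b == 0.0:
        return params.z
    c = 4.0 / w
    u = (-c + np.sqrt(c * c + 4.0 * b * b)) / (2.0 * b)
    return params.z + (w / 2.0) * u


def derive_topt(params: ReactionNormParams, tolerance: float = 1e-6) -> float:
    """Optimum growth temperature: numerical argmax of f over the niche.

    Bounded scalar optimization on [z - w/2, z + w/2], cross-validated
    against the closed-form stationarity root with 1e-4 deg C slack.
    """
    lo, hi = params.t_min, params.t_max_analytic
    res = optimize.minimize_scalar(
        lambda T: -eval_reaction_norm(params, T),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tolerance},
    )
    t_opt = float(res.x)
    ref = topt_closed_form(params)
    if abs(t_opt - ref) > max(1e-4, 10 * tolerance):
        raise InvalidParameterError(
            f"numerical T_opt {t_opt:.6f} disagrees with stationarity root {ref:.6f}"
        )
    return t_opt


def derive_tmax(params: ReactionNormParams, tolerance: float = 1e-6) -> float:
    """Maximum persistence temperature: upper zero of f by bracketed root-finding.

    Validated against the closed form z + w/2 each call.
    """
    t_opt = derive_topt(params, tolerance)
    hi = params.t_max_analytic
    eps = max(1e-9, tolerance)
    t_max = float(
        optimize.brentq(
            lambda T: eval_reaction_norm(params, T),
            t_opt,
            hi + eps,
            xtol=tolerance,
        )
    )
    if abs(t_max - hi) > max(1e-4, 10 * tolerance):
        raise InvalidParameterError(
            f"numerical T_max {t_max:.6f} disagrees with z + w/2 = {hi:.6f}"
        )
    return t_max


def observed_mu_max(records) -> tuple[float, float]:
    """Highest measured growth rate and its assay temperature.

    Censored records are excluded; ties report the lowest qualifying
    temperature for determinism.
    """
    t, y = _as_xy(records)
    if t.size == 0:
        raise InsufficientDataError("no uncensored records to take the maximum over")
    best = float(y.max())
    return best, float(t[y == best].min())


def derive_traits(
    fit: ReactionNormFit, tolerance: float = 1e-6, with_mu_max: bool = True
) -> ThermalTraits:
    """Bundle T_opt, T_max and (optionally) observed mu_max for one fit."""
    t_opt = derive_topt(fit.params, tolerance)
    t_max = derive_tmax(fit.params, tolerance)
    if with_mu_max:
        mu, mu_t = observed_mu_max((fit.temps, fit.observed))
        return ThermalTraits(t_opt, t_max, mu, mu_t)
    return ThermalTraits(t_opt, t_max)
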