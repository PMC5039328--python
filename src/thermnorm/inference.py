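"""Treatment-effect inference on the thermal traits.

Each trait is modelled with an ordinary least-squares linear model

    trait ~ 1 + temp_high + pco2_std + temp_high : pco2_std

where ``temp_high`` indicates selection at the warm temperature (26.3 deg C;
the 15.0 deg C lines are the reference) and ``pco2_std`` is the pCO2 level
standardized by subtracting the mean and dividing by two sample standard
deviations, so its coefficient is directly comparable to the binary
temperature contrast.

For T_opt and T_max the model is fitted once per bootstrap iteration — for
iteration k, the 30 trait values are assembled from every unit's k-th draw —
and coefficient uncertainty is read off the percentile spread of the
resulting coefficient draws.  A coefficient is called significant when its
95% interval excludes zero; when the interaction is significant the main
effects are reported but flagged not interpretable.

mu_max uses a single OLS fit on the highest measured rates (no bootstrap)
with normal-theory t intervals on n - 4 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bootstrap import BootstrapTraitDistribution, trait_ci
from .errors import InvalidInputError, RankDeficientError

__all__ = [
    "COEF_NAMES",
    "CoefficientEstimate",
    "TraitEffectSummary",
    "standardize_pco2",
    "design_matrix",
    "fit_trait_lm",
    "bootstrap_trait_inference",
    "mu_max_inference",
    "summarize_traits_by_treatment",
]

COEF_NAMES = ("intercept", "temp_effect", "pco2_effect", "interaction")


def standardize_pco2(levels) -> np.ndarray:
    """Center pCO2 and divide by two sample standard deviations.

    The resulting predictor has mean 0 and SD 0.5 by construction, putting
    its regression coefficient on the same footing as a binary contrast.
    """
    x = np.asarray(levels, float)
    if np.unique(x).size < 2:
        raise InvalidInputError("pCO2 levels are constant; cannot standardize (zero SD)")
    sd = x.std(ddof=1)
    return (x - x.mean()) / (2.0 * sd)


def design_matrix(selection_temp, pco2, high_temp: float = 26.3) -> np.ndarray:
    """Columns (intercept, temp_high, pco2_std, temp_high * pco2_std)."""
    sel = np.asarray(selection_temp, float)
    temp_high = (np.abs(sel - high_temp) < 1e-6).astype(float)
    pco2_std = standardize_pco2(pco2)
    return np.column_stack(
        [np.ones_like(temp_high), temp_high, pco2_std, temp_high * pco2_std]
    )


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the first column that adds no rank
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise RankDeficientError(
                    f"design matrix is rank deficient: column '{COEF_NAMES[j - 1]}' "
                    "is collinear with the preceding columns"
                )


def fit_trait_lm(X: np.ndarray, y) -> tuple[np.ndarray, float]:
    """OLS coefficients and adjusted R-squared for one trait vector."""
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 5:
        raise InvalidInputError(f"need >= 5 rows to fit 4 coefficients, got {n}")
    if not set(np.unique(X[:, 1])) >= {0.0, 1.0}:
        raise InvalidInputError("both selection temperatures must be present")
    _check_rank(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        adj_r2 = 1.0 if ss_res == 0.0 else -np.inf
    else:
        adj_r2 = 1.0 - (ss_res / (n - p)) / (ss_tot / (n - 1))
    return beta, float(adj_r2)


@dataclass
class CoefficientEstimate:
    """One model term: point value, 95% interval and the CI-exclusion call."""

    estimate: float
    ci_lower: float
    ci_upper: float
    significant: bool
    interpretable: bool = True


@dataclass
class TraitEffectSummary:
    """Coefficient table for one trait's linear model."""

    trait_name: str
    coefficients: dict[str, CoefficientEstimate]
    adjusted_r2: float
    interaction_masks_main_effects: bool
    n_bootstrap: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trait": self.trait_name,
                "term": name,
                "estimate": c.estimate,
                "ci_lo": c.ci_lower,
                "ci_hi": c.ci_upper,
                "significant": c.significant,
                "interpretable": c.interpretable,
            }
            for name, c in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


#: interval bounds within this distance of zero count as touching zero,
#: guarding the CI-exclusion rule against floating-point residue
ZERO_ATOL = 1e-10


def _build_summary(
    trait_name, estimates, cis, adj_r2, n_bootstrap
) -> TraitEffectSummary:
    coefs = {}
    for name, est, (lo, hi) in zip(COEF_NAMES, estimates, cis):
        coefs[name] = CoefficientEstimate(
            float(est), float(lo), float(hi),
            significant=(lo > ZERO_ATOL or hi < -ZERO_ATOL),
        )
    interaction_sig = coefs["interaction"].significant
    if interaction_sig:
        coefs["temp_effect"].interpretable = False
        coefs["pco2_effect"].interpretable = False
    return TraitEffectSummary(
        trait_name=trait_name,
        coefficients=coefs,
        adjusted_r2=float(adj_r2),
        interaction_masks_main_effects=interaction_sig,
        n_bootstrap=n_bootstrap,
    )


def bootstrap_trait_inference(
    distributions: dict[str, BootstrapTraitDistribution],
    design: pd.DataFrame,
    trait: str = "t_opt",
    level: float = 0.95,
) -> TraitEffectSummary:
    """Propagate per-unit bootstrap draws into LM coefficient intervals.

    Parameters
    ----------
    distributions : dict
        replicate_id -> :class:`BootstrapTraitDistribution`, all run with the
        same ``n_iter`` so iteration indices align.
    design : DataFrame
        One row per unit with columns replicate_id, selection_temp, pco2.
    trait : {"t_opt", "t_max"}
        Which derived trait's draws to model.

    For each iteration present in *every* unit (iterations where any unit's
    refit failed are dropped listwise, keeping the design balanced), the
    trait values are assembled and the LM fitted; percentile intervals of the
    coefficient draws give the significance calls.  Point coefficient values
    and adjusted R-squared come from the LM on the per-unit point estimates
    when ``design`` carries a column named after the trait, otherwise from
    the per-unit mean draws.
    """
    ids = list(design["replicate_id"].astype(str))
    missing = [i for i in ids if i not in distributions]
    if missing:
        raise InvalidInputError(f"no bootstrap distribution for unit(s) {missing}")
    dists = [distributions[i] for i in ids]
    n_iters = {d.n_iter for d in dists}
    if len(n_iters) != 1:
        raise InvalidInputError(f"misaligned bootstrap iteration counts: {sorted(n_iters)}")
    attr = {"t_opt": "t_opt_draws", "t_max": "t_max_draws"}[trait]

    common = dists[0].iterations
    for d in dists[1:]:
        common = np.intersect1d(common, d.iterations, assume_unique=True)
    if common.size < 20:
        raise InvalidInputError(
            f"only {common.size} iterations survived listwise alignment"
        )

    # units x common-iterations matrix of trait draws
    Y = np.empty((len(dists), common.size))
    for i, d in enumerate(dists):
        pos = np.searchsorted(d.iterations, common)
        Y[i] = getattr(d, attr)[pos]

    X = design_matrix(design["selection_temp"], design["pco2"])
    _check_rank(X)
    beta_draws = np.linalg.pinv(X) @ Y  # (4, n_common)

    if trait in design.columns:
        point = np.asarray(design[trait], float)
    else:
        point = Y.mean(axis=1)
    beta_point, adj_r2 = fit_trait_lm(X, point)
    cis = [trait_ci(beta_draws[j], level) for j in range(4)]
    return _build_summary(trait, beta_point, cis, adj_r2, int(common.size))


def mu_max_inference(
    design: pd.DataFrame, level: float = 0.95
) -> TraitEffectSummary:
    """Single OLS fit of mu_max on the design; t-based normal-theory CIs.

    ``design`` carries one row per unit with columns replicate_id,
    selection_temp, pco2 and mu_max (the highest measured rate).
    """
    X = design_matrix(design["selection_temp"], design["pco2"])
    y = np.asarray(design["mu_max"], float)
    if len(y) < 5:
        raise InvalidInputError(f"need >= 5 units, got {len(y)}")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=1.0 - level)
    return _build_summary(
        "mu_max", res.params, [tuple(ci[j]) for j in range(4)],
        res.rsquared_adj, 0,
    )


def summarize_traits_by_treatment(
    design: pd.DataFrame,
    distributions: dict[str, BootstrapTraitDistribution] | None = None,
    point_traits: pd.DataFrame | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Treatment-cell means of T_opt, T_max and mu_max with 95% intervals.

    For T_opt and T_max the cell mean's interval comes from the bootstrap:
    iteration k's cell mean is the mean of the member units' k-th draws, and
    the percentile interval of those means is reported.  For mu_max the
    interval is normal-theory across the replicates in the cell (t
    distribution, n_cell - 1 df), following the assumption of normality of
    the measured rates.
    """
    if point_traits is None:
        raise InvalidInputError("point_traits table is required")
    df = design.merge(point_traits, on="replicate_id")
    out = []
    from scipy import stats

    for (sel, pco2), cell in df.groupby(["selection_temp", "pco2"], sort=True):
        if len(cell) == 0:
            raise InvalidInputError(f"empty treatment cell ({sel}, {pco2})")
        row = {"selection_temp": sel, "pco2": pco2, "n": len(cell)}
        for trait in ("t_opt", "t_max"):
            row[f"{trait}_mean"] = float(cell[trait].mean())
            if distributions is not None:
                ids = list(cell["replicate_id"].astype(str))
                dists = [distributions[i] for i in ids]
                common = dists[0].iterations
                for d in dists[1:]:
                    common = np.intersect1d(common, d.iterations, assume_unique=True)
                draws = np.stack(
                    [
                        getattr(d, f"{trait}_draws")[
                            np.searchsorted(d.iterations, common)
                        ]
                        for d in dists
                    ]
                ).mean(axis=0)
                lo, hi = trait_ci(draws, level)
                row[f"{trait}_ci_lo"], row[f"{trait}_ci_hi"] = lo, hi
        mu = cell["mu_max"].to_numpy(float)
        row["mu_max_mean"] = float(mu.mean())
        if mu.size > 1:
            se = mu.std(ddof=1) / np.sqrt(mu.size)
            tcrit = stats.t.ppf(0.5 + level / 2.0, mu.size - 1)
            row["mu_max_ci_lo"] = float(mu.mean() - tcrit * se)
            row["mu_max_ci_hi"] = float(mu.mean() + tcrit * se)
        else:
            row["mu_max_ci_lo"] = row["mu_max_ci_hi"] = float(mu.mean())
        out.append(row)
    return pd.DataFrame(out)
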