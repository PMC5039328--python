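"""Static figure exports: fitted curves, treatment-mean traits, coefficients."""

from __future__ import annotations

import numpy as np

from .model import eval_reaction_norm


def plot_reaction_norms(fits: dict, units=None, ax=None, temp_grid=None):
    """Per-replicate fitted curves over their data points.

    ``fits`` maps replicate_id -> (ReactionNormFit, ThermalTraits) as
    produced by the pipeline.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for rid, (fit, _) in fits.items():
        t = fit.temps
        grid = temp_grid if temp_grid is not None else np.linspace(t.min() - 2, t.max() + 2, 200)
        curve = eval_reaction_norm(fit.params, grid)
        (line,) = ax.plot(grid, np.maximum(curve, np.nan), lw=1, alpha=0.7)
        ax.plot(t, fit.observed, "o", ms=3, color=line.get_color())
    ax.axhline(0.0, color="0.6", lw=0.5)
    ax.set_xlabel("assay temperature (deg C)")
    ax.set_ylabel("growth rate (per day)")
    return ax


def plot_coefficients(coefficients, ax=None):
    """Forest-style plot of standardized LM coefficients with 95% intervals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = coefficients[coefficients["term"] != "intercept"].reset_index(drop=True)
    y = np.arange(len(df))
    ax.errorbar(
        df["estimate"], y,
        xerr=[df["estimate"] - df["ci_lo"], df["ci_hi"] - df["estimate"]],
        fmt="o", capsize=3,
    )
    ax.axvline(0.0, color="0.6", lw=0.5)
    ax.set_yticks(y)
    ax.set_yticklabels(df["trait"] + ": " + df["term"])
    ax.set_xlabel("standardized coefficient")
    return ax
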