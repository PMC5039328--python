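"""Synthetic assay datasets with the statistical structure the analysis assumes.

The generator emulates the factorial design of the selection experiment: two
selection temperatures (15.0 / 26.3 deg C) crossed with three pCO2 levels
(400 / 1100 / 2200 uatm), five replicate populations per cell, each assayed
at six temperatures (15, 18, 22, 24, 26, 27 deg C).  Each treatment cell has
a true reaction norm; replicates jitter around it (location and scale only),
observed rates add homoscedastic Gaussian noise on the rate scale, and
negative observations are floored at zero to mirror the measurement limit of
batch-culture growth assays.

Planted truths are specified via trait targets (lower/upper thermal limits,
optimum, peak rate), converted exactly to (z, w, a, b); the truth table the
generator returns carries both the parameters and the derived traits per
unit, so parameter-recovery and coverage studies need no refitting of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExperimentalUnit, GrowthRecord
from .errors import InvalidInputError, InvalidParameterError
from .model import ReactionNormParams, derive_topt, eval_reaction_norm

__all__ = [
    "ScenarioSpec",
    "params_from_traits",
    "generate_dataset",
    "paper_like_scenario",
    "null_scenario",
]

DEFAULT_ASSAY_TEMPS = (15.0, 18.0, 22.0, 24.0, 26.0, 27.0)
DEFAULT_SELECTION_TEMPS = (15.0, 26.3)
DEFAULT_PCO2_LEVELS = (400.0, 1100.0, 2200.0)


def params_from_traits(
    t_min: float, t_max: float, t_opt: float, mu_peak: float
) -> ReactionNormParams:
    """Reaction-norm parameters hitting the given trait targets exactly.

    z and w follow from the two zeros; b from the stationarity condition at
    the requested optimum; a from the requested peak rate.
    """
    if not t_min < t_opt < t_max:
        raise InvalidParameterError(
            f"need t_min < t_opt < t_max, got {t_min}, {t_opt}, {t_max}"
        )
    if not mu_peak > 0:
        raise InvalidParameterError(f"peak rate must be positive, got {mu_peak}")
    z = 0.5 * (t_min + t_max)
    w = t_max - t_min
    u = (t_opt - z) / (w / 2.0)
    b = (4.0 / w) * u / (1.0 - u * u) if u != 0.0 else 0.0
    a = mu_peak * np.exp(-b * t_opt) / (1.0 - u * u)
    return ReactionNormParams(z=z, w=w, a=float(a), b=float(b), sigma=0.0)


@dataclass
class ScenarioSpec:
    """Full description of one synthetic experiment."""

    cell_params: dict[tuple[float, float], ReactionNormParams]
    n_replicates: int = 5
    assay_temps: tuple = DEFAULT_ASSAY_TEMPS
    noise_sd: float = 0.05  # per day, Gaussian on the rate scale
    z_jitter_sd: float = 0.1  # deg C, between-replicate shift of z
    a_jitter_frac: float = 0.02  # multiplicative spread of a
    truncate_negative: bool = True
    name: str = "custom"

    def __post_init__(self):
        if not self.cell_params:
            raise InvalidInputError("cell_params must not be empty")
        for key, p in self.cell_params.items():
            if not isinstance(p, ReactionNormParams):
                raise InvalidInputError(f"cell {key}: expected ReactionNormParams")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if self.noise_sd < 0 or self.z_jitter_sd < 0 or self.a_jitter_frac < 0:
            raise InvalidInputError("noise and jitter scales must be >= 0")

    @property
    def selection_temps(self):
        return tuple(sorted({k[0] for k in self.cell_params}))

    @property
    def pco2_levels(self):
        return tuple(sorted({k[1] for k in self.cell_params}))

    @property
    def n_units(self) -> int:
        return len(self.cell_params) * self.n_replicates

    @property
    def n_records(self) -> int:
        return self.n_units * len(self.assay_temps)


def generate_dataset(
    spec: ScenarioSpec, seed: int = 0
) -> tuple[list[ExperimentalUnit], pd.DataFrame]:
    """Draw one dataset; returns (units, truth table).

    Per unit, true parameters are the cell's parameters with replicate
    jitter applied to z (additive Gaussian) and a (multiplicative
    lognormal-free Gaussian factor, floored at 10% of nominal); the observed
    rate at each assay temperature is the true curve value plus
    N(0, noise_sd), floored at zero when ``truncate_negative``.  Identical
    (spec, seed) pairs give identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0xA55A)))
    units: list[ExperimentalUnit] = []
    truth_rows = []
    for (sel, pco2), base in sorted(spec.cell_params.items()):
        for rep in range(1, spec.n_replicates + 1):
            rid = f"S{sel:g}_C{pco2:g}_R{rep}"
            z = base.z + rng.normal(0.0, spec.z_jitter_sd)
            a_factor = max(1.0 + rng.normal(0.0, spec.a_jitter_frac), 0.1)
            true = ReactionNormParams(z=z, w=base.w, a=base.a * a_factor, b=base.b)
            curve = eval_reaction_norm(true, np.asarray(spec.assay_temps))
            obs = curve + rng.normal(0.0, spec.noise_sd, size=curve.size)
            if spec.truncate_negative:
                obs = np.maximum(obs, 0.0)
            records = [
                GrowthRecord(rid, sel, pco2, float(T), float(y))
                for T, y in zip(spec.assay_temps, obs)
            ]
            units.append(ExperimentalUnit(rid, sel, pco2, records))
            t_opt = derive_topt(true)
            truth_rows.append(
                {
                    "replicate_id": rid,
                    "selection_temp": sel,
                    "pco2": pco2,
                    "z": true.z,
                    "w": true.w,
                    "a": true.a,
                    "b": true.b,
                    "t_opt": t_opt,
                    "t_max": true.t_max_analytic,
                    "mu_peak": float(eval_reaction_norm(true, t_opt)),
                }
            )
    return units, pd.DataFrame(truth_rows)


def paper_like_scenario(
    noise_sd: float = 0.05, n_replicates: int = 5
) -> ScenarioSpec:
    """Scenario whose planted traits follow the study's headline patterns.

    Low-temperature-selected lines: T_opt 21.3 deg C throughout, T_max
    falling from 28 deg C at ambient pCO2 to 27 / 26 deg C at 1100 / 2200
    uatm, peak rates declining steeply with pCO2.  High-temperature-selected
    lines: T_opt 22.0 deg C, T_max 28.7 deg C flat in pCO2, peak rates
    declining more gently.  The planted between-selection T_opt difference is
    exactly 0.7 deg C; the lower thermal limit is set to 4 deg C everywhere
    (the assay design carries no information below 15 deg C).
    """
    targets = {
        # (selection_temp, pco2): (t_min, t_max, t_opt, mu_peak)
        (15.0, 400.0): (4.0, 28.0, 21.3, 1.00),
        (15.0, 1100.0): (4.0, 27.0, 21.3, 0.93),
        (15.0, 2200.0): (4.0, 26.0, 21.3, 0.81),
        (26.3, 400.0): (4.0, 28.7, 22.0, 0.87),
        (26.3, 1100.0): (4.0, 28.7, 22.0, 0.83),
        (26.3, 2200.0): (4.0, 28.7, 22.0, 0.78),
    }
    cells = {key: params_from_traits(*tgt) for key, tgt in targets.items()}
    return ScenarioSpec(
        cell_params=cells,
        n_replicates=n_replicates,
        noise_sd=noise_sd,
        name="paper_like",
    )


def null_scenario(noise_sd: float = 0.05, n_replicates: int = 5) -> ScenarioSpec:
    """Same design, identical reaction norm in every cell (no true effects)."""
    base = params_from_traits(4.0, 28.0, 21.5, 0.9)
    cells = {
        (sel, pco2): base
        for sel in DEFAULT_SELECTION_TEMPS
        for pco2 in DEFAULT_PCO2_LEVELS
    }
    return ScenarioSpec(
        cell_params=cells, n_replicates=n_replicates, noise_sd=noise_sd, name="null"
    )
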