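"""End-to-end orchestration: censor -> fit -> bootstrap -> linear models.

`run_full_pipeline` executes the whole analysis on a dataset (read from an
assay table or drawn from a synthetic scenario) and writes:

* ``fits.json`` — per-replicate parameters, traits, residuals, convergence
  metadata;
* ``bootstrap_draws.csv`` — columnar draws (replicate_id, iteration, z, w,
  a, b, t_opt, t_max);
* ``coefficients.csv`` — tidy coefficient table for T_opt, T_max, mu_max;
* ``treatment_means.csv`` — per-treatment-cell trait means with intervals;
* ``manifest.json`` — everything needed to reproduce the run bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import BootstrapTraitDistribution, residual_bootstrap, trait_ci
from .data import ExperimentalUnit, censor_no_growth, read_assay_table, units_to_frame
from .errors import ThermnormError, UndefinedFitnessError
from .inference import (
    bootstrap_trait_inference,
    mu_max_inference,
    summarize_traits_by_treatment,
)
from .model import FitConfig, derive_traits, fit_reaction_norm
from .simulate import generate_dataset, paper_like_scenario

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "PipelineResult",
    "run_full_pipeline",
    "compute_relative_fitness",
    "fits_to_json",
]


@dataclass
class PipelineConfig:
    """All knobs of one analysis run; the manifest records them verbatim."""

    input_path: str | None = None  # assay table; exclusive with scenario
    scenario: str | None = None  # "paper_like" or None
    seed: int = 0
    n_iter: int = 1000
    bootstrap_mode: str = "permute"
    censor_mode: str = "or"
    level: float = 0.95
    outdir: str | None = None
    noise_sd: float = 0.05  # scenario-only


@dataclass
class RunManifest:
    config: dict
    software_version: str
    n_units: int
    n_records_in: int
    n_records_censored: int
    n_records_fitted: int
    n_bootstrap_failures: int
    output_files: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    fits: dict
    distributions: dict[str, BootstrapTraitDistribution]
    traits: pd.DataFrame  # per-unit point traits
    coefficients: pd.DataFrame
    treatment_means: pd.DataFrame
    summaries: dict


def compute_relative_fitness(rate_selected: float, rate_control: float) -> float:
    """Relative fitness as the quotient of exponential growth rates.

    Undefined when the control (reference) rate is not positive — e.g. when
    no growth is observed in the reference lines at the assay temperature.
    """
    if not rate_control > 0:
        raise UndefinedFitnessError(
            f"relative fitness undefined: reference rate {rate_control} <= 0"
        )
    return float(rate_selected) / float(rate_control)


def fits_to_json(fits: dict, seed: int) -> str:
    """Serialize per-replicate fits (params, traits, residuals, metadata)."""
    payload = {"software_version": __version__, "seed": seed, "replicates": {}}
    for rid, (fit, traits) in fits.items():
        payload["replicates"][rid] = {
            "params": dataclasses.asdict(fit.params),
            "traits": dataclasses.asdict(traits),
            "temps": fit.temps.tolist(),
            "observed": fit.observed.tolist(),
            "fitted_values": fit.fitted_values.tolist(),
            "residuals": fit.residuals.tolist(),
            "log_likelihood": fit.log_likelihood,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "start_points_tried": fit.start_points_tried,
        }
    return json.dumps(payload, indent=2, sort_keys=True)


def _load_units(config: PipelineConfig) -> tuple[list[ExperimentalUnit], pd.DataFrame | None]:
    if config.input_path is not None:
        units = read_assay_table(config.input_path)
        return units, None
    scenario = paper_like_scenario(noise_sd=config.noise_sd)
    units, truth = generate_dataset(scenario, seed=config.seed)
    return units, truth


def run_full_pipeline(
    config: PipelineConfig,
    units: list[ExperimentalUnit] | None = None,
    fit_config: FitConfig | None = None,
) -> PipelineResult:
    """Run censoring, per-replicate fits, bootstraps and trait inference.

    ``units`` may be passed directly (library use); otherwise they come from
    ``config.input_path`` or the named synthetic scenario.  Any stage error
    is re-raised annotated with the stage and replicate that failed.
    """
    truth = None
    if units is None:
        units, truth = _load_units(config)
    n_records_in = sum(len(u.records) for u in units)

    # --- censor ---------------------------------------------------------
    censored_units = [censor_no_growth(u, mode=config.censor_mode) for u in units]
    n_censored = sum(
        sum(r.censored for r in u.records) for u in censored_units
    )
    logger.info("stage=censor units=%d censored_records=%d", len(units), n_censored)

    # --- fit ------------------------------------------------------------
    fits = {}
    for u in censored_units:
        try:
            fit = fit_reaction_norm(u.active_records, fit_config)
            traits = derive_traits(fit)
        except ThermnormError as exc:
            raise type(exc)(f"stage=fit replicate={u.replicate_id}: {exc}") from exc
        fits[u.replicate_id] = (fit, traits)
    n_fitted = sum(f.n_obs for f, _ in fits.values())
    logger.info("stage=fit replicates=%d records=%d", len(fits), n_fitted)

    # --- bootstrap ------------------------------------------------------
    distributions = {}
    n_failures = 0
    for u in censored_units:
        fit, _ = fits[u.replicate_id]
        dist = residual_bootstrap(
            fit,
            n_iter=config.n_iter,
            seed=config.seed,
            mode=config.bootstrap_mode,
            replicate_id=u.replicate_id,
        )
        if not dist.reliable:
            logger.warning(
                "replicate %s: %d/%d bootstrap refits failed",
                u.replicate_id, dist.n_failed, dist.n_iter,
            )
        n_failures += dist.n_failed
        distributions[u.replicate_id] = dist
    logger.info("stage=bootstrap n_iter=%d failures=%d", config.n_iter, n_failures)

    # --- inference ------------------------------------------------------
    traits_df = pd.DataFrame(
        [
            {
                "replicate_id": u.replicate_id,
                "selection_temp": u.selection_temp,
                "pco2": u.pco2,
                "t_opt": fits[u.replicate_id][1].t_opt,
                "t_max": fits[u.replicate_id][1].t_max,
                "mu_max": fits[u.replicate_id][1].mu_max,
                "mu_max_temp": fits[u.replicate_id][1].mu_max_temp,
            }
            for u in censored_units
        ]
    )
    summaries = {
        "t_opt": bootstrap_trait_inference(
            distributions, traits_df, trait="t_opt", level=config.level
        ),
        "t_max": bootstrap_trait_inference(
            distributions, traits_df, trait="t_max", level=config.level
        ),
        "mu_max": mu_max_inference(traits_df, level=config.level),
    }
    coefficients = pd.concat(
        [s.to_frame() for s in summaries.values()], ignore_index=True
    )
    treatment_means = summarize_traits_by_treatment(
        traits_df[["replicate_id", "selection_temp", "pco2"]],
        distributions,
        traits_df[["replicate_id", "t_opt", "t_max", "mu_max"]],
        level=config.level,
    )
    logger.info("stage=infer traits=%s", list(summaries))

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        software_version=__version__,
        n_units=len(units),
        n_records_in=n_records_in,
        n_records_censored=n_censored,
        n_records_fitted=n_fitted,
        n_bootstrap_failures=n_failures,
    )

    result = PipelineResult(
        manifest=manifest,
        fits=fits,
        distributions=distributions,
        traits=traits_df,
        coefficients=coefficients,
        treatment_means=treatment_means,
        summaries=summaries,
    )
    if config.outdir is not None:
        _write_outputs(result, truth, Path(config.outdir), config)
    return result


def draws_to_frame(distributions: dict[str, BootstrapTraitDistribution]) -> pd.DataFrame:
    rows = []
    for rid, d in distributions.items():
        for i, k in enumerate(d.iterations):
            z, w, a, b = d.param_draws[i]
            rows.append(
                {
                    "replicate_id": rid, "iteration": int(k),
                    "z": z, "w": w, "a": a, "b": b,
                    "t_opt": d.t_opt_draws[i], "t_max": d.t_max_draws[i],
                    "mode": d.mode,
                }
            )
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, truth, outdir: Path, config: PipelineConfig):
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    files["fits"] = str(outdir / "fits.json")
    Path(files["fits"]).write_text(fits_to_json(result.fits, config.seed))

    files["draws"] = str(outdir / "bootstrap_draws.csv")
    draws_to_frame(result.distributions).to_csv(
        files["draws"], index=False, float_format="%.17g"
    )

    files["coefficients"] = str(outdir / "coefficients.csv")
    result.coefficients.to_csv(files["coefficients"], index=False, float_format="%.17g")

    files["treatment_means"] = str(outdir / "treatment_means.csv")
    result.treatment_means.to_csv(
        files["treatment_means"], index=False, float_format="%.17g"
    )

    files["traits"] = str(outdir / "traits.csv")
    result.traits.to_csv(files["traits"], index=False, float_format="%.17g")

    if truth is not None:
        files["truth"] = str(outdir / "truth.csv")
        truth.to_csv(files["truth"], index=False, float_format="%.17g")

    result.manifest.output_files = files
    (outdir / "manifest.json").write_text(result.manifest.to_json())
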