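"""Assay data model and tabular I/O.

The unit of observation is one specific daily growth rate mu = (ln N_d - ln
N_0)/d for a replicate population held at one assay temperature.  Thirty
replicate populations (2 selection temperatures x 3 pCO2 levels x 5
replicates) each assayed at six temperatures give the full factorial design.

Censoring follows the study's rule: where a strain shows no growth at either
26 or 27 deg C, the 27 deg C measurement is flagged censored, because a
measured zero stands in for an unmeasurable negative rate and would otherwise
drag the fitted upper limb of the reaction norm.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

#: Columns an assay table must provide, either with growth_rate directly or
#: with the raw-count triplet (n0, nd, duration) from which it is computed.
REQUIRED_COLUMNS = ("replicate_id", "selection_temp", "pco2", "assay_temp")
COUNT_COLUMNS = ("n0", "nd", "duration")


def compute_growth_rate(n0: float, nd: float, duration: float) -> float:
    """Specific daily growth rate mu = (ln nd - ln n0) / duration.

    Parameters
    ----------
    n0, nd : float
        Cell abundance at the start and end of the batch cycle (cells/mL or
        any common unit; only the ratio matters).
    duration : float
        Length of the batch cycle in days.

    Returns
    -------
    float
        Growth rate per day. Negative if the culture shrank.
    """
    if not (n0 > 0 and nd > 0):
        raise InvalidInputError(f"cell counts must be positive, got n0={n0}, nd={nd}")
    if not duration > 0:
        raise InvalidInputError(f"duration must be positive, got {duration}")
    return (math.log(nd) - math.log(n0)) / duration


@dataclass
class GrowthRecord:
    """One growth-rate observation of one replicate population."""

    replicate_id: str
    selection_temp: float  # deg C, selection treatment (15.0 or 26.3)
    pco2: float  # uatm, CO2 treatment label
    assay_temp: float  # deg C
    growth_rate: float  # per day, >= 0 (negatives were not measurable)
    n0: float | None = None
    nd: float | None = None
    duration: float | None = None
    censored: bool = False

    def __post_init__(self):
        if not np.isfinite(self.assay_temp):
            raise InvalidInputError(
                f"assay_temp must be finite, got {self.assay_temp!r}"
            )
        if self.growth_rate is None or not np.isfinite(self.growth_rate):
            raise InvalidInputError(
                f"growth_rate must be finite, got {self.growth_rate!r}"
            )
        if all(v is not None for v in (self.n0, self.nd, self.duration)):
            implied = compute_growth_rate(self.n0, self.nd, self.duration)
            if not math.isclose(implied, self.growth_rate, rel_tol=1e-6, abs_tol=1e-9):
                raise InvalidInputError(
                    f"growth_rate {self.growth_rate} inconsistent with counts "
                    f"(implied {implied:.6g}) for replicate {self.replicate_id} "
                    f"at {self.assay_temp} deg C"
                )


@dataclass
class ExperimentalUnit:
    """One replicate population with its growth records across assay temperatures."""

    replicate_id: str
    selection_temp: float
    pco2: float
    records: list[GrowthRecord] = field(default_factory=list)

    def __post_init__(self):
        seen: set[float] = set()
        for rec in self.records:
            if (rec.selection_temp, rec.pco2) != (self.selection_temp, self.pco2):
                raise SchemaError(
                    f"record treatment labels {(rec.selection_temp, rec.pco2)} "
                    f"disagree with unit {self.replicate_id} "
                    f"{(self.selection_temp, self.pco2)}"
                )
            if rec.assay_temp in seen:
                raise SchemaError(
                    f"duplicate assay_temp {rec.assay_temp} in unit {self.replicate_id}"
                )
            seen.add(rec.assay_temp)

    @property
    def active_records(self) -> list[GrowthRecord]:
        """Records entering the fit (censored ones excluded)."""
        return [r for r in self.records if not r.censored]

    def record_at(self, temp: float, tol: float = 0.5) -> GrowthRecord | None:
        """The record whose assay temperature is within ``tol`` of ``temp``."""
        best, best_d = None, tol
        for rec in self.records:
            d = abs(rec.assay_temp - temp)
            if d <= best_d:
                best, best_d = rec, d
        return best


def censor_no_growth(
    unit: ExperimentalUnit,
    mode: str = "or",
    temp_tol: float = 0.5,
) -> ExperimentalUnit:
    """Flag the 27 deg C record censored when the strain shows no growth there.

    ``mode="or"`` (default) removes the 27 deg C measurement when the growth
    rate at 26 deg C is <= 0 *or* the rate at 27 deg C is <= 0 — the literal
    reading of the rule.  ``mode="and"`` requires no growth at both.  Records
    are never dropped: the flag is set and downstream fitting skips flagged
    records, so both views remain writable.

    Idempotent: censoring an already-censored unit changes nothing.
    """
    if mode not in ("or", "and"):
        raise InvalidInputError(f"censor mode must be 'or' or 'and', got {mode!r}")
    r26 = unit.record_at(26.0, temp_tol)
    r27 = unit.record_at(27.0, temp_tol)
    if r26 is None or r27 is None:
        return unit  # rule vacuously skipped
    no26 = r26.growth_rate <= 0
    no27 = r27.growth_rate <= 0
    hit = (no26 or no27) if mode == "or" else (no26 and no27)
    if not hit or r27.censored:
        return unit
    new_records = [
        replace(rec, censored=True) if rec is r27 else replace(rec)
        for rec in unit.records
    ]
    logger.info(
        "censored 27 degC record of replicate %s (rate26=%.3g, rate27=%.3g, mode=%s)",
        unit.replicate_id, r26.growth_rate, r27.growth_rate, mode,
    )
    return ExperimentalUnit(
        unit.replicate_id, unit.selection_temp, unit.pco2, new_records
    )


def _units_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[ExperimentalUnit]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    has_rate = "growth_rate" in df.columns
    has_counts = all(c in df.columns for c in COUNT_COLUMNS)
    if not (has_rate or has_counts):
        raise SchemaError(
            f"{source}: need a growth_rate column or all of {COUNT_COLUMNS}"
        )

    units: dict[str, ExperimentalUnit] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # 1-based, after header
        d = row._asdict()
        try:
            counts = {
                c: (None if not has_counts or pd.isna(d.get(c)) else float(d[c]))
                for c in COUNT_COLUMNS
            }
            if has_rate and not pd.isna(d.get("growth_rate")):
                rate = float(d["growth_rate"])
            elif all(v is not None for v in counts.values()):
                rate = compute_growth_rate(**counts)
            else:
                raise SchemaError("no growth_rate and incomplete counts")
            if rate < 0:
                raise SchemaError(
                    f"negative growth_rate {rate}: negative rates are not measurable"
                )
            rec = GrowthRecord(
                replicate_id=str(d["replicate_id"]),
                selection_temp=float(d["selection_temp"]),
                pco2=float(d["pco2"]),
                assay_temp=float(d["assay_temp"]),
                growth_rate=rate,
                censored=bool(d.get("censored", False)),
                **counts,
            )
        except (ValueError, TypeError, SchemaError, InvalidInputError) as exc:
            raise SchemaError(f"{source}, row {rownum}: {exc}") from exc
        key = rec.replicate_id
        unit = units.get(key)
        if unit is None:
            units[key] = ExperimentalUnit(
                key, rec.selection_temp, rec.pco2, [rec]
            )
        else:
            if any(r.assay_temp == rec.assay_temp for r in unit.records):
                raise SchemaError(
                    f"{source}, row {rownum}: duplicate (replicate, assay_temp) "
                    f"pair ({key}, {rec.assay_temp})"
                )
            if (rec.selection_temp, rec.pco2) != (unit.selection_temp, unit.pco2):
                raise SchemaError(
                    f"{source}, row {rownum}: treatment labels change within "
                    f"replicate {key}"
                )
            unit.records.append(rec)
    return list(units.values())


def read_assay_table(path, sep: str | None = None) -> list[ExperimentalUnit]:
    """Read a CSV/TSV assay table into validated experimental units.

    Growth rates are filled from (n0, nd, duration) for rows where the
    growth_rate field is empty.  The delimiter is sniffed from the extension
    unless ``sep`` is given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise SchemaError(f"{path}: cannot parse as delimited text: {exc}") from exc
    return _units_from_frame(df, source=str(path))


def units_to_frame(units: Iterable[ExperimentalUnit]) -> pd.DataFrame:
    """Flatten units to the tidy one-row-per-record schema."""
    rows = []
    for u in units:
        for r in u.records:
            rows.append(
                {
                    "replicate_id": r.replicate_id,
                    "selection_temp": r.selection_temp,
                    "pco2": r.pco2,
                    "assay_temp": r.assay_temp,
                    "growth_rate": r.growth_rate,
                    "n0": r.n0,
                    "nd": r.nd,
                    "duration": r.duration,
                    "censored": r.censored,
                }
            )
    return pd.DataFrame(rows)


def write_assay_table(
    units: Iterable[ExperimentalUnit], path, sep: str | None = None,
    include_censored: bool = True,
) -> None:
    """Write units back to delimited text, full precision, round-trip safe."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = units_to_frame(units)
    if not include_censored:
        df = df[~df["censored"]]
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


#: Default mapping from PANGAEA-style export headers onto the assay schema.
PANGAEA_DEFAULT_MAPPING = {
    "replicate_id": "Replicate",
    "selection_temp": "Temp selection [degC]",
    "pco2": "pCO2 [uatm]",
    "assay_temp": "Temp assay [degC]",
    "growth_rate": "Growth rate [1/day]",
}


def read_pangaea_table(path, mapping: dict[str, str] | None = None) -> list[ExperimentalUnit]:
    """Import a PANGAEA tab-delimited export via a column-mapping config.

    ``mapping`` sends assay-schema column names to the export's headers;
    unmapped optional columns are ignored.
    """
    mapping = {**PANGAEA_DEFAULT_MAPPING, **(mapping or {})}
    text = Path(path).read_text()
    if text.startswith("/*"):  # strip the metadata comment block
        end = text.find("*/")
        if end != -1:
            text = text[end + 2 :].lstrip("\n")
    df = pd.read_csv(io.StringIO(text), sep="\t", float_precision="round_trip")
    missing = [v for v in mapping.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"{path}: mapped column(s) not found: {missing}")
    renamed = df.rename(columns={v: k for k, v in mapping.items()})
    return _units_from_frame(renamed[list(mapping)], source=str(path))
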