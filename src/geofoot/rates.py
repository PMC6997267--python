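"""Crude prevalence and incidence rates, overall and per zone.

Two rate kinds are used downstream:

* crude prevalence-adjusted rate, in percent: 100 * cases / population at
  risk (the zone's diabetic population);
* incidence rate per 10,000 person-years under a closed-cohort
  approximation: 10000 * events / (population * window years).

Rates are computed and carried at full precision; the 1-decimal-place
rounding used in reports is applied only at formatting time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import OutcomeTable

PREVALENCE = "prevalence_percent"
INCIDENCE = "incidence_per_10k_per_year"

#: rate kind conventionally used for each outcome
OUTCOME_KIND = {
    "dfu": PREVALENCE,
    "lea": PREVALENCE,
    "death_after_dfu": INCIDENCE,
    "death_after_lea": INCIDENCE,
    "death_after_dfu_or_lea": INCIDENCE,
}


class RateError(ValueError):
    pass


def round1(x: float) -> float:
    """Round half away from zero to 1 decimal place (reporting convention)."""
    if np.isnan(x):
        return x
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


def prevalence_rate(numerator: int, denominator: int) -> float:
    """Crude prevalence-adjusted rate in percent: 100 * numerator / denominator.

    A zero denominator yields NaN (missing, not zero) with a warning.
    """
    if numerator < 0 or denominator < 0:
        raise RateError("counts must be non-negative")
    if numerator > denominator:
        raise RateError(f"numerator {numerator} exceeds denominator {denominator}")
    if denominator == 0:
        warnings.warn("prevalence_rate: zero denominator, returning missing value", stacklevel=2)
        return float("nan")
    return 100.0 * numerator / denominator


def incidence_rate(events: int, population: int, years: float) -> float:
    """Incidence per 10,000 per year: 10000 * events / (population * years).

    Person-time is approximated as population x window length (closed
    cohort); exact person-years are not modelled.
    """
    if events < 0 or population < 0:
        raise RateError("counts must be non-negative")
    if years <= 0:
        raise RateError(f"window length must be positive, got {years}")
    if population == 0:
        warnings.warn("incidence_rate: zero population, returning missing value", stacklevel=2)
        return float("nan")
    return 10000.0 * events / (population * years)


@dataclass
class RateTable:
    """Per-zone rates for one outcome, plus the pooled overall rate.

    ``data`` columns: zone_id, numerator, denominator, rate, flag. Flags:
    ``ok``, ``low_confidence`` (denominator below the minimum), ``missing``
    (zero denominator; rate is NaN, never silently 0).
    """

    kind: str
    overall: float
    window_years: float | None
    data: pd.DataFrame = field(repr=False)

    @property
    def values(self) -> np.ndarray:
        return self.data["rate"].to_numpy(dtype=float)

    @property
    def zone_ids(self) -> np.ndarray:
        return self.data["zone_id"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["rate_1dp"] = out["rate"].map(round1)
        out.to_csv(path, index=False)


def zone_rates(table: OutcomeTable, min_denominator: int = 5, years: float | None = None) -> RateTable:
    """Zone-wise rates from an OutcomeTable.

    The rate kind follows the outcome (prevalence for DFU/LEA, incidence
    for the mortality outcomes); incidence uses the table's window length
    unless ``years`` overrides it. Zones with denominators below
    ``min_denominator`` are flagged low-confidence but still computed; zero
    denominators become missing values.
    """
    kind = OUTCOME_KIND[table.outcome]
    d = table.data
    num = d["numerator"].to_numpy(dtype=float)
    den = d["denominator"].to_numpy(dtype=float)
    if kind == INCIDENCE:
        wyears = float(years) if years is not None else table.window.years
        if wyears <= 0:
            raise RateError("window length must be positive")
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(den > 0, 10000.0 * num / (den * wyears), np.nan)
        overall = incidence_rate(table.numerator_total, table.denominator_total, wyears)
    else:
        wyears = None
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(den > 0, 100.0 * num / den, np.nan)
        overall = prevalence_rate(table.numerator_total, table.denominator_total)
    flag = np.where(den == 0, "missing", np.where(den < min_denominator, "low_confidence", "ok"))
    if (den == 0).any():
        warnings.warn(
            f"{int((den == 0).sum())} zone(s) with zero denominator flagged missing", stacklevel=2
        )
    data = pd.DataFrame(
        {
            "zone_id": d["zone_id"].to_numpy(),
            "numerator": d["numerator"].to_numpy(),
            "denominator": d["denominator"].to_numpy(),
            "rate": rate,
            "flag": flag,
        }
    )
    return RateTable(kind=kind, overall=overall, window_years=wyears, data=data)
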