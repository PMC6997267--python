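"""Cohort records and per-zone outcome aggregation.

Turns individual-level records (one row per person with diabetes, with
dated foot-ulcer, amputation and death events) into per-zone
numerator/denominator tables for a given outcome and analysis window.

Outcome semantics follow the clinical definitions of the study setting:

* ``dfu`` — any previous or active diabetic foot ulcer (history-based per
  SIGN-116 risk stratification), so a DFU dated before the window start
  still counts for a person in the window denominator;
* ``lea`` — any lower-extremity amputation, major and minor pooled;
* ``death_after_dfu`` / ``death_after_lea`` / ``death_after_dfu_or_lea`` —
  death within the window preceded (strictly earlier or same date) by the
  named event.

Windows: the full registry window runs 2002-01-01 to 2016-11-07; the DFU
prevalence window is restricted to 2012-01-01 to 2016-11-07 because foot
screening coverage only became complete towards the end of 2011.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .zones import ZoneSet

OUTCOMES = ("dfu", "lea", "death_after_dfu", "death_after_lea", "death_after_dfu_or_lea")

COHORT_COLUMNS = ("person_id", "zone_id", "entry_date", "dfu_date", "lea_date", "lea_level", "death_date")
_DATE_COLUMNS = ("entry_date", "dfu_date", "lea_date", "death_date")

FULL_WINDOW_YEARS = 14.0  # closed-cohort person-time convention for 2002-2016


class CohortError(ValueError):
    """Invalid cohort records or aggregation request."""


@dataclass(frozen=True)
class AnalysisWindow:
    """A labelled date window for aggregation."""

    label: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        if self.start >= self.end:
            raise CohortError(f"window start {self.start} must precede end {self.end}")

    @classmethod
    def full(cls) -> "AnalysisWindow":
        return cls("full", pd.Timestamp("2002-01-01"), pd.Timestamp("2016-11-07"))

    @classmethod
    def dfu_subset(cls) -> "AnalysisWindow":
        return cls("dfu_subset", pd.Timestamp("2012-01-01"), pd.Timestamp("2016-11-07"))

    @property
    def years(self) -> float:
        """Window length in years; the full registry window uses the
        conventional 14-year span."""
        if self.label == "full":
            return FULL_WINDOW_YEARS
        return (self.end - self.start).days / 365.25


@dataclass
class PersonRecord:
    """One cohort member with zone assignment and dated events."""

    person_id: str
    zone_id: object
    entry_date: pd.Timestamp
    dfu_date: pd.Timestamp | None = None
    lea_date: pd.Timestamp | None = None
    lea_level: str | None = None  # "major" | "minor"
    death_date: pd.Timestamp | None = None

    def __post_init__(self):
        for name in _DATE_COLUMNS:
            v = getattr(self, name)
            setattr(self, name, None if v is None or pd.isna(v) else pd.Timestamp(v))
        self.validate()

    def validate(self) -> None:
        if self.lea_level is not None and self.lea_level not in ("major", "minor"):
            raise CohortError(f"person {self.person_id}: lea_level must be 'major' or 'minor', got {self.lea_level!r}")
        if self.death_date is not None and not pd.isna(self.death_date):
            for name in ("entry_date", "dfu_date", "lea_date"):
                v = getattr(self, name)
                if v is not None and not pd.isna(v) and self.death_date < v:
                    raise CohortError(
                        f"person {self.person_id}: death_date {self.death_date.date()} precedes {name} "
                        f"{pd.Timestamp(v).date()}"
                    )

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in COHORT_COLUMNS}


def cohort_frame(records: Iterable[PersonRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalise records into the canonical cohort DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.to_dict() for r in records], columns=COHORT_COLUMNS)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort frame missing columns: {missing}")
    for c in _DATE_COLUMNS:
        df[c] = pd.to_datetime(df[c])
    return df.reset_index(drop=True)


def validate_cohort(df: pd.DataFrame, zones: ZoneSet) -> None:
    """Check record invariants: known zones; death not before any event."""
    zones.validate_zone_ids(df["zone_id"].unique())
    has_death = df["death_date"].notna()
    for col in ("entry_date", "dfu_date", "lea_date"):
        bad = has_death & df[col].notna() & (df["death_date"] < df[col])
        if bad.any():
            ids = df.loc[bad, "person_id"].tolist()[:10]
            raise CohortError(f"death_date precedes {col} for persons {ids}")


@dataclass
class OutcomeTable:
    """Per-zone numerator/denominator counts for one outcome and window."""

    outcome: str
    window: AnalysisWindow
    data: pd.DataFrame = field(repr=False)  # columns: zone_id, numerator, denominator

    def __post_init__(self):
        d = self.data
        if (d["numerator"] > d["denominator"]).any():
            raise CohortError("numerator exceeds denominator in OutcomeTable")
        if (d["numerator"] < 0).any():
            raise CohortError("negative numerator")

    @property
    def numerator_total(self) -> int:
        return int(self.data["numerator"].sum())

    @property
    def denominator_total(self) -> int:
        return int(self.data["denominator"].sum())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def aggregate(
    records: Iterable[PersonRecord] | pd.DataFrame,
    zones: ZoneSet,
    outcome: str,
    window: AnalysisWindow | None = None,
) -> OutcomeTable:
    """Aggregate individual records into a per-zone OutcomeTable.

    The denominator is every person registered by the window end
    (``entry_date <= window.end``). Numerator rules:

    * ``dfu`` / ``lea``: any event dated on or before the window end
      (history counts), person in the denominator. DFU prevalence must be
      computed on the ``dfu_subset`` window (screening coverage).
    * ``death_after_*``: death within the window with a prior (<= death
      date) qualifying event.

    Each person counts at most once per outcome.
    """
    if outcome not in OUTCOMES:
        raise CohortError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if window is None:
        window = AnalysisWindow.dfu_subset() if outcome == "dfu" else AnalysisWindow.full()
    if outcome == "dfu" and window.label != "dfu_subset":
        raise CohortError(
            "DFU prevalence must use the dfu_subset window (2012-01-01 to 2016-11-07): "
            "foot-screening coverage is incomplete before 2012"
        )
    df = cohort_frame(records)
    validate_cohort(df, zones)

    in_denom = df["entry_date"] <= window.end

    dfu_by_end = df["dfu_date"].notna() & (df["dfu_date"] <= window.end)
    lea_by_end = df["lea_date"].notna() & (df["lea_date"] <= window.end)
    death_in_win = df["death_date"].notna() & (df["death_date"] >= window.start) & (df["death_date"] <= window.end)
    dfu_before_death = df["dfu_date"].notna() & df["death_date"].notna() & (df["dfu_date"] <= df["death_date"])
    lea_before_death = df["lea_date"].notna() & df["death_date"].notna() & (df["lea_date"] <= df["death_date"])

    if outcome == "dfu":
        num = dfu_by_end
    elif outcome == "lea":
        num = lea_by_end
    elif outcome == "death_after_dfu":
        num = death_in_win & dfu_before_death
    elif outcome == "death_after_lea":
        num = death_in_win & lea_before_death
    else:  # death_after_dfu_or_lea
        num = death_in_win & (dfu_before_death | lea_before_death)
    num = num & in_denom

    order = pd.CategoricalDtype(categories=list(zones.zone_ids), ordered=True)
    zid = df["zone_id"].astype(order)
    denom_counts = zid[in_denom].value_counts(sort=False).reindex(order.categories, fill_value=0)
    num_counts = zid[num].value_counts(sort=False).reindex(order.categories, fill_value=0)
    data = pd.DataFrame(
        {
            "zone_id": zones.zone_ids,
            "numerator": num_counts.to_numpy(dtype=np.int64),
            "denominator": denom_counts.to_numpy(dtype=np.int64),
        }
    )
    return OutcomeTable(outcome=outcome, window=window, data=data)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (ISO-8601 dates, empty field = no event)."""
    df = pd.read_csv(path, dtype={"person_id": str, "zone_id": str, "lea_level": "object"})
    return cohort_frame(df)


def write_cohort_csv(df: pd.DataFrame | Sequence[PersonRecord], path) -> None:
    df = cohort_frame(df)
    out = df.copy()
    for c in _DATE_COLUMNS:
        out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
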