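"""Deprivation-quintile association via the one-sample chi-squared test.

Hot-spot and cold-spot zones (significance tiers pooled) are counted per
multiple-deprivation quintile and tested against expected proportions with
the one-sample (goodness-of-fit) chi-squared statistic

    X^2 = sum_q (O_q - E_q)^2 / E_q,   E_q = N * pi_q,   df = 4.

Two expected models are supported: ``"zones"`` (default) takes pi_q as
each quintile's share of data zones — spots are zone-level events and the
quintiles need not hold equal numbers of zones within one health board —
and ``"uniform"`` takes pi_q = 1/5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .zones import ZoneSet

N_QUINTILES = 5


class AssociationError(ValueError):
    pass


@dataclass
class QuintileCounts:
    """Observed counts per deprivation quintile with expected proportions."""

    counts: np.ndarray  # shape (5,), quintile 1 first
    expected_proportions: np.ndarray  # shape (5,), sums to 1
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.expected_proportions = np.asarray(self.expected_proportions, dtype=float)
        if self.counts.shape != (N_QUINTILES,) or self.expected_proportions.shape != (N_QUINTILES,):
            raise AssociationError("exactly 5 quintile entries required")
        if (self.counts < 0).any():
            raise AssociationError("counts must be non-negative")
        if not np.isclose(self.expected_proportions.sum(), 1.0):
            raise AssociationError("expected proportions must sum to 1")


@dataclass
class ChiSquareResult:
    """One-sample chi-squared test result."""

    statistic: float
    df: int
    pvalue: float
    observed: np.ndarray
    expected: np.ndarray
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "unit": self.label,
            "observed": [float(v) for v in self.observed],
            "expected": [float(v) for v in self.expected],
            "chi2": float(self.statistic),
            "df": int(self.df),
            "p": float(self.pvalue),
        }


def zone_quintile_proportions(zones: ZoneSet) -> np.ndarray:
    """Each quintile's share of data zones, quintile 1 first."""
    q = zones.quintiles
    counts = np.array([(q == k).sum() for k in range(1, N_QUINTILES + 1)], dtype=float)
    return counts / counts.sum()


def quintile_counts(
    classification,
    zones: ZoneSet,
    which: str = "hot",
    expected: str = "zones",
) -> QuintileCounts:
    """Count hot (or cold) spot zones per deprivation quintile.

    ``classification`` is a zone_id -> bin mapping (a Series as produced by
    :class:`~geofoot.hotspot.HotspotResults`, or a DataFrame with zone_id
    and bin columns). All significance tiers of the requested class are
    pooled, matching the single hot/cold dichotomy used in reporting.
    """
    if which not in ("hot", "cold"):
        raise AssociationError(f"which must be 'hot' or 'cold', got {which!r}")
    if isinstance(classification, pd.DataFrame):
        bins = classification.set_index("zone_id")["bin"]
    else:
        bins = pd.Series(classification)
    if not zones.has_quintiles:
        raise AssociationError("zones have no deprivation quintiles assigned")
    quint = pd.Series(zones.quintiles, index=zones.zone_ids)
    missing = bins.index.difference(quint.index)
    if len(missing):
        raise AssociationError(f"classified zones missing a quintile: {list(missing[:10])}")
    selected = bins[bins.str.startswith(which + "_")]
    q_of_selected = quint.loc[selected.index].to_numpy()
    counts = np.array([(q_of_selected == k).sum() for k in range(1, N_QUINTILES + 1)], dtype=float)
    if expected == "zones":
        props = zone_quintile_proportions(zones)
    elif expected == "uniform":
        props = np.full(N_QUINTILES, 1.0 / N_QUINTILES)
    else:
        raise AssociationError(f"expected model must be 'zones' or 'uniform', got {expected!r}")
    return QuintileCounts(counts=counts, expected_proportions=props, label=f"{which}_spots")


def chi_square_one_sample(qc: QuintileCounts) -> ChiSquareResult:
    """One-sample chi-squared goodness-of-fit test on quintile counts.

    Raises (rather than returning NaN) when the total count is zero or any
    expected cell is zero — the statistic is undefined in both cases.
    """
    total = qc.counts.sum()
    if total <= 0:
        raise AssociationError(f"chi-squared undefined on zero total count ({qc.label or 'unlabelled'})")
    expected = total * qc.expected_proportions
    if (expected <= 0).any():
        raise AssociationError("chi-squared undefined with zero expected cells")
    stat = float(((qc.counts - expected) ** 2 / expected).sum())
    df = N_QUINTILES - 1
    p = float(stats.chi2.sf(stat, df))
    return ChiSquareResult(statistic=stat, df=df, pvalue=p, observed=qc.counts.copy(),
                           expected=expected, label=qc.label)
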