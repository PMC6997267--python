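"""Getis-Ord Gi* hot/cold-spot analysis.

For a value x_j observed on each of n zones and a binary symmetric weights
matrix w_ij with self-inclusion (w_ii = 1, the "star" variant), the local
statistic for zone i is the z-score

    z_i = (sum_j w_ij x_j - Xbar W_i) / (S * sqrt[(n S1_i - W_i^2) / (n - 1)])

with W_i = sum_j w_ij, S1_i = sum_j w_ij^2 (= W_i for binary weights),
Xbar = mean(x) and S = sqrt(mean(x^2) - Xbar^2) (population SD). Under the
usual normal approximation z_i is a standard-normal deviate: large positive
values mark zones embedded in neighbourhoods of high values (hot spots),
large negative values cold spots.

The modelling interface follows the Model/Results convention: build a
:class:`HotspotModel` from a per-zone value vector and a weights matrix,
call :meth:`~HotspotModel.fit`, and read z-scores, two-tailed p-values,
tiered confidence bins and summaries off the :class:`HotspotResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import ChiSquareResult, chi_square_one_sample, quintile_counts
from .rates import RateTable, round1
from .weights import WeightsMatrix
from .zones import ZoneSet

#: two-tailed |z| thresholds for the 90 / 95 / 99% confidence tiers
CONFIDENCE_THRESHOLDS = ((2.576, "99"), (1.960, "95"), (1.645, "90"))

HOT_BINS = ("hot_90", "hot_95", "hot_99")
COLD_BINS = ("cold_90", "cold_95", "cold_99")
ALL_BINS = ("hot_99", "hot_95", "hot_90", "not_significant", "cold_90", "cold_95", "cold_99")


class HotspotError(ValueError):
    pass


def gi_star(values, weights: WeightsMatrix, include_self: bool | None = None) -> np.ndarray:
    """Per-zone Getis-Ord Gi* z-scores.

    Parameters
    ----------
    values : array-like, shape (n,)
        One finite value per zone, ordered as the weights matrix.
    weights : WeightsMatrix
        Binary symmetric neighbour structure; its ``include_self`` flag
        selects Gi* (w_ii = 1, default) versus plain Gi.
    include_self : bool, optional
        Override the matrix's self-inclusion convention.

    Returns
    -------
    z : ndarray, shape (n,)
        Gi* z-scores. A constant value field has no spatial structure to
        standardise against; by convention all z are 0 then (with a
        warning). Zones whose neighbourhood spans the whole map (variance
        denominator 0) also get z = 0 — their local mean is the global mean.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise HotspotError(f"Gi* needs at least 3 zones, got {n}")
    if weights.n != n:
        raise HotspotError(f"weights universe ({weights.n}) does not match values ({n})")
    if not np.all(np.isfinite(x)):
        raise HotspotError("values must be finite; exclude missing zones first")

    w = weights.sparse(include_self=include_self)
    wi = np.asarray(w.sum(axis=1)).ravel()  # W_i
    s1 = np.asarray(w.multiply(w).sum(axis=1)).ravel()  # sum_j w_ij^2 (= W_i when binary)

    xbar = x.mean()
    s = np.sqrt(max((x * x).mean() - xbar * xbar, 0.0))
    if s == 0.0:
        warnings.warn("gi_star: constant value field, returning z = 0 for all zones", stacklevel=2)
        return np.zeros(n)

    num = w @ x - xbar * wi
    var = (n * s1 - wi * wi) / (n - 1)
    # var == 0 only when zone i neighbours every zone; numerator is then 0 too
    den = s * np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return z


def classify_spots(z, zone_ids=None) -> pd.DataFrame:
    """Bin Gi* z-scores into tiered two-tailed hot/cold-spot classes.

    Thresholds |z| >= 1.645 / 1.960 / 2.576 give 90 / 95 / 99% two-tailed
    confidence; a score exactly at a threshold takes the higher-confidence
    bin. Positive z = hot, negative z = cold.

    Returns a DataFrame with columns zone_id (if given), z, p (two-tailed
    normal) and bin.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise HotspotError("non-finite z-scores cannot be classified")
    absz = np.abs(z)
    bins = np.full(z.shape, "not_significant", dtype=object)
    for thr, tier in CONFIDENCE_THRESHOLDS:
        unset = bins == "not_significant"
        hit = unset & (absz >= thr)
        bins[hit & (z > 0)] = f"hot_{tier}"
        bins[hit & (z < 0)] = f"cold_{tier}"
    p = 2.0 * stats.norm.sf(absz)
    out = {"z": z, "p": p, "bin": bins}
    if zone_ids is not None:
        out = {"zone_id": np.asarray(zone_ids), **out}
    return pd.DataFrame(out)


def spot_summary(classification: pd.DataFrame) -> dict:
    """Counts and percentages of hot and cold zones (all tiers pooled).

    Percentages are of all classified zones, rounded half-away-from-zero
    to 1 decimal place as in reports.
    """
    bins = classification["bin"] if isinstance(classification, pd.DataFrame) else pd.Series(classification)
    total = len(bins)
    counts = bins.value_counts()
    n_hot = int(sum(counts.get(b, 0) for b in HOT_BINS))
    n_cold = int(sum(counts.get(b, 0) for b in COLD_BINS))
    pct = lambda k: round1(100.0 * k / total) if total else 0.0
    return {
        "n_zones": total,
        "hot": n_hot,
        "hot_percent": pct(n_hot),
        "cold": n_cold,
        "cold_percent": pct(n_cold),
        "not_significant": int(counts.get("not_significant", 0)),
        "by_bin": {b: int(counts.get(b, 0)) for b in ALL_BINS},
    }


class HotspotModel:
    """Gi* hot-spot model for one per-zone value vector.

    Parameters
    ----------
    values : array-like, shape (n,)
        The per-zone rate (or any interval-scale value). NaN entries mark
        zones excluded from the analysis: their weights rows are dropped
        before computation and the zone ids are reported on the results.
    weights : WeightsMatrix
        Neighbour structure over the same n zones.
    zone_ids : sequence, optional
        Identifiers aligned with ``values``; defaults to 0..n-1.
    """

    def __init__(self, values, weights: WeightsMatrix, zone_ids=None, include_self: bool = True):
        values = np.asarray(values, dtype=float)
        if weights.n != values.size:
            raise HotspotError(f"weights universe ({weights.n}) does not match values ({values.size})")
        self.zone_ids = np.arange(values.size, dtype=object) if zone_ids is None else np.asarray(zone_ids)
        self.values = values
        self.weights = weights
        self.include_self = include_self

    @classmethod
    def from_rates(cls, rate_table: RateTable, weights: WeightsMatrix, include_self: bool = True) -> "HotspotModel":
        """Build the model from a :class:`~geofoot.rates.RateTable`."""
        return cls(rate_table.values, weights, zone_ids=rate_table.zone_ids, include_self=include_self)

    def fit(self) -> "HotspotResults":
        """Compute Gi* z-scores and classify spots."""
        keep = np.isfinite(self.values)
        excluded = list(self.zone_ids[~keep])
        if excluded:
            warnings.warn(f"excluding {len(excluded)} zone(s) with missing values from Gi*", stacklevel=2)
        x = self.values[keep]
        w = self.weights.subset(np.flatnonzero(keep)) if excluded else self.weights
        z = gi_star(x, w, include_self=self.include_self)
        cls_df = classify_spots(z, zone_ids=self.zone_ids[keep])
        cls_df["value"] = x
        return HotspotResults(model=self, table=cls_df, excluded=excluded)


@dataclass
class HotspotResults:
    """Fitted Gi* classification: per-zone z, p and confidence bin."""

    model: HotspotModel
    table: pd.DataFrame = field(repr=False)  # zone_id, z, p, bin, value
    excluded: list = field(default_factory=list)

    @property
    def zscores(self) -> pd.Series:
        return self.table.set_index("zone_id")["z"]

    @property
    def pvalues(self) -> pd.Series:
        return self.table.set_index("zone_id")["p"]

    @property
    def bins(self) -> pd.Series:
        return self.table.set_index("zone_id")["bin"]

    def spot_summary(self) -> dict:
        return spot_summary(self.table)

    def quintile_association(self, zones: ZoneSet, which: str, expected: str = "zones") -> ChiSquareResult:
        """One-sample chi-squared test of hot (or cold) spot counts across
        deprivation quintiles. ``expected``: 'zones' (each quintile's share
        of data zones) or 'uniform'."""
        qc = quintile_counts(self.bins, zones, which=which, expected=expected)
        return chi_square_one_sample(qc)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        """Plain-text summary table in the Model/Results style."""
        s = self.spot_summary()
        lines = [
            "Getis-Ord Gi* hot-spot analysis",
            "=" * 46,
            f"zones analysed       {s['n_zones']:>8}",
            f"zones excluded       {len(self.excluded):>8}",
            f"weights scheme       {self.model.weights.scheme:>8}",
            f"hot spots (>=90%)    {s['hot']:>8}  ({s['hot_percent']}%)",
            f"cold spots (>=90%)   {s['cold']:>8}  ({s['cold_percent']}%)",
            "-" * 46,
        ]
        for b in ALL_BINS:
            lines.append(f"  {b:<18} {s['by_bin'][b]:>8}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, zones: ZoneSet, path=None, title: str | None = None):
        """Choropleth of the confidence bins (red hot / blue cold / grey)."""
        from .geo_io import render_map

        zs = zones.replace(extra={"bin": self.bins.reindex(zones.zone_ids, fill_value="not_significant").to_numpy()})
        return render_map(zs, field="bin", path=path, title=title)
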