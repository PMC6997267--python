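"""Synthetic geography and cohort generator.

The real study data — a health-board diabetes register linked to hospital
admissions and death records over ~1,460 census data zones — are held in an
NHS safe haven and cannot be redistributed. This module generates stand-in
data with the statistical structure the downstream analysis assumes:

* a contiguous tessellated geography whose polygons are smaller towards
  the map centre (urban) and larger towards the periphery (rural);
* zone populations with mean ~760 (the census data-zone design target);
* a spatially autocorrelated deprivation surface expressed as quintiles
  (1 = most deprived);
* per-zone outcome risks graded by deprivation quintile, with optional
  planted hot/cold clusters of known location for recovery experiments;
* an individual-level cohort drawn from those risks, with ~80% of
  amputations preceded by a foot ulcer and mortality only arising in
  people with ulcer or amputation history.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from shapely.geometry.polygon import orient

from .cohort import COHORT_COLUMNS, AnalysisWindow
from .weights import WeightsMatrix, neighbor_hops, queen_contiguity
from .zones import ZoneSet

#: (center zone index, radius in neighbour hops, risk multiplier)
PlantedCluster = tuple[int, int, float]

DEFAULT_QUINTILE_RELATIVE_RISKS = (2.5, 1.5, 1.0, 0.8, 0.6)
DEFAULT_BASE_RATES = {"dfu": 0.046, "lea": 0.013, "death": 0.30}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic geography and cohort.

    Attributes
    ----------
    n_zones : int
        Number of data zones (default 200; the study geography has 1,460).
    mean_population : float
        Mean diabetic population per zone (census design target 760).
    seed : int
        Master seed; all randomness derives from it.
    deprivation_smoothness : float
        Spatial correlation range of the latent deprivation score, as a
        fraction of the unit-square map width. 0 = independent zones.
    quintile_relative_risks : 5 floats
        Outcome risk multiplier per deprivation quintile, quintile 1
        (most deprived) first.
    planted_hot, planted_cold : list of (center, radius, multiplier)
        Clusters of excess (or deficit) risk planted on the risk surface;
        the cluster covers every zone within ``radius`` queen-contiguity
        hops of the center zone index.
    base_rates : mapping
        Baseline per-person probabilities: ``dfu`` (ulcer over the study
        period), ``lea`` (amputation), ``death`` (death given ulcer or
        amputation history).
    window : (int, int)
        Start and end calendar year of the registry window; the end date
        is the extraction date 7 Nov when the end year is 2016.
    population_cv : float
        Coefficient of variation of the lognormal zone-population draw.
    lea_dfu_coupling : float
        Probability that an amputation is preceded by a foot ulcer.
    center_concentration : float
        Exponent (> 1) pulling tessellation seeds towards the map centre,
        making peripheral zones systematically larger.
    """

    n_zones: int = 200
    mean_population: float = 760.0
    seed: int = 0
    deprivation_smoothness: float = 0.15
    quintile_relative_risks: Sequence[float] = DEFAULT_QUINTILE_RELATIVE_RISKS
    planted_hot: Sequence[PlantedCluster] = ()
    planted_cold: Sequence[PlantedCluster] = ()
    base_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    window: tuple[int, int] = (2002, 2016)
    population_cv: float = 0.3
    lea_dfu_coupling: float = 0.8
    center_concentration: float = 1.6

    def validate(self) -> "SimulationConfig":
        if self.n_zones < 10:
            raise SimulationError(f"n_zones must be >= 10, got {self.n_zones}")
        if self.mean_population <= 0:
            raise SimulationError("mean_population must be positive")
        if self.deprivation_smoothness < 0:
            raise SimulationError("deprivation_smoothness must be non-negative")
        rrs = tuple(self.quintile_relative_risks)
        if len(rrs) != 5:
            raise SimulationError(f"exactly 5 quintile relative risks required, got {len(rrs)}")
        if any(r <= 0 for r in rrs):
            raise SimulationError("quintile relative risks must be positive")
        for name, p in dict(self.base_rates).items():
            if not 0 < p < 1:
                raise SimulationError(f"base rate {name!r} must be in (0, 1), got {p}")
        for clusters in (self.planted_hot, self.planted_cold):
            for c, r, m in clusters:
                if m <= 0:
                    raise SimulationError("planted cluster multipliers must be positive")
                if r < 0:
                    raise SimulationError("planted cluster radius must be non-negative")
        if not 0 <= self.lea_dfu_coupling <= 1:
            raise SimulationError("lea_dfu_coupling must be a probability")
        if not 0 < self.population_cv:
            raise SimulationError("population_cv must be positive")
        return self

    def analysis_window(self) -> AnalysisWindow:
        y0, y1 = self.window
        start = pd.Timestamp(f"{y0}-01-01")
        end = pd.Timestamp("2016-11-07") if y1 == 2016 else pd.Timestamp(f"{y1}-12-31")
        return AnalysisWindow("full", start, end)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per pipeline stage
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def _seed_points(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Tessellation seeds in the unit square, denser towards the centre.

    Uniform draws are contracted towards 0.5 coordinate-wise with exponent
    ``center_concentration`` > 1, so central polygons are small (urban) and
    peripheral polygons large (rural).
    """
    u = rng.random((config.n_zones, 2))
    g = config.center_concentration
    return 0.5 + 0.5 * np.sign(u - 0.5) * np.abs(2.0 * u - 1.0) ** g


def _bounded_voronoi(points: np.ndarray) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the unit square.

    Cells are bounded by mirroring the points across all four square
    edges, so the cells of the original points exactly partition [0,1]^2.
    """
    reflections = [
        np.column_stack([-points[:, 0], points[:, 1]]),
        np.column_stack([2 - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], -points[:, 1]]),
        np.column_stack([points[:, 0], 2 - points[:, 1]]),
    ]
    vor = Voronoi(np.vstack([points] + reflections))
    square = box(0.0, 0.0, 1.0, 1.0)
    polys = []
    for i in range(points.shape[0]):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:  # pragma: no cover - cannot happen with mirrored points
            raise SimulationError("unbounded Voronoi cell despite mirroring")
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:  # pragma: no cover - safety net
            poly = poly.buffer(0)
        polys.append(orient(poly.intersection(square), sign=1.0))
    return polys


def generate_geography(config: SimulationConfig) -> ZoneSet:
    """Generate the synthetic zone geography with populations.

    A Voronoi tessellation of the unit square with centrally concentrated
    seeds; zone populations are lognormal with the configured mean and
    coefficient of variation, rounded to integers (minimum 1).
    """
    config.validate()
    rng = _rng(config, 1)
    points = _seed_points(config, rng)
    polys = _bounded_voronoi(points)
    sigma2 = np.log1p(config.population_cv**2)
    mu = np.log(config.mean_population) - sigma2 / 2.0
    pops = np.maximum(1, np.round(rng.lognormal(mu, np.sqrt(sigma2), config.n_zones))).astype(np.int64)
    ids = [f"Z{i:05d}" for i in range(config.n_zones)]
    return ZoneSet(ids, polys, populations=pops)


# ---------------------------------------------------------------------------
# deprivation surface
# ---------------------------------------------------------------------------

def assign_deprivation(zones: ZoneSet, smoothness: float, seed: int) -> ZoneSet:
    """Assign spatially autocorrelated deprivation quintiles.

    A latent score per zone is built as Gaussian noise smoothed with a
    Gaussian kernel of range ``smoothness`` (map-width fraction) over zone
    centroids — a cheap stand-in for a Gaussian random field. Scores are
    ranked highest-to-lowest and cut into five rank quintiles of equal
    size (within one zone); quintile 1 = most deprived = highest score.
    """
    if smoothness < 0:
        raise SimulationError("smoothness must be non-negative")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 2])
    n = zones.n
    noise = rng.standard_normal(n)
    if smoothness > 0:
        pts = zones.centroids()
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        k = np.exp(-d2 / (2.0 * smoothness**2))
        score = k @ noise
    else:
        score = noise
    # rank: highest score first; stable order for reproducibility
    order = np.argsort(-score, kind="stable")
    quintiles = np.empty(n, dtype=np.int64)
    splits = np.array_split(order, 5)
    for q, idx in enumerate(splits, start=1):
        quintiles[idx] = q
    return zones.replace(quintiles=quintiles, extra={"deprivation_score": score})


# ---------------------------------------------------------------------------
# risk surface
# ---------------------------------------------------------------------------

@dataclass
class RiskSurface:
    """Per-zone, per-outcome event probabilities.

    ``probabilities`` columns: zone_id, dfu, lea, death; every entry is a
    probability capped at 0.99 after multiplier stacking. Surfaces built
    from a config always have strictly positive entries (base rates live
    in (0, 1)); hand-built surfaces may set 0 to switch an outcome off.
    ``death`` is the probability of death *given* ulcer or amputation
    history.
    """

    probabilities: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        p = self.probabilities[["dfu", "lea", "death"]].to_numpy()
        if not ((p >= 0) & (p < 1)).all():
            raise SimulationError("risk surface probabilities must lie in [0, 1)")

    def prob(self, outcome: str) -> np.ndarray:
        return self.probabilities[outcome].to_numpy(dtype=float)


PROBABILITY_CAP = 0.99


def build_risk_surface(
    zones: ZoneSet,
    config: SimulationConfig,
    queen: WeightsMatrix | None = None,
) -> RiskSurface:
    """Per-zone outcome probabilities from base rates, quintile relative
    risks and planted clusters.

    A zone is covered by a planted cluster if it lies within the cluster's
    radius in queen-contiguity hops of its center zone (the contiguity
    graph is built from the zone polygons unless supplied). Multipliers
    stack multiplicatively and the result is capped at 0.99.
    """
    config.validate()
    if not zones.has_quintiles:
        raise SimulationError("assign deprivation quintiles before building the risk surface")
    n = zones.n
    rr = np.asarray(config.quintile_relative_risks, dtype=float)[zones.quintiles - 1]

    planted = np.ones(n)
    all_clusters = list(config.planted_hot) + list(config.planted_cold)
    if all_clusters:
        if queen is None:
            queen = queen_contiguity(zones)
        for center, radius, mult in all_clusters:
            center = int(center)
            if not 0 <= center < n:
                raise SimulationError(f"planted cluster center {center} is not a zone index (n={n})")
            covered = neighbor_hops(queen, center, int(radius))
            planted[covered] *= float(mult)

    base = dict(config.base_rates)
    probs = {"zone_id": zones.zone_ids}
    for outcome in ("dfu", "lea", "death"):
        probs[outcome] = np.minimum(base[outcome] * rr * planted, PROBABILITY_CAP)
    return RiskSurface(probabilities=pd.DataFrame(probs))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _uniform_dates(rng, lo_days: np.ndarray, hi_days: np.ndarray) -> np.ndarray:
    """Uniform integer day offsets in [lo, hi] (vectorised, inclusive)."""
    span = np.maximum(hi_days - lo_days, 0)
    return lo_days + np.floor(rng.random(lo_days.size) * (span + 1)).astype(np.int64)


def simulate_cohort(zones: ZoneSet, surface: RiskSurface, config: SimulationConfig) -> pd.DataFrame:
    """Draw the individual-level cohort.

    One person per head of zone population. Ulcer and amputation events
    are Bernoulli draws with the zone's probabilities; with probability
    ``lea_dfu_coupling`` an amputation is preceded by an ulcer (the ulcer
    date is forced on or before the amputation date). Death is drawn only
    for people with ulcer or amputation history and is dated after their
    last event. Event dates are uniform over the registry window.

    Returns the canonical cohort DataFrame (see :mod:`geofoot.cohort`).
    """
    config.validate()
    if list(surface.probabilities["zone_id"]) != list(zones.zone_ids):
        raise SimulationError("risk surface zone universe does not match the geography")
    rng = _rng(config, 3)
    pops = zones.populations
    n_people = int(pops.sum())
    zone_idx = np.repeat(np.arange(zones.n), pops)

    p_dfu = surface.prob("dfu")[zone_idx]
    p_lea = surface.prob("lea")[zone_idx]
    p_death = surface.prob("death")[zone_idx]

    lea = rng.random(n_people) < p_lea
    dfu_indep = rng.random(n_people) < p_dfu
    coupled = lea & (rng.random(n_people) < config.lea_dfu_coupling)
    dfu = dfu_indep | coupled
    death = (dfu | lea) & (rng.random(n_people) < p_death)

    window = config.analysis_window()
    start = window.start.to_datetime64().astype("datetime64[D]").astype(np.int64)
    end = window.end.to_datetime64().astype("datetime64[D]").astype(np.int64)

    entry = _uniform_dates(rng, np.full(n_people, start), np.full(n_people, end))
    d1 = _uniform_dates(rng, np.full(n_people, start), np.full(n_people, end))
    d2 = _uniform_dates(rng, np.full(n_people, start), np.full(n_people, end))
    dfu_days = np.where(coupled, np.minimum(d1, d2), d1)
    lea_days = np.where(coupled, np.maximum(d1, d2), d2)
    last_event = np.maximum(np.where(dfu, dfu_days, start), np.where(lea, lea_days, start))
    death_days = _uniform_dates(rng, last_event, np.full(n_people, end))
    # registration precedes the first recorded event
    first_event = np.minimum(
        np.where(dfu, dfu_days, end), np.where(lea, lea_days, end)
    )
    entry = np.where(dfu | lea, np.minimum(entry, first_event), entry)

    lea_level = np.where(rng.random(n_people) < 0.4, "major", "minor")

    def _dates(day_ints, mask):
        vals = day_ints.astype("datetime64[D]").astype("datetime64[ns]")
        out = pd.Series(vals)
        return out.where(pd.Series(mask), pd.NaT)

    df = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n_people)],
            "zone_id": zones.zone_ids[zone_idx],
            "entry_date": entry.astype("datetime64[D]").astype("datetime64[ns]"),
            "dfu_date": _dates(dfu_days, dfu),
            "lea_date": _dates(lea_days, lea),
            "lea_level": pd.Series(np.where(lea, lea_level, None), dtype="object"),
            "death_date": _dates(death_days, death),
        },
        columns=list(COHORT_COLUMNS),
    )
    return df


def simulate(config: SimulationConfig) -> tuple[ZoneSet, RiskSurface, pd.DataFrame]:
    """Full generator chain: geography -> deprivation -> risks -> cohort."""
    config.validate()
    zones = generate_geography(config)
    zones = assign_deprivation(zones, config.deprivation_smoothness, config.seed)
    surface = build_risk_surface(zones, config)
    cohort = simulate_cohort(zones, surface, config)
    return zones, surface, cohort
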