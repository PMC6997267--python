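"""Calibration experiments for the hot-spot pipeline.

These drive the full synthetic chain (geography -> deprivation -> risk
surface -> cohort -> rates -> Gi*) under controlled conditions:

* planted-cluster recovery: flat deprivation risk with one planted
  excess-risk cluster of known centre — is the centre flagged hot?
* null calibration: flat risk, nothing planted — how often is a zone
  flagged hot at the 90% tier (nominal one-sided level 5%)?

Both are per-replicate functions plus replicated wrappers, deterministic
in the seeds supplied.
"""

from __future__ import annotations

import numpy as np

from .cohort import AnalysisWindow, aggregate
from .hotspot import HotspotModel, HotspotResults
from .pipeline import build_weights
from .rates import zone_rates
from .simulate import (
    SimulationConfig,
    assign_deprivation,
    build_risk_surface,
    generate_geography,
    simulate_cohort,
)
from .weights import queen_contiguity

FLAT_RISKS = (1.0, 1.0, 1.0, 1.0, 1.0)


def central_zone(zones) -> int:
    """Index of the zone whose centroid is nearest the map centre."""
    c = zones.centroids()
    return int(np.argmin(((c - 0.5) ** 2).sum(axis=1)))


def _fit_dfu_hotspots(zones, cfg, queen) -> HotspotResults:
    surface = build_risk_surface(zones, cfg, queen=queen)
    cohort = simulate_cohort(zones, surface, cfg)
    table = aggregate(cohort, zones, "dfu", AnalysisWindow.dfu_subset())
    rt = zone_rates(table)
    return HotspotModel.from_rates(rt, build_weights(zones, "hybrid")).fit()


def planted_recovery_replicate(seed: int, n_zones: int = 200, multiplier: float = 3.0,
                               radius: int = 1) -> tuple[str, float]:
    """One replicate: flat quintile risk, one planted hot cluster at the
    central zone. Returns the centre zone's (confidence bin, z-score)."""
    base_cfg = SimulationConfig(n_zones=n_zones, seed=seed, quintile_relative_risks=FLAT_RISKS)
    zones = generate_geography(base_cfg)
    zones = assign_deprivation(zones, base_cfg.deprivation_smoothness, base_cfg.seed)
    queen = queen_contiguity(zones)
    center = central_zone(zones)
    cfg = SimulationConfig(
        n_zones=n_zones, seed=seed, quintile_relative_risks=FLAT_RISKS,
        planted_hot=[(center, radius, multiplier)],
    )
    res = _fit_dfu_hotspots(zones, cfg, queen)
    zid = zones.zone_ids[center]
    return str(res.bins.loc[zid]), float(res.zscores.loc[zid])


def planted_recovery_rate(seeds, n_zones: int = 200, multiplier: float = 3.0,
                          min_tier: str = "95") -> float:
    """Fraction of replicates whose planted centre is hot at >= the tier."""
    accept = {"95": ("hot_95", "hot_99"), "90": ("hot_90", "hot_95", "hot_99"),
              "99": ("hot_99",)}[min_tier]
    hits = sum(planted_recovery_replicate(s, n_zones, multiplier)[0] in accept for s in seeds)
    return hits / len(list(seeds))


def null_hot_rate(seeds, n_zones: int = 200) -> float:
    """Mean per-zone rate of hot flags (any tier, i.e. the 90% threshold)
    under flat risk with nothing planted."""
    rates = []
    for seed in seeds:
        cfg = SimulationConfig(n_zones=n_zones, seed=seed, quintile_relative_risks=FLAT_RISKS)
        zones = generate_geography(cfg)
        zones = assign_deprivation(zones, cfg.deprivation_smoothness, cfg.seed)
        res = _fit_dfu_hotspots(zones, cfg, queen=None)
        rates.append(res.bins.str.startswith("hot_").mean())
    return float(np.mean(rates))
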