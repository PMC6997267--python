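"""Synthetic geography / deprivation / risk-surface / cohort generator tests."""

import numpy as np
import pandas as pd
import pytest

from geofoot.simulate import (
    RiskSurface,
    SimulationConfig,
    SimulationError,
    assign_deprivation,
    build_risk_surface,
    generate_geography,
    simulate,
    simulate_cohort,
)
from geofoot.weights import queen_contiguity

from conftest import grid_zones


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def test_tessellation_partitions_unit_square():
    zones = generate_geography(SimulationConfig(n_zones=200, seed=1))
    assert zones.n == 200
    assert abs(zones.areas().sum() - 1.0) < 1e-9


def test_geography_seed_determinism():
    a = generate_geography(SimulationConfig(n_zones=200, seed=1))
    b = generate_geography(SimulationConfig(n_zones=200, seed=1))
    assert np.array_equal(a.populations, b.populations)
    for ga, gb in zip(a.polygons, b.polygons):
        assert ga.equals_exact(gb, 0.0)


def test_geography_seed_sensitivity():
    a = generate_geography(SimulationConfig(n_zones=50, seed=1))
    b = generate_geography(SimulationConfig(n_zones=50, seed=2))
    assert not np.array_equal(a.centroids(), b.centroids())


def test_mean_population_near_target():
    zones = generate_geography(SimulationConfig(n_zones=200, mean_population=760, seed=1))
    assert abs(zones.populations.mean() - 760) / 760 < 0.10


def test_peripheral_zones_larger():
    # urban/rural emulation: mean area of the outer half exceeds the inner half
    zones = generate_geography(SimulationConfig(n_zones=300, seed=3))
    c = zones.centroids()
    r = np.hypot(c[:, 0] - 0.5, c[:, 1] - 0.5)
    areas = zones.areas()
    assert areas[r > np.median(r)].mean() > areas[r <= np.median(r)].mean()


def test_too_few_zones_rejected():
    with pytest.raises(SimulationError):
        generate_geography(SimulationConfig(n_zones=9, seed=1))


# ---------------------------------------------------------------------------
# deprivation surface
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n", [10, 37, 200])
def test_quintile_balance(n):
    cfg = SimulationConfig(n_zones=max(n, 10), seed=5)
    zones = assign_deprivation(generate_geography(cfg), 0.1, seed=5)
    counts = np.bincount(zones.quintiles, minlength=6)[1:]
    assert counts.sum() == zones.n
    assert (np.abs(counts - zones.n / 5) < 1).all()


def test_quintile_one_is_highest_score():
    cfg = SimulationConfig(n_zones=50, seed=5)
    zones = assign_deprivation(generate_geography(cfg), 0.1, seed=5)
    score = zones.extra["deprivation_score"].astype(float)
    q = zones.quintiles
    assert score[q == 1].min() >= score[q == 5].max()


def _same_quintile_neighbor_count(zones, pairs, quintiles):
    return int((quintiles[pairs[:, 0]] == quintiles[pairs[:, 1]]).sum())


def _permutation_null(pairs, quintiles, rng, n_perm=999):
    stats = np.empty(n_perm)
    q = quintiles.copy()
    for k in range(n_perm):
        rng.shuffle(q)
        stats[k] = _same_quintile_neighbor_count(None, pairs, q)
    return stats


def test_smoothness_zero_is_spatially_independent():
    """With no smoothing, same-quintile adjacency matches its permutation null."""
    cfg = SimulationConfig(n_zones=200, seed=8)
    zones = assign_deprivation(generate_geography(cfg), 0.0, seed=8)
    pairs = queen_contiguity(zones).pairs()
    obs = _same_quintile_neighbor_count(zones, pairs, zones.quintiles)
    null = _permutation_null(pairs, zones.quintiles, np.random.default_rng(101))
    assert abs(obs - null.mean()) <= 2 * null.std()


def test_large_smoothness_clusters_quintiles():
    """Strong smoothing puts same-quintile zones next to each other."""
    cfg = SimulationConfig(n_zones=200, seed=8)
    zones = assign_deprivation(generate_geography(cfg), 0.5, seed=8)
    pairs = queen_contiguity(zones).pairs()
    obs = _same_quintile_neighbor_count(zones, pairs, zones.quintiles)
    null = _permutation_null(pairs, zones.quintiles, np.random.default_rng(101))
    assert obs > np.quantile(null, 0.975)


def test_negative_smoothness_rejected(small_geography):
    with pytest.raises(SimulationError):
        assign_deprivation(small_geography, -0.1, seed=1)


# ---------------------------------------------------------------------------
# risk surface
# ---------------------------------------------------------------------------

def test_flat_risk_surface_equals_base_rates(small_geography):
    cfg = SimulationConfig(n_zones=200, seed=11, quintile_relative_risks=(1,) * 5)
    surface = build_risk_surface(small_geography, cfg)
    for outcome, base in cfg.base_rates.items():
        assert np.allclose(surface.prob(outcome), base)


def test_quintile_multiplier_applied(small_geography):
    cfg = SimulationConfig(
        n_zones=200, seed=11,
        quintile_relative_risks=(2.0, 1.0, 1.0, 1.0, 1.0),
        base_rates={"dfu": 0.04, "lea": 0.013, "death": 0.3},
    )
    surface = build_risk_surface(small_geography, cfg)
    p = surface.prob("dfu")
    q = small_geography.quintiles
    assert np.allclose(p[q == 1], 0.08)
    assert np.allclose(p[q != 1], 0.04)


def test_planted_cluster_covers_center_and_queen_neighbors(small_geography):
    queen = queen_contiguity(small_geography)
    center = 42
    cfg = SimulationConfig(
        n_zones=200, seed=11, quintile_relative_risks=(1,) * 5, planted_hot=[(center, 1, 3.0)]
    )
    surface = build_risk_surface(small_geography, cfg, queen=queen)
    p = surface.prob("dfu")
    expected = set(queen.neighbors(center).tolist()) | {center}
    tripled = set(np.flatnonzero(np.isclose(p, 3 * 0.046)).tolist())
    assert tripled == expected
    assert np.allclose(p[sorted(set(range(200)) - expected)], 0.046)


def test_planted_cold_and_cap(small_geography):
    cfg = SimulationConfig(
        n_zones=200, seed=11, quintile_relative_risks=(1,) * 5,
        planted_hot=[(0, 0, 50.0)], planted_cold=[(100, 0, 0.5)],
    )
    surface = build_risk_surface(small_geography, cfg)
    p = surface.prob("dfu")
    assert p[0] == pytest.approx(0.99)  # capped
    assert p[100] == pytest.approx(0.023)


def test_unknown_planted_center_rejected(small_geography):
    cfg = SimulationConfig(n_zones=200, seed=11, planted_hot=[(999, 1, 2.0)])
    with pytest.raises(SimulationError, match="center"):
        build_risk_surface(small_geography, cfg)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _flat_surface(zones, dfu, lea, death):
    return RiskSurface(
        probabilities=pd.DataFrame(
            {
                "zone_id": zones.zone_ids,
                "dfu": np.full(zones.n, dfu, dtype=float),
                "lea": np.full(zones.n, lea, dtype=float),
                "death": np.full(zones.n, death, dtype=float),
            }
        )
    )


def test_zero_probability_yields_zero_events():
    zones = grid_zones(4, 3, populations=[50] * 12)
    cfg = SimulationConfig(n_zones=12, seed=2)
    cohort = simulate_cohort(zones, _flat_surface(zones, 0.0, 0.0, 0.0), cfg)
    assert len(cohort) == 600
    assert cohort["dfu_date"].isna().all()
    assert cohort["lea_date"].isna().all()
    assert cohort["death_date"].isna().all()


def test_dfu_count_binomial():
    zones = grid_zones(1, 1, populations=[10_000]).replace(quintiles=[3])
    cfg = SimulationConfig(n_zones=10, seed=4)
    cohort = simulate_cohort(zones, _flat_surface(zones, 0.046, 1e-9, 1e-9), cfg)
    count = cohort["dfu_date"].notna().sum()
    sd = np.sqrt(10_000 * 0.046 * 0.954)
    assert abs(count - 460) <= 3 * sd


def test_lea_preceded_by_dfu_fraction():
    """~80% of amputations carry an earlier-or-same-date ulcer."""
    zones = grid_zones(2, 2, populations=[50_000] * 4)
    cfg = SimulationConfig(n_zones=10, seed=6)
    cohort = simulate_cohort(zones, _flat_surface(zones, 0.046, 0.013, 0.3), cfg)
    lea = cohort[cohort["lea_date"].notna()]
    prior = (lea["dfu_date"].notna() & (lea["dfu_date"] <= lea["lea_date"])).mean()
    sd = np.sqrt(0.8 * 0.2 / len(lea))
    assert abs(prior - 0.8) <= 3 * sd + 0.01  # small slack for independent-ulcer overlap


def test_cohort_event_date_ordering():
    zones = grid_zones(3, 3, populations=[2_000] * 9)
    cfg = SimulationConfig(n_zones=10, seed=7)
    cohort = simulate_cohort(zones, _flat_surface(zones, 0.1, 0.05, 0.5), cfg)
    dead = cohort[cohort["death_date"].notna()]
    assert (dead["death_date"] >= dead["dfu_date"].fillna(dead["death_date"])).all()
    assert (dead["death_date"] >= dead["lea_date"].fillna(dead["death_date"])).all()
    assert (cohort["entry_date"] <= cohort["dfu_date"].fillna(cohort["entry_date"])).all()
    win = cfg.analysis_window()
    for col in ("entry_date", "dfu_date", "lea_date", "death_date"):
        dates = cohort[col].dropna()
        assert (dates >= win.start).all() and (dates <= win.end).all()


def test_cohort_seed_determinism():
    cfg = SimulationConfig(n_zones=30, seed=9)
    _, _, a = simulate(cfg)
    _, _, b = simulate(cfg)
    pd.testing.assert_frame_equal(a, b)


def test_deprivation_gradient_recovered_in_cases():
    """Quintile-1 share of ulcer cases exceeds quintile-5 share (~150k persons)."""
    cfg = SimulationConfig(n_zones=200, seed=12)  # default RRs (2.5,...,0.6)
    zones, _, cohort = simulate(cfg)
    quint = pd.Series(zones.quintiles, index=zones.zone_ids)
    cases = cohort[cohort["dfu_date"].notna()]
    case_q = quint.loc[cases["zone_id"]].to_numpy()
    shares = np.bincount(case_q, minlength=6)[1:] / len(cases)
    assert len(cohort) > 100_000
    assert shares[0] > shares[4]
    assert shares[0] > 0.3  # strong gradient, not a squeaker


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_zones=5),
        dict(mean_population=0),
        dict(deprivation_smoothness=-1),
        dict(quintile_relative_risks=(1, 1, 1)),
        dict(quintile_relative_risks=(1, 1, 1, 1, -2)),
        dict(base_rates={"dfu": 0.0, "lea": 0.013, "death": 0.3}),
        dict(planted_hot=[(0, -1, 2.0)]),
        dict(lea_dfu_coupling=1.5),
    ],
)
def test_invalid_configs_rejected(bad):
    with pytest.raises(SimulationError):
        SimulationConfig(**bad).validate()
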