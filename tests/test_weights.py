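"""Spatial weights construction tests: distance band, queen contiguity, hybrid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon, box

from geofoot.weights import (
    WeightsError,
    WeightsMatrix,
    auto_threshold,
    centroids,
    fixed_distance_band,
    hybrid_weights,
    neighbor_hops,
    queen_contiguity,
)
from geofoot.zones import ZoneSet, ZoneSetError

from conftest import grid_zones


def _point_zones(points, radius=0.01):
    """Tiny squares centred on the given points (for distance-band tests)."""
    polys = [box(x - radius, y - radius, x + radius, y + radius) for x, y in points]
    return ZoneSet([f"P{i}" for i in range(len(points))], polys)


CORNERS = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]


# ---------------------------------------------------------------------------
# centroids
# ---------------------------------------------------------------------------

def test_centroid_unit_square():
    z = ZoneSet(["s"], [box(0, 0, 1, 1)])
    assert centroids(z)[0] == pytest.approx((0.5, 0.5))


def test_centroid_triangle():
    z = ZoneSet(["t"], [Polygon([(0, 0), (1, 0), (0, 1)])])
    assert centroids(z)[0] == pytest.approx((1 / 3, 1 / 3))


def test_centroid_l_shape_is_area_weighted():
    # L from two unit squares: centroid = mean of the squares' centroids
    l_shape = Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
    z = ZoneSet(["l"], [l_shape])
    sq1, sq2 = box(0, 0, 1, 2), box(1, 0, 2, 1)  # decomposition (areas 2 and 1)
    expected = (2 * np.array([sq1.centroid.x, sq1.centroid.y]) + 1 * np.array([sq2.centroid.x, sq2.centroid.y])) / 3
    assert centroids(z)[0] == pytest.approx(tuple(expected))


def test_degenerate_polygon_rejected():
    degenerate = Polygon([(0, 0), (1, 0), (2, 0)])  # zero area
    with pytest.raises(ZoneSetError):
        ZoneSet(["d"], [degenerate]).centroids()


# ---------------------------------------------------------------------------
# fixed distance band
# ---------------------------------------------------------------------------

def test_band_unit_square_corners():
    z = _point_zones(CORNERS)
    w = fixed_distance_band(z, threshold=1.0)
    assert list(w.degrees) == [2, 2, 2, 2]  # diagonal sqrt(2) excluded


def test_band_auto_threshold_on_corners():
    z = _point_zones(CORNERS)
    w = fixed_distance_band(z, "auto")
    assert w.threshold == pytest.approx(1.0)
    assert list(w.degrees) == [2, 2, 2, 2]
    assert auto_threshold(np.array(CORNERS)) == pytest.approx(1.0)


def test_band_complete_graph_at_sqrt2():
    z = _point_zones(CORNERS)
    w = fixed_distance_band(z, threshold=np.sqrt(2) + 1e-9)
    assert list(w.degrees) == [3, 3, 3, 3]


def test_band_rejects_nonpositive_threshold():
    with pytest.raises(WeightsError):
        fixed_distance_band(_point_zones(CORNERS), threshold=0.0)


def test_auto_band_guarantees_min_degree(small_geography):
    w = fixed_distance_band(small_geography, "auto")
    assert w.degrees.min() >= 1


# ---------------------------------------------------------------------------
# queen contiguity
# ---------------------------------------------------------------------------

def test_queen_2x2_grid():
    w = queen_contiguity(grid_zones(2, 2))
    assert list(w.degrees) == [3, 3, 3, 3]  # 2 edge neighbours + 1 corner


def test_queen_3x3_center(grid3):
    w = queen_contiguity(grid3)
    center = grid3.index_of("G1_1")
    assert w.degrees[center] == 8
    corners = [grid3.index_of(z) for z in ("G0_0", "G2_0", "G0_2", "G2_2")]
    assert [w.degrees[c] for c in corners] == [3, 3, 3, 3]


def test_queen_disjoint_squares():
    z = ZoneSet(["a", "b"], [box(0, 0, 1, 1), box(2, 0, 3, 1)])
    w = queen_contiguity(z)
    assert w.degrees.sum() == 0


def test_queen_snap_tolerance_bridges_sliver():
    z = ZoneSet(["a", "b"], [box(0, 0, 1, 1), box(1 + 1e-6, 0, 2, 1)])
    assert queen_contiguity(z).degrees.sum() == 0  # default tolerance too small
    assert list(queen_contiguity(z, snap_tolerance=1e-5).degrees) == [1, 1]


# ---------------------------------------------------------------------------
# hybrid + matrix mechanics
# ---------------------------------------------------------------------------

def test_hybrid_union_identity(grid3):
    queen = queen_contiguity(grid3)
    wide = fixed_distance_band(grid3, threshold=3.0)  # superset of queen
    hybrid = hybrid_weights(wide, queen)
    assert np.array_equal(hybrid.pairs(), wide.pairs())


def test_hybrid_disjoint_degrees_add():
    a = WeightsMatrix(4, [(0, 1)])
    b = WeightsMatrix(4, [(2, 3)])
    assert list(a.union(b).degrees) == [1, 1, 1, 1]


def test_hybrid_dominates_both_on_synthetic_geography(small_geography):
    band = fixed_distance_band(small_geography, "auto")
    queen = queen_contiguity(small_geography)
    hybrid = hybrid_weights(band, queen)
    assert (hybrid.degrees >= band.degrees).all()
    assert (hybrid.degrees >= queen.degrees).all()
    assert hybrid.degrees.min() >= 1
    assert hybrid.is_symmetric()


def test_union_rejects_mismatched_universes():
    with pytest.raises(WeightsError):
        WeightsMatrix(3, [(0, 1)]).union(WeightsMatrix(4, [(0, 1)]))


def test_self_pairs_rejected():
    with pytest.raises(WeightsError):
        WeightsMatrix(3, [(1, 1)])


def test_sparse_self_inclusion_flag():
    w = WeightsMatrix(3, [(0, 1)], include_self=True)
    assert w.sparse().diagonal().sum() == 3.0
    assert w.sparse(include_self=False).diagonal().sum() == 0.0
    assert 1 not in w.neighbors(1)


def test_neighbor_hops(grid3):
    queen = queen_contiguity(grid3)
    center = grid3.index_of("G1_1")
    assert len(neighbor_hops(queen, center, 0)) == 1
    assert len(neighbor_hops(queen, center, 1)) == 9
    corner = grid3.index_of("G0_0")
    assert len(neighbor_hops(queen, corner, 1)) == 4


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_band_symmetry_and_permutation_equivariance(seed):
    """Constructors are symmetric and equivariant under zone relabelling."""
    rng = np.random.default_rng(seed)
    pts = rng.random((20, 2))
    z = _point_zones(pts, radius=1e-4)
    w = fixed_distance_band(z, threshold=0.3)
    assert w.is_symmetric()
    perm = rng.permutation(20)
    z2 = _point_zones(pts[perm], radius=1e-4)
    w2 = fixed_distance_band(z2, threshold=0.3)
    # edge {perm_pos(i), perm_pos(j)} present iff {i, j} present
    pos = np.argsort(perm)  # original index -> new position
    remapped = {tuple(sorted((pos[i], pos[j]))) for i, j in w.pairs()}
    assert remapped == {tuple(p) for p in map(tuple, map(sorted, w2.pairs()))}
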