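"""Spatial weights matrices for local autocorrelation statistics.

The neighbourhood model is the one used in the underlying hot-spot
analysis: a fixed distance band on zone centroids (so that small urban
zones and large peripheral/rural zones get comparable neighbourhoods)
corrected by queen contiguity, i.e. polygons sharing an edge *or a
corner* are always neighbours. Weights are binary (0/1) and symmetric;
self-inclusion (w_ii = 1, the "star" in Gi*) is a convention flag on the
matrix, not an entry in the neighbour sets.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from shapely.strtree import STRtree

from .zones import ZoneSet, ZoneSetError


class WeightsError(ValueError):
    """Invalid weights construction."""


class WeightsMatrix:
    """Sparse symmetric binary neighbour structure over ``n`` zones.

    Parameters
    ----------
    n : int
        Number of zones (indices 0..n-1, in ZoneSet order).
    pairs : iterable of (i, j)
        Neighbour pairs; symmetrised, self-pairs rejected.
    include_self : bool
        Convention flag: whether statistics consuming this matrix should
        take w_ii = 1 (Gi*) or 0 (plain Gi). Neighbour sets never contain
        the zone itself.
    scheme : {"distance_band", "queen", "hybrid", "custom"}
    threshold : float, optional
        Distance-band threshold, recorded for reproducibility.
    """

    def __init__(self, n: int, pairs: Iterable[tuple[int, int]], include_self: bool = True,
                 scheme: str = "custom", threshold: float | None = None):
        if n <= 0:
            raise WeightsError("n must be positive")
        pairs = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
        if pairs.size:
            if pairs.min() < 0 or pairs.max() >= n:
                raise WeightsError("neighbor index out of range")
            if (pairs[:, 0] == pairs[:, 1]).any():
                raise WeightsError("self-pairs are not allowed; self-inclusion is the include_self flag")
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        data = np.ones(i.size, dtype=np.float64)
        adj = sp.csr_matrix((data, (i, j)), shape=(n, n))
        adj.data[:] = 1.0  # collapse duplicates to binary
        adj.sum_duplicates()
        adj.data[:] = 1.0
        self._adj = adj
        self.n = int(n)
        self.include_self = bool(include_self)
        self.scheme = scheme
        self.threshold = threshold

    # -- queries ------------------------------------------------------------
    def sparse(self, include_self: bool | None = None) -> sp.csr_matrix:
        """Binary CSR adjacency; optionally with the unit diagonal added."""
        if include_self is None:
            include_self = self.include_self
        if include_self:
            return (self._adj + sp.identity(self.n, format="csr")).tocsr()
        return self._adj.copy()

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted neighbour indices of zone ``i`` (self excluded)."""
        return np.sort(self._adj.indices[self._adj.indptr[i]:self._adj.indptr[i + 1]])

    @property
    def degrees(self) -> np.ndarray:
        """Neighbour counts per zone (self excluded)."""
        return np.asarray(self._adj.sum(axis=1)).ravel().astype(np.int64)

    def pairs(self) -> np.ndarray:
        """Unique (i, j) pairs with i < j, shape (m, 2)."""
        coo = sp.triu(self._adj, k=1).tocoo()
        out = np.stack([coo.row, coo.col], axis=1)
        return out[np.lexsort((out[:, 1], out[:, 0]))]

    def is_symmetric(self) -> bool:
        return (self._adj != self._adj.T).nnz == 0

    # -- combination / subsetting ------------------------------------------
    def union(self, other: "WeightsMatrix") -> "WeightsMatrix":
        """Union of neighbour sets (w_ij = 1 if either scheme says so)."""
        if other.n != self.n:
            raise WeightsError(f"mismatched zone universes: {self.n} vs {other.n}")
        merged = (self._adj + other._adj).tocsr()
        merged.data[:] = 1.0
        coo = sp.triu(merged, k=1).tocoo()
        w = WeightsMatrix(self.n, zip(coo.row, coo.col), include_self=self.include_self,
                          scheme="hybrid", threshold=self.threshold if self.threshold is not None else other.threshold)
        return w

    def subset(self, keep: np.ndarray) -> "WeightsMatrix":
        """Restrict to the given zone indices (in their given order)."""
        keep = np.asarray(keep, dtype=np.int64)
        sub = self._adj[keep][:, keep].tocoo()
        mask = sub.row < sub.col
        return WeightsMatrix(keep.size, zip(sub.row[mask], sub.col[mask]),
                             include_self=self.include_self, scheme=self.scheme, threshold=self.threshold)

    # -- serialisation ------------------------------------------------------
    def to_pairs_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i,j\n")
            for i, j in self.pairs():
                fh.write(f"{i},{j}\n")

    def summary(self) -> dict:
        deg = self.degrees
        hist = np.bincount(deg)
        return {
            "n": self.n,
            "scheme": self.scheme,
            "threshold": self.threshold,
            "include_self": self.include_self,
            "n_pairs": int(deg.sum() // 2),
            "min_degree": int(deg.min()),
            "max_degree": int(deg.max()),
            "mean_degree": float(deg.mean()),
            "degree_histogram": {str(k): int(v) for k, v in enumerate(hist) if v},
        }

    def to_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"WeightsMatrix(n={self.n}, scheme={self.scheme!r}, pairs={int(self.degrees.sum() // 2)})"


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def centroids(zones: ZoneSet) -> np.ndarray:
    """Area-weighted centroid per zone, shape (n, 2).

    Raises for degenerate (zero-area) polygons, which have no meaningful
    representative point for a distance band.
    """
    return zones.centroids()


def auto_threshold(points: np.ndarray) -> float:
    """Smallest distance band giving every zone at least one neighbour.

    This is the maximum over zones of the nearest-neighbour distance.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise WeightsError("need at least 2 zones for a distance band")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(d[:, 1].max())


def fixed_distance_band(zones: ZoneSet, threshold: float | str = "auto") -> WeightsMatrix:
    """Fixed distance band weights: w_ij = 1 iff centroid distance <= threshold.

    ``threshold="auto"`` picks the smallest band under which every zone has
    at least one neighbour; the chosen value is recorded on the matrix.
    """
    pts = centroids(zones)
    if threshold == "auto":
        thr = auto_threshold(pts)
    else:
        thr = float(threshold)
        if thr <= 0:
            raise WeightsError(f"distance-band threshold must be positive, got {thr}")
    tree = cKDTree(pts)
    # small epsilon so the "auto" critical pair is included despite rounding
    pairs = tree.query_pairs(thr * (1 + 1e-12), output_type="ndarray")
    return WeightsMatrix(zones.n, pairs, scheme="distance_band", threshold=thr)


def queen_contiguity(zones: ZoneSet, snap_tolerance: float | None = None) -> WeightsMatrix:
    """Queen contiguity: zones sharing at least one boundary point are neighbours.

    Shared edges and shared corners both count. ``snap_tolerance`` absorbs
    sliver gaps between nominally adjacent polygons; the default is 1e-9 of
    the map width.
    """
    polys = zones.polygons
    for zid, g in zip(zones.zone_ids, polys):
        if not g.is_valid:  # pragma: no cover - ZoneSet already validates
            raise ZoneSetError(f"zone {zid!r}: invalid geometry")
    xmin, ymin, xmax, ymax = zones.bounds()
    width = max(xmax - xmin, ymax - ymin)
    if snap_tolerance is None:
        snap_tolerance = 1e-9 * (width if width > 0 else 1.0)
    tree = STRtree(polys)
    qi, qj = tree.query(polys, predicate="dwithin", distance=snap_tolerance)
    mask = qi < qj
    return WeightsMatrix(zones.n, zip(qi[mask], qj[mask]), scheme="queen")


def hybrid_weights(band: WeightsMatrix, queen: WeightsMatrix) -> WeightsMatrix:
    """Distance band corrected by contiguity: union of the two neighbour sets."""
    return band.union(queen)


def neighbor_hops(weights: WeightsMatrix, center: int, radius: int) -> np.ndarray:
    """Zone indices within ``radius`` graph hops of ``center`` (inclusive).

    Used to expand planted cluster centres into the set of covered zones.
    """
    if not 0 <= center < weights.n:
        raise WeightsError(f"center index {center} out of range for n={weights.n}")
    seen = {int(center)}
    frontier = {int(center)}
    for _ in range(int(radius)):
        nxt = set()
        for i in frontier:
            nxt.update(int(k) for k in weights.neighbors(i))
        frontier = nxt - seen
        seen |= frontier
        if not frontier:
            break
    return np.array(sorted(seen), dtype=np.int64)
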