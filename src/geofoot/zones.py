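"""Zone geography container.

A :class:`ZoneSet` holds the small-area geography the whole pipeline works
on: one polygon per data zone together with its diabetic population count
and its multiple-deprivation quintile (1 = most deprived 20%, 5 = least
deprived). It is an ordered, immutable-by-convention container; derived
columns are added by returning a new instance.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry


class ZoneSetError(ValueError):
    """Invalid zone geography or attributes."""


def _check_polygon(geom: BaseGeometry, zone_id) -> BaseGeometry:
    if not isinstance(geom, (Polygon, MultiPolygon)):
        raise ZoneSetError(f"zone {zone_id!r}: geometry must be Polygon or MultiPolygon, got {geom.geom_type}")
    if geom.is_empty:
        raise ZoneSetError(f"zone {zone_id!r}: empty geometry")
    if not geom.is_valid:
        raise ZoneSetError(f"zone {zone_id!r}: invalid geometry ({geom.geom_type})")
    return geom


class ZoneSet:
    """Ordered collection of zones: polygon, population, deprivation quintile.

    Parameters
    ----------
    zone_ids : sequence of hashable
        Unique zone identifiers, in analysis order.
    polygons : sequence of shapely Polygon/MultiPolygon
        Planar (projected) geometries, one per zone.
    populations : sequence of int, optional
        Diabetic population per zone (the rate denominator universe).
    quintiles : sequence of int in 1..5, optional
        Deprivation quintile per zone, 1 = most deprived.
    extra : mapping of column name -> sequence, optional
        Arbitrary additional per-zone properties, carried through I/O.
    """

    def __init__(
        self,
        zone_ids: Sequence,
        polygons: Sequence[BaseGeometry],
        populations: Sequence[int] | None = None,
        quintiles: Sequence[int] | None = None,
        extra: Mapping[str, Sequence] | None = None,
    ):
        ids = list(zone_ids)
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids)
            dupes = sorted(dupes[dupes.duplicated()].unique().tolist())
            raise ZoneSetError(f"duplicate zone ids: {dupes}")
        if len(polygons) != len(ids):
            raise ZoneSetError("zone_ids and polygons length mismatch")
        self._polygons = [_check_polygon(g, i) for i, g in zip(ids, polygons)]

        n = len(ids)
        if populations is not None:
            populations = np.asarray(populations, dtype=np.int64)
            if populations.shape != (n,):
                raise ZoneSetError("populations length mismatch")
            if (populations < 0).any():
                raise ZoneSetError("populations must be non-negative")
        if quintiles is not None:
            quintiles = np.asarray(quintiles, dtype=np.int64)
            if quintiles.shape != (n,):
                raise ZoneSetError("quintiles length mismatch")
            bad = ~np.isin(quintiles, [1, 2, 3, 4, 5])
            if bad.any():
                raise ZoneSetError(f"quintile values outside 1..5 for zones {list(np.asarray(ids, object)[bad][:5])}")
        self._ids = np.asarray(ids, dtype=object)
        self._populations = populations
        self._quintiles = quintiles
        self._extra: dict[str, np.ndarray] = {}
        if extra:
            for k, v in extra.items():
                v = np.asarray(v, dtype=object)
                if v.shape != (n,):
                    raise ZoneSetError(f"extra column {k!r} length mismatch")
                self._extra[str(k)] = v
        self._index = {zid: i for i, zid in enumerate(ids)}

    # -- basic introspection ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self._ids)

    def __len__(self) -> int:
        return self.n

    @property
    def zone_ids(self) -> np.ndarray:
        return self._ids.copy()

    @property
    def polygons(self) -> list[BaseGeometry]:
        return list(self._polygons)

    @property
    def populations(self) -> np.ndarray:
        if self._populations is None:
            raise ZoneSetError("populations not set on this ZoneSet")
        return self._populations.copy()

    @property
    def has_populations(self) -> bool:
        return self._populations is not None

    @property
    def quintiles(self) -> np.ndarray:
        if self._quintiles is None:
            raise ZoneSetError("quintiles not assigned on this ZoneSet")
        return self._quintiles.copy()

    @property
    def has_quintiles(self) -> bool:
        return self._quintiles is not None

    @property
    def extra(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._extra.items()}

    def index_of(self, zone_id) -> int:
        try:
            return self._index[zone_id]
        except KeyError:
            raise ZoneSetError(f"unknown zone id {zone_id!r}") from None

    def areas(self) -> np.ndarray:
        return np.array([g.area for g in self._polygons])

    def centroids(self) -> np.ndarray:
        """Area-weighted polygon centroids, shape (n, 2)."""
        out = np.empty((self.n, 2))
        for i, g in enumerate(self._polygons):
            if g.area == 0:
                raise ZoneSetError(f"zone {self._ids[i]!r}: degenerate zero-area polygon has no centroid")
            c = g.centroid
            out[i] = (c.x, c.y)
        return out

    def bounds(self) -> tuple[float, float, float, float]:
        bs = np.array([g.bounds for g in self._polygons])
        return (bs[:, 0].min(), bs[:, 1].min(), bs[:, 2].max(), bs[:, 3].max())

    def table(self) -> pd.DataFrame:
        """Attribute table (no geometry) as a DataFrame."""
        data: dict = {"zone_id": self._ids}
        if self._populations is not None:
            data["population"] = self._populations
        if self._quintiles is not None:
            data["quintile"] = self._quintiles
        for k, v in self._extra.items():
            data[k] = v
        return pd.DataFrame(data)

    # -- derivation ---------------------------------------------------------
    def replace(self, populations=None, quintiles=None, extra: Mapping[str, Sequence] | None = None) -> "ZoneSet":
        """Return a copy with the given attributes replaced/added."""
        new_extra = dict(self._extra)
        if extra:
            for k, v in extra.items():
                new_extra[str(k)] = np.asarray(v, dtype=object)
        return ZoneSet(
            self._ids,
            self._polygons,
            populations=self._populations if populations is None else populations,
            quintiles=self._quintiles if quintiles is None else quintiles,
            extra=new_extra,
        )

    def validate_zone_ids(self, ids: Iterable) -> None:
        """Raise listing any ids not present in this geography."""
        unknown = sorted({i for i in ids if i not in self._index}, key=str)
        if unknown:
            shown = unknown[:10]
            more = "" if len(unknown) <= 10 else f" (+{len(unknown) - 10} more)"
            raise ZoneSetError(f"unknown zone ids: {shown}{more}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        bits = [f"n={self.n}"]
        if self._populations is not None:
            bits.append(f"total_population={int(self._populations.sum())}")
        if self._quintiles is not None:
            bits.append("quintiles=assigned")
        return f"ZoneSet({', '.join(bits)})"
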