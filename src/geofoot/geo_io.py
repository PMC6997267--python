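"""GeoJSON I/O and choropleth rendering.

GeoJSON (RFC 7946) is the canonical interchange format for the zone
geography: one Feature per zone with ``zone_id``, ``population`` and
``quintile`` properties (names configurable on read). Coordinates are
treated as planar/projected throughout — distance-band weights are
Euclidean — so files declaring a geographic (longitude/latitude) CRS are
rejected with an explanatory error rather than silently mis-measured.

ESRI shapefile input is not supported in this build (no shapefile reader
is available); convert to GeoJSON first (e.g. ``ogr2ogr -f GeoJSON``).

Maps are rendered as deterministic SVG choropleths: diverging red (hot
tiers, darker = higher confidence) / blue (cold tiers) / neutral grey.
"""

from __future__ import annotations

import json
import warnings
from typing import Mapping

import numpy as np

from .zones import ZoneSet, ZoneSetError

from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.geometry.polygon import orient


class GeoIOError(ValueError):
    pass


_DEFAULT_PROPERTY_MAP = {"zone_id": "zone_id", "population": "population", "quintile": "quintile"}

#: confidence-bin fill colours: dark->light red for hot, light->dark blue for cold
BIN_COLORS = {
    "hot_99": "#67000d",
    "hot_95": "#cb181d",
    "hot_90": "#fb6a4a",
    "not_significant": "#bdbdbd",
    "cold_90": "#6baed6",
    "cold_95": "#2171b5",
    "cold_99": "#08306b",
}


def _orient_geometry(geom):
    """Normalise ring orientation to RFC 7946 (exterior CCW, holes CW)."""
    if isinstance(geom, Polygon):
        return orient(geom, sign=1.0)
    if isinstance(geom, MultiPolygon):
        return MultiPolygon([orient(g, sign=1.0) for g in geom.geoms])
    return geom


def write_zones(zones: ZoneSet, path) -> None:
    """Write a ZoneSet as an RFC 7946 GeoJSON FeatureCollection.

    Property key order is deterministic: zone_id, population, quintile,
    then extra properties sorted by name.
    """
    extra = zones.extra
    feats = []
    pops = zones.populations if zones.has_populations else None
    quints = zones.quintiles if zones.has_quintiles else None
    for i, (zid, geom) in enumerate(zip(zones.zone_ids, zones.polygons)):
        props: dict = {"zone_id": zid}
        if pops is not None:
            props["population"] = int(pops[i])
        if quints is not None:
            props["quintile"] = int(quints[i])
        for k in sorted(extra):
            v = extra[k][i]
            props[k] = v.item() if isinstance(v, np.generic) else v
        feats.append(
            {"type": "Feature", "properties": props, "geometry": mapping(_orient_geometry(geom))}
        )
    doc = {"type": "FeatureCollection", "features": feats}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, separators=(",", ":"))
        fh.write("\n")


def read_zones(path, fmt: str = "geojson", property_map: Mapping[str, str] | None = None,
               require_quintile: bool = True) -> ZoneSet:
    """Read a zone geography from GeoJSON.

    Parameters
    ----------
    path : path-like
    fmt : {"geojson"}
        Only GeoJSON is supported; a shapefile path raises with advice.
    property_map : mapping, optional
        Feature-property names holding ``zone_id``, ``population`` and
        ``quintile`` (e.g. ``{"zone_id": "DataZone", "quintile": "Quintile"}``).
    require_quintile : bool
        If False, files without a quintile property load with quintiles unset.
    """
    if fmt == "shapefile":
        raise GeoIOError(
            "shapefile input is not supported in this build: no shapefile reader is "
            "installed. Convert to GeoJSON in a projected CRS first, e.g. "
            "`ogr2ogr -f GeoJSON -t_srs EPSG:27700 zones.geojson zones.shp`."
        )
    if fmt != "geojson":
        raise GeoIOError(f"unknown format {fmt!r}; expected 'geojson'")
    pm = dict(_DEFAULT_PROPERTY_MAP)
    if property_map:
        pm.update(property_map)

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeoIOError(f"expected a GeoJSON FeatureCollection, got type {doc.get('type')!r}")

    crs = doc.get("crs")
    if crs is not None:
        name = str(crs.get("properties", {}).get("name", ""))
        if any(tag in name for tag in ("4326", "CRS84")):
            raise GeoIOError(
                f"geographic (longitude/latitude) CRS {name!r} is not supported: distance-band "
                "weights are Euclidean. Reproject to a planar CRS (e.g. the national grid, "
                "EPSG:27700) before loading."
            )

    ids, polys, pops, quints, extra_rows = [], [], [], [], []
    repaired = 0
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        geom = feat.get("geometry")
        if geom is None:
            raise GeoIOError(f"feature {k}: missing geometry")
        g = shape(geom)
        oriented = _orient_geometry(g)
        if not g.equals_exact(oriented, 0.0):
            repaired += 1
        g = oriented
        if pm["zone_id"] not in props:
            raise GeoIOError(
                f"feature {k}: missing zone id property {pm['zone_id']!r}; "
                f"available properties: {sorted(props)}"
            )
        ids.append(props[pm["zone_id"]])
        polys.append(g)
        pops.append(props.get(pm["population"]))
        if pm["quintile"] not in props and require_quintile:
            raise GeoIOError(
                f"feature {k}: missing quintile property {pm['quintile']!r}; "
                f"available properties: {sorted(props)}"
            )
        quints.append(props.get(pm["quintile"]))
        extra_rows.append({p: v for p, v in props.items() if p not in set(pm.values())})
    if repaired:
        warnings.warn(f"normalised ring orientation on {repaired} feature(s)", stacklevel=2)

    have_pops = all(p is not None for p in pops) and len(pops) > 0
    have_quints = all(q is not None for q in quints) and len(quints) > 0
    extra_keys = sorted({k for row in extra_rows for k in row})
    extra = {k: [row.get(k) for row in extra_rows] for k in extra_keys} if len(ids) else None
    try:
        return ZoneSet(
            ids,
            polys,
            populations=pops if have_pops else None,
            quintiles=quints if have_quints else None,
            extra=extra,
        )
    except ZoneSetError as exc:
        raise GeoIOError(f"invalid zone data in {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _polygon_patches(geom):
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path as MplPath

    geoms = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    verts: list = []
    codes: list = []
    for g in geoms:
        for ring in [g.exterior, *g.interiors]:
            pts = np.asarray(ring.coords)
            verts.extend(pts)
            codes.extend([MplPath.MOVETO] + [MplPath.LINETO] * (len(pts) - 2) + [MplPath.CLOSEPOLY])
    return PathPatch(MplPath(verts, codes))


def render_map(zones: ZoneSet, field: str, path=None, title: str | None = None):
    """Render a choropleth of a per-zone field.

    ``field="bin"`` draws the tiered hot/cold classification with the
    standard red/blue/grey palette and a legend; any numeric field (e.g.
    ``rate``) is drawn with a sequential colour map. Output format follows
    the path suffix (SVG recommended); SVG output is byte-deterministic
    for identical input. Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    table = zones.table()
    if field == "quintile":
        values = zones.quintiles
    elif field in table.columns:
        values = table[field].to_numpy()
    else:
        raise GeoIOError(f"field {field!r} not present on zones; have {sorted(table.columns)}")

    with matplotlib.rc_context({"svg.hashsalt": "geofoot"}):
        fig, ax = plt.subplots(figsize=(7, 7))
        if field == "bin":
            unknown = sorted(set(values) - set(BIN_COLORS))
            if unknown:
                raise GeoIOError(f"unknown confidence bins {unknown}")
            for geom, b in zip(zones.polygons, values):
                patch = _polygon_patches(geom)
                patch.set_facecolor(BIN_COLORS[b])
                patch.set_edgecolor("white")
                patch.set_linewidth(0.3)
                ax.add_patch(patch)
            handles = [Patch(facecolor=BIN_COLORS[b], label=b) for b in BIN_COLORS if b in set(values)]
            ax.legend(handles=handles, loc="upper right", fontsize=8, frameon=False)
        else:
            vals = np.asarray(values, dtype=float)
            finite = vals[np.isfinite(vals)]
            vmin = finite.min() if finite.size else 0.0
            vmax = finite.max() if finite.size else 1.0
            cmap = plt.get_cmap("viridis")
            span = (vmax - vmin) or 1.0
            for geom, v in zip(zones.polygons, vals):
                patch = _polygon_patches(geom)
                color = "#dddddd" if not np.isfinite(v) else cmap((v - vmin) / span)
                patch.set_facecolor(color)
                patch.set_edgecolor("white")
                patch.set_linewidth(0.3)
                ax.add_patch(patch)
        xmin, ymin, xmax, ymax = zones.bounds()
        ax.set_xlim(xmin, xmax)
        ax.set_ylim(ymin, ymax)
        ax.set_aspect("equal")
        ax.set_axis_off()
        if title:
            ax.set_title(title)
        if path is not None:
            fig.savefig(path, metadata={"Date": None}, bbox_inches="tight")
            plt.close(fig)
        return fig
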