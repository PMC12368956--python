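"""Voronoi movement maps: excitable region, tessellation, case maps.

Each electrode site is surrounded by its Voronoi cell — the set of points
nearer to it than to any other site — clipped to the case's excitable
region (the drawn craniotomy when supplied, otherwise the convex hull of
the sites dilated by half the median nearest-neighbour spacing).  Cells of
responsive sites carry that site's evoked-movement labels (suprathreshold:
any movement evoked at a current up to the protocol ceiling); cells of
nonresponsive sites exist (they bound their neighbours) but carry no
labels and contribute no area to any movement.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import MultiPoint, Point, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry

from .geometry import RegionGeometry
from .protocol import StimProtocol
from .sites import StimSite
from .taxonomy import MovementLabel, MovementTaxonomy

MERGE_TOL_MM = 1e-6


class TessellationError(ValueError):
    pass


@dataclass(frozen=True)
class Cell:
    """One site's Voronoi cell, clipped to the case region."""

    site_id: str
    polygon: BaseGeometry
    labels: frozenset[MovementLabel] = frozenset()
    position: tuple[float, float] | None = None

    @property
    def area_mm2(self) -> float:
        return self.polygon.area


@dataclass(frozen=True)
class CaseMap:
    """A case's movement map: sites, geometry, region and labelled cells."""

    case_id: str
    sites: tuple[StimSite, ...]
    geometry: RegionGeometry | None
    region: Polygon
    cells: tuple[Cell, ...]

    @property
    def responsive_cells(self) -> tuple[Cell, ...]:
        return tuple(c for c in self.cells if c.labels)

    @property
    def excitable_area_mm2(self) -> float:
        """Area of the union of movement-evoking cells (the "All" denominator).

        Cells have pairwise-disjoint interiors, so the union area is the sum.
        """
        return sum(c.area_mm2 for c in self.responsive_cells)


def excitable_region(
    positions: Sequence[tuple[float, float]] | np.ndarray,
    craniotomy: Polygon | None = None,
) -> Polygon:
    """Clipping region for a case's map.

    The craniotomy polygon when provided; otherwise the convex hull of the
    site positions dilated by half the median nearest-neighbour distance
    (dilation guarantees 2D extent even for degenerate collinear layouts).
    """
    if craniotomy is not None:
        return craniotomy
    pts = np.asarray(positions, dtype=float)
    if len(pts) < 3:
        raise TessellationError(
            f"need >= 3 sites or a craniotomy polygon, got {len(pts)} sites"
        )
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    nn = np.median(dists[:, 1])
    if nn <= 0:
        raise TessellationError("all sites coincident; cannot build a region")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    return hull.buffer(nn / 2.0)


def _merge_coincident(pts: np.ndarray, tol: float = MERGE_TOL_MM) -> tuple[np.ndarray, list[int]]:
    """Merge points closer than ``tol``; returns unique points and, per
    input point, the index of its representative unique point."""
    unique: list[np.ndarray] = []
    assign: list[int] = []
    for p in pts:
        for j, u in enumerate(unique):
            if np.hypot(*(p - u)) <= tol:
                assign.append(j)
                break
        else:
            unique.append(p)
            assign.append(len(unique) - 1)
    if len(unique) < len(pts):
        warnings.warn(
            f"merged {len(pts) - len(unique)} coincident site position(s) within {tol} mm",
            stacklevel=3,
        )
    return np.array(unique), assign


def tessellate(
    positions: Sequence[tuple[float, float]] | np.ndarray,
    region: Polygon,
) -> list[BaseGeometry]:
    """Voronoi cells of ``positions`` clipped to ``region``.

    Returns one polygon per input position, in input order; positions
    coincident within 1e-6 mm are merged (with a warning) and share a cell.
    A position outside the region is an error naming the site index.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise TessellationError("positions must be an (n, 2) array")
    for i, p in enumerate(pts):
        if not region.covers(Point(*p)):
            raise TessellationError(f"site index {i} at {tuple(p)} lies outside the region")
    uniq, assign = _merge_coincident(pts)
    n = len(uniq)
    if n == 1:
        return [region] * len(pts)
    # guard generators far outside the region bound every real cell, and are
    # never the nearest generator for any point inside the region
    minx, miny, maxx, maxy = region.bounds
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    diam = math.hypot(maxx - minx, maxy - miny)
    spread = float(np.max(np.hypot(uniq[:, 0] - cx, uniq[:, 1] - cy))) if n else 0.0
    radius = 10.0 * max(diam, spread, 1.0)
    angles = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    guards = np.column_stack([cx + radius * np.cos(angles), cy + radius * np.sin(angles)])
    vor = Voronoi(np.vstack([uniq, guards]))
    cells: list[BaseGeometry] = []
    for i in range(n):
        verts_idx = vor.regions[vor.point_region[i]]
        if -1 in verts_idx or not verts_idx:
            raise TessellationError("unbounded Voronoi cell despite guard points")
        poly = Polygon(vor.vertices[verts_idx])
        cells.append(poly.intersection(region))
    return [cells[j] for j in assign]


def build_case_map(
    sites: Sequence[StimSite],
    geometry: RegionGeometry | None = None,
    protocol: StimProtocol | None = None,
    region: Polygon | None = None,
) -> CaseMap:
    """Assemble a case's movement map.

    Cell labels are the site's evoked movements observed at any current up
    to the protocol ceiling (suprathreshold map semantics).  Sites merged
    for coincident positions pool their labels into the shared cell.
    """
    protocol = protocol or StimProtocol()
    if not sites:
        raise TessellationError("no sites")
    case_ids = {s.case_id for s in sites}
    if len(case_ids) > 1:
        raise TessellationError(f"sites span multiple cases: {sorted(case_ids)}")
    positions = [s.position for s in sites]
    if region is None:
        craniotomy = geometry.craniotomy if geometry is not None else None
        region = excitable_region(positions, craniotomy)
    polys = tessellate(positions, region)
    # group sites sharing a polygon object (merged coincident positions)
    by_poly: dict[int, list[int]] = {}
    for i, poly in enumerate(polys):
        by_poly.setdefault(id(poly), []).append(i)
    cells: list[Cell] = []
    for idxs in by_poly.values():
        members = [sites[i] for i in idxs]
        labels: set[MovementLabel] = set()
        for s in members:
            labels.update(_suprathreshold_labels(s, protocol))
        cells.append(
            Cell(
                site_id=members[0].site_id,
                polygon=polys[idxs[0]],
                labels=frozenset(labels),
                position=members[0].position,
            )
        )
    return CaseMap(
        case_id=sites[0].case_id,
        sites=tuple(sites),
        geometry=geometry,
        region=region,
        cells=tuple(cells),
    )


def _suprathreshold_labels(site: StimSite, protocol: StimProtocol) -> set[MovementLabel]:
    labels: set[MovementLabel] = set()
    for lab in site.movements:
        series = site.trials.get(lab)
        if series is None:
            labels.add(lab)  # recorded movement without a trial series
            continue
        if any(t.observed and t.current_ua <= protocol.max_current_ua + 1e-9 for t in series):
            labels.add(lab)
    return labels


# ---------------------------------------------------------------------------
# GeoJSON export / import of case maps


def case_map_to_geojson(case_map: CaseMap, path: str | Path) -> None:
    """Write a case map: one polygon Feature per cell (site_id + labels),
    plus the clipping region."""
    features = [
        {
            "type": "Feature",
            "properties": {"kind": "region", "name": "excitable-region"},
            "geometry": mapping(case_map.region),
        }
    ]
    for cell in case_map.cells:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "kind": "cell",
                    "site_id": cell.site_id,
                    "labels": sorted(str(l) for l in cell.labels),
                    "site_xy": list(cell.position) if cell.position else None,
                },
                "geometry": mapping(cell.polygon),
            }
        )
    doc = {"type": "FeatureCollection", "case_id": case_map.case_id, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def case_map_from_geojson(path: str | Path, taxonomy: MovementTaxonomy) -> CaseMap:
    """Rebuild a case map from its GeoJSON export.

    Sites are reconstructed as label-only stubs (no trial series); this is
    sufficient for quantification and consensus.
    """
    with open(path) as fh:
        doc = json.load(fh)
    case_id = str(doc.get("case_id", Path(path).stem))
    region: Polygon | None = None
    cells: list[Cell] = []
    sites: list[StimSite] = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if props.get("kind") == "region":
            region = geom
        elif props.get("kind") == "cell":
            labels = frozenset(taxonomy.parse(t) for t in props.get("labels", []))
            xy = props.get("site_xy")
            pos = tuple(xy) if xy else tuple(geom.representative_point().coords[0])
            cell = Cell(str(props["site_id"]), geom, labels, pos)
            cells.append(cell)
            sites.append(
                StimSite(
                    case_id=case_id,
                    site_id=cell.site_id,
                    position=pos,  # type: ignore[arg-type]
                    movements=labels,
                )
            )
    if region is None:
        raise TessellationError(f"{path}: no region feature")
    return CaseMap(case_id, tuple(sites), None, region, tuple(cells))
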