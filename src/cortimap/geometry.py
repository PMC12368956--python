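"""Cortical region geometry: field boundaries, sulci, landmarks, craniotomy.

Geometry arrives already in the same mm coordinate frame as the stimulation
sites (histological boundaries are taken as given input).  The on-disk
format is a GeoJSON FeatureCollection whose features carry properties
``kind`` (field / sulcus / craniotomy / landmark), ``name``, and, for field
boundaries, ``confidence`` (solid for histologically clear borders, dashed
for borders estimated from other cases).

Field assignment places each site in the field polygon containing it;
sites on a shared boundary are resolved by a fixed deterministic field
order and flagged, mirroring how ambiguous boundary sites would otherwise
be resolved by eye.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from shapely.geometry import LineString, Point, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry

from .sites import StimSite

#: Deterministic tie-break order for boundary-contact assignment.
FIELD_ORDER = ("PM", "M1", "3a", "3b", "1/2", "PPC")

CONFIDENCES = ("solid", "dashed")
KINDS = ("field", "sulcus", "craniotomy", "landmark")


class GeometryError(ValueError):
    """Region geometry fails validation."""


@dataclass(frozen=True)
class FieldBoundary:
    geometry: BaseGeometry  # Polygon, or LineString for open borders
    confidence: str = "solid"

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCES:
            raise GeometryError(f"unknown confidence {self.confidence!r}")


@dataclass(frozen=True)
class RegionGeometry:
    """A case's field boundaries, sulci, craniotomy and registration landmarks."""

    case_id: str
    field_boundaries: Mapping[str, FieldBoundary] = field(default_factory=dict)
    sulci: Mapping[str, LineString] = field(default_factory=dict)
    craniotomy: Polygon | None = None
    landmarks: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.field_boundaries:
            if name not in FIELD_ORDER:
                raise GeometryError(f"unknown field name {name!r}")

    def landmark_points(self) -> dict[str, Point]:
        return {k: Point(*v) for k, v in self.landmarks.items()}


def _validate_geometry(geom: BaseGeometry, name: str) -> BaseGeometry:
    if geom.is_empty:
        raise GeometryError(f"feature {name!r}: empty geometry")
    if not geom.is_valid:
        raise GeometryError(f"feature {name!r}: invalid geometry (self-intersection?)")
    return geom


def read_region_geometry(path: str | Path) -> RegionGeometry:
    """Read a region-geometry GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{path}: expected a GeoJSON FeatureCollection")
    case_id = str(doc.get("case_id", Path(path).stem))
    boundaries: dict[str, FieldBoundary] = {}
    sulci: dict[str, LineString] = {}
    landmarks: dict[str, tuple[float, float]] = {}
    craniotomy: Polygon | None = None
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        kind = props.get("kind")
        name = props.get("name", "")
        if kind not in KINDS:
            raise GeometryError(f"{path}: feature {name!r} has unknown kind {kind!r}")
        geom = _validate_geometry(shape(feat["geometry"]), name)
        if kind == "field":
            boundaries[name] = FieldBoundary(geom, props.get("confidence", "solid"))
        elif kind == "sulcus":
            sulci[name] = geom
        elif kind == "craniotomy":
            craniotomy = geom
        elif kind == "landmark":
            landmarks[name] = (geom.x, geom.y)
    return RegionGeometry(case_id, boundaries, sulci, craniotomy, landmarks)


def write_region_geometry(geometry: RegionGeometry, path: str | Path) -> None:
    """Write region geometry as a GeoJSON FeatureCollection."""
    features: list[dict] = []
    for name, fb in geometry.field_boundaries.items():
        features.append(
            {
                "type": "Feature",
                "properties": {"kind": "field", "name": name, "confidence": fb.confidence},
                "geometry": mapping(fb.geometry),
            }
        )
    for name, line in geometry.sulci.items():
        features.append(
            {
                "type": "Feature",
                "properties": {"kind": "sulcus", "name": name},
                "geometry": mapping(line),
            }
        )
    if geometry.craniotomy is not None:
        features.append(
            {
                "type": "Feature",
                "properties": {"kind": "craniotomy", "name": "craniotomy"},
                "geometry": mapping(geometry.craniotomy),
            }
        )
    for name, xy in geometry.landmarks.items():
        features.append(
            {
                "type": "Feature",
                "properties": {"kind": "landmark", "name": name},
                "geometry": mapping(Point(*xy)),
            }
        )
    doc = {"type": "FeatureCollection", "case_id": geometry.case_id, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


@dataclass
class AssignmentReport:
    """What field assignment did: tie-breaks and manual-assignment conflicts."""

    tie_breaks: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    conflicts: list[tuple[str, str, str]] = field(default_factory=list)  # site, manual, geometric
    unassigned: list[str] = field(default_factory=list)


def assign_fields(
    sites: Sequence[StimSite],
    geometry: RegionGeometry,
) -> tuple[list[StimSite], AssignmentReport]:
    """Assign each site to the field polygon containing its position.

    Sites outside every polygon become ``unassigned``.  A site touching
    several field boundaries is assigned to the lowest field in
    :data:`FIELD_ORDER` and flagged ``field_tie_break``.  Pre-existing
    manual assignments are kept; disagreements with the geometric
    assignment are recorded as conflicts (warnings, not failures).
    Assignment depends only on position and geometry, never on input order.
    """
    report = AssignmentReport()
    out: list[StimSite] = []
    for site in sites:
        pt = Point(*site.position)
        containing = tuple(
            f
            for f in FIELD_ORDER
            if f in geometry.field_boundaries
            and isinstance(geometry.field_boundaries[f].geometry, Polygon)
            and geometry.field_boundaries[f].geometry.covers(pt)
        )
        if not containing:
            geometric = "unassigned"
        else:
            geometric = containing[0]
        extra: tuple[str, ...] = ()
        if len(containing) > 1:
            report.tie_breaks.append((site.site_id, containing))
            extra = ("field_tie_break",)
        if site.field != "unassigned":
            if geometric != "unassigned" and geometric != site.field:
                report.conflicts.append((site.site_id, site.field, geometric))
                warnings.warn(
                    f"site {site.case_id}/{site.site_id}: manual field {site.field!r} kept; "
                    f"geometry says {geometric!r}",
                    stacklevel=2,
                )
            out.append(site.with_field(site.field, extra))
        else:
            if geometric == "unassigned":
                report.unassigned.append(site.site_id)
            out.append(site.with_field(geometric, extra))
    return out, report
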