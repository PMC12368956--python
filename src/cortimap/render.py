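"""SVG rendering of movement maps and consensus maps.

Case maps follow the conventions of printed movement maps: one polygon
per electrode site, filled by body part (multi-movement cells striped),
dots at responsive sites, X marks at nonresponsive ones, solid/dashed
field borders.  Consensus maps shade overlap depth (darker = more cases)
with an n-of-m key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

from .registration import ConsensusMap
from .tessellation import CaseMap

# body-part palette, grouped by body region hue family
PALETTE = {
    "tongue": "#d62728",
    "lips": "#ff7f0e",
    "jaw": "#e377c2",
    "ear": "#bc6c25",
    "eye": "#8c564b",
    "eyelid": "#c49c94",
    "shoulder": "#1f77b4",
    "elbow": "#17becf",
    "wrist": "#9edae5",
    "digit": "#2ca02c",
    "trunk": "#7f7f7f",
    "hip": "#9467bd",
    "knee": "#c5b0d5",
    "ankle": "#bcbd22",
    "toe": "#dbdb8d",
}
_FALLBACK = "#cccccc"


def _poly_paths(geom: BaseGeometry) -> list[np.ndarray]:
    if isinstance(geom, Polygon):
        return [np.asarray(geom.exterior.coords)]
    if isinstance(geom, MultiPolygon):
        return [np.asarray(p.exterior.coords) for p in geom.geoms]
    return []


def _path_d(coords: np.ndarray) -> str:
    pts = " L ".join(f"{x:.3f} {y:.3f}" for x, y in coords)
    return f"M {pts} Z"


class _SVG:
    """Tiny SVG document builder (mm user units, y flipped to screen)."""

    def __init__(self, bounds: tuple[float, float, float, float], scale: float = 20.0):
        minx, miny, maxx, maxy = bounds
        self.minx, self.maxy = minx, maxy
        self.scale = scale
        self.width = (maxx - minx) * scale
        self.height = (maxy - miny) * scale
        self.defs: list[str] = []
        self.body: list[str] = []

    def tx(self, coords: np.ndarray) -> np.ndarray:
        out = np.asarray(coords, dtype=float).copy()
        out[:, 0] = (out[:, 0] - self.minx) * self.scale
        out[:, 1] = (self.maxy - out[:, 1]) * self.scale
        return out

    def polygon(self, geom: BaseGeometry, fill: str, stroke: str = "#333", width: float = 0.5, dashed: bool = False, opacity: float = 1.0) -> None:
        dash = ' stroke-dasharray="6 4"' if dashed else ""
        for coords in _poly_paths(geom):
            d = _path_d(self.tx(coords))
            self.body.append(
                f'<path d="{d}" fill="{fill}" fill-opacity="{opacity}" '
                f'stroke="{stroke}" stroke-width="{width}"{dash}/>'
            )

    def polyline(self, coords: np.ndarray, stroke: str = "#000", width: float = 1.0, dashed: bool = False) -> None:
        pts = " ".join(f"{x:.3f},{y:.3f}" for x, y in self.tx(coords))
        dash = ' stroke-dasharray="6 4"' if dashed else ""
        self.body.append(
            f'<polyline points="{pts}" fill="none" stroke="{stroke}" stroke-width="{width}"{dash}/>'
        )

    def marker(self, xy: tuple[float, float], kind: str) -> None:
        (x, y) = self.tx(np.array([xy]))[0]
        if kind == "dot":
            self.body.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="2.2" fill="#000"/>')
        else:  # X mark for nonresponsive sites
            r = 3.0
            self.body.append(
                f'<path d="M {x - r:.2f} {y - r:.2f} L {x + r:.2f} {y + r:.2f} '
                f'M {x - r:.2f} {y + r:.2f} L {x + r:.2f} {y - r:.2f}" '
                f'stroke="#000" stroke-width="1.2"/>'
            )

    def text(self, xy: tuple[float, float], s: str, size: float = 12.0) -> None:
        (x, y) = self.tx(np.array([xy]))[0]
        self.body.append(f'<text x="{x:.1f}" y="{y:.1f}" font-size="{size}">{s}</text>')

    def stripe_pattern(self, pid: str, colors: Sequence[str]) -> str:
        n = len(colors)
        w = 6.0 * n
        stripes = "".join(
            f'<rect x="{6.0 * i}" y="0" width="6" height="{w}" fill="{c}"/>'
            for i, c in enumerate(colors)
        )
        self.defs.append(
            f'<pattern id="{pid}" width="{w}" height="{w}" patternUnits="userSpaceOnUse" '
            f'patternTransform="rotate(45)">{stripes}</pattern>'
        )
        return f"url(#{pid})"

    def render(self) -> str:
        return (
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{self.width:.0f}" '
            f'height="{self.height:.0f}" viewBox="0 0 {self.width:.0f} {self.height:.0f}">\n'
            f"<defs>{''.join(self.defs)}</defs>\n" + "\n".join(self.body) + "\n</svg>\n"
        )


def case_map_svg(case_map: CaseMap, path: str | Path) -> None:
    """Render a case's movement map to SVG."""
    pad = 1.0
    minx, miny, maxx, maxy = case_map.region.bounds
    svg = _SVG((minx - pad, miny - pad, maxx + pad, maxy + pad))
    svg.polygon(case_map.region, fill="#f7f7f7", stroke="#000", width=1.0)
    for i, cell in enumerate(case_map.cells):
        parts = sorted({l.body_part for l in cell.labels})
        if not parts:
            fill = "#ffffff"
        elif len(parts) == 1:
            fill = PALETTE.get(parts[0], _FALLBACK)
        else:
            fill = svg.stripe_pattern(
                f"stripes{i}", [PALETTE.get(p, _FALLBACK) for p in parts]
            )
        svg.polygon(cell.polygon, fill=fill, stroke="#444", width=0.4, opacity=0.85)
    if case_map.geometry is not None:
        for name, fb in case_map.geometry.field_boundaries.items():
            for coords in _poly_paths(fb.geometry):
                svg.polyline(coords, stroke="#000", width=1.2, dashed=fb.confidence == "dashed")
        for coords in (np.asarray(s.coords) for s in case_map.geometry.sulci.values()):
            svg.polyline(coords, stroke="#555", width=1.5)
    for cell in case_map.cells:
        if cell.position is not None:
            svg.marker(cell.position, "dot" if cell.labels else "x")
    svg.text((minx - pad + 0.2, maxy + pad - 0.2), case_map.case_id, size=16)
    Path(path).write_text(svg.render())


def consensus_svg(cmap: ConsensusMap, path: str | Path, color: str = "#1f77b4") -> None:
    """Render a consensus map: iso-depth bands shaded darker with depth,
    with an n-of-m key."""
    ny, nx = cmap.grid.shape
    res = cmap.resolution_mm
    x0, y0 = cmap.origin
    bounds = (x0 - res, y0 - res, x0 + nx * res, y0 + ny * res)
    svg = _SVG(bounds)
    for depth in range(1, cmap.n_cases + 1):
        opacity = depth / cmap.n_cases
        for line in cmap.iso_depth_contours(depth):
            d = _path_d(svg.tx(line))
            svg.body.append(
                f'<path d="{d}" fill="{color}" fill-opacity="{opacity * 0.8:.3f}" '
                f'stroke="none" fill-rule="evenodd"/>'
            )
    if cmap.averaged_geometry is not None:
        for geom in cmap.averaged_geometry.boundaries.values():
            for coords in _poly_paths(geom) or [np.asarray(geom.coords)]:
                svg.polyline(coords, stroke="#000", width=1.0)
        for line in cmap.averaged_geometry.sulci.values():
            svg.polyline(np.asarray(line.coords), stroke="#555", width=1.5)
    for depth in range(1, cmap.n_cases + 1):
        y = bounds[3] - 0.6 * depth
        svg.text((bounds[0] + 0.3, y), f"{depth}/{cmap.n_cases}", size=11)
    svg.text((bounds[0] + 0.3, bounds[3] - 0.1), cmap.movement, size=14)
    Path(path).write_text(svg.render())
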