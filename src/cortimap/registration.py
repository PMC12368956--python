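"""Cross-case alignment, boundary averaging, and consensus (overlap) maps.

Cases are aligned into a common frame with a least-squares similarity
transform (rotation + uniform scale + translation) fitted to named
landmarks shared across cases: uniform scale absorbs brain-size
differences without shearing the somatotopy.  Field boundaries and sulci
are averaged pointwise after arc-length-uniform resampling.  Consensus
maps count, per raster pixel, in how many aligned cases a given movement's
labelled cells cover that location — the overlap-depth shading of averaged
movement maps (a depth of 2 out of 4 means the movement was evoked there
in two of four cases).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import LineString, Polygon, mapping
from shapely.geometry.base import BaseGeometry
from shapely.geometry.polygon import orient
from shapely.ops import unary_union

from .geometry import FieldBoundary, RegionGeometry
from .quantify import _as_predicate
from .tessellation import CaseMap, Cell


class RegistrationError(ValueError):
    pass


@dataclass(frozen=True)
class Transform2D:
    """Similarity transform: rotate by ``rotation``, scale, then translate."""

    rotation: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise RegistrationError(f"scale must be positive, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray | Sequence[Sequence[float]]) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + np.asarray(self.translation)

    def apply_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        m = self.matrix
        return affinity.affine_transform(
            geom, [m[0, 0], m[0, 1], m[1, 0], m[1, 1], *self.translation]
        )

    def inverse(self) -> "Transform2D":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        t = np.asarray(self.translation)
        c, s = math.cos(inv_rot), math.sin(inv_rot)
        m = inv_scale * np.array([[c, -s], [s, c]])
        inv_t = -(m @ t)
        return Transform2D(inv_rot, inv_scale, (float(inv_t[0]), float(inv_t[1])))

    @staticmethod
    def identity() -> "Transform2D":
        return Transform2D()


def fit_alignment(
    src: Mapping[str, tuple[float, float]],
    ref: Mapping[str, tuple[float, float]],
) -> tuple[Transform2D, dict[str, float]]:
    """Least-squares similarity transform taking ``src`` landmarks onto
    ``ref`` landmarks matched by name (closed-form orthogonal-Procrustes
    solution with uniform scale).

    Returns the transform and the per-landmark residual distance after
    alignment.  Requires >= 2 common landmark names, not all coincident.
    """
    names = sorted(set(src) & set(ref))
    if len(names) < 2:
        raise RegistrationError(
            f"need >= 2 common landmark names, got {len(names)}: {names}"
        )
    X = np.array([src[n] for n in names], dtype=float)
    Y = np.array([ref[n] for n in names], dtype=float)
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    var_x = float((Xc**2).sum()) / len(names)
    if var_x <= 1e-18:
        raise RegistrationError("all source landmarks coincident")
    cov = (Yc.T @ Xc) / len(names)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    scale = float((D * np.diag(S)).sum() / var_x)
    rotation = math.atan2(R[1, 0], R[0, 0])
    t = my - scale * (R @ mx)
    transform = Transform2D(rotation, scale, (float(t[0]), float(t[1])))
    aligned = transform.apply(X)
    residuals = {n: float(np.hypot(*(aligned[i] - Y[i]))) for i, n in enumerate(names)}
    return transform, residuals


def transform_geometry(geometry: RegionGeometry, transform: Transform2D) -> RegionGeometry:
    """Apply a transform to every component of a region geometry."""
    return RegionGeometry(
        case_id=geometry.case_id,
        field_boundaries={
            k: FieldBoundary(transform.apply_geometry(fb.geometry), fb.confidence)
            for k, fb in geometry.field_boundaries.items()
        },
        sulci={k: transform.apply_geometry(v) for k, v in geometry.sulci.items()},
        craniotomy=(
            transform.apply_geometry(geometry.craniotomy)
            if geometry.craniotomy is not None
            else None
        ),
        landmarks={
            k: tuple(transform.apply([v])[0]) for k, v in geometry.landmarks.items()
        },
    )


def transform_case_map(case_map: CaseMap, transform: Transform2D) -> CaseMap:
    """Apply a transform to a case map's region, cells and sites."""
    cells = tuple(
        Cell(
            c.site_id,
            transform.apply_geometry(c.polygon),
            c.labels,
            tuple(transform.apply([c.position])[0]) if c.position else None,
        )
        for c in case_map.cells
    )
    sites = tuple(
        replace(s, position=tuple(transform.apply([s.position])[0])) for s in case_map.sites
    )
    geometry = (
        transform_geometry(case_map.geometry, transform)
        if case_map.geometry is not None
        else None
    )
    return CaseMap(
        case_map.case_id,
        sites,
        geometry,
        transform.apply_geometry(case_map.region),
        cells,
    )


def align_cases(
    geometries: Sequence[RegionGeometry],
    reference: int | Mapping[str, tuple[float, float]] = 0,
) -> list[tuple[Transform2D, dict[str, float]]]:
    """Fit per-case transforms onto a reference landmark set.

    ``reference`` is a case index (default: first case) or an explicit
    landmark mapping, e.g. the landmark-wise mean frame.
    """
    if isinstance(reference, int):
        ref = geometries[reference].landmarks
    else:
        ref = reference
    return [fit_alignment(g.landmarks, ref) for g in geometries]


def mean_landmark_frame(
    geometries: Sequence[RegionGeometry],
) -> dict[str, tuple[float, float]]:
    """Landmark-wise mean positions over landmarks present in every case."""
    common = set(geometries[0].landmarks)
    for g in geometries[1:]:
        common &= set(g.landmarks)
    if not common:
        raise RegistrationError("no landmark shared by all cases")
    return {
        n: tuple(np.mean([g.landmarks[n] for g in geometries], axis=0))
        for n in sorted(common)
    }


# ---------------------------------------------------------------------------
# Boundary / sulcus averaging


def resample_polyline(coords: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` arc-length-uniform points."""
    coords = np.asarray(coords, dtype=float)
    seg = np.hypot(*np.diff(coords, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(coords[:1], n_points, axis=0)
    target = np.linspace(0.0, s[-1], n_points)
    return np.column_stack(
        [np.interp(target, s, coords[:, 0]), np.interp(target, s, coords[:, 1])]
    )


def _align_resampled(refc: np.ndarray, other: np.ndarray, closed: bool) -> np.ndarray:
    """Orient/shift a resampled curve to best match the reference curve."""
    if closed:
        # rings: try every cyclic shift (and orientation handled upstream)
        best, best_cost = other, np.inf
        n = len(other)
        for shift in range(n):
            cand = np.roll(other[:-1], shift, axis=0)
            cand = np.vstack([cand, cand[:1]])
            cost = float(((cand - refc) ** 2).sum())
            if cost < best_cost:
                best, best_cost = cand, cost
        return best
    fwd = float(((other - refc) ** 2).sum())
    rev = float(((other[::-1] - refc) ** 2).sum())
    return other if fwd <= rev else other[::-1]


@dataclass
class AveragedGeometry:
    boundaries: dict[str, BaseGeometry]
    sulci: dict[str, LineString]
    flags: dict[str, str] = field(default_factory=dict)


def average_geometry(
    aligned: Sequence[RegionGeometry],
    n_points: int = 100,
) -> AveragedGeometry:
    """Pointwise-mean field boundaries and sulci over aligned cases.

    Matching curves are resampled to ``n_points`` arc-length-uniform
    points (rings cyclically aligned, open lines orientation-aligned to
    the first case) and averaged pointwise.  A curve present in fewer than
    two cases is passed through unchanged with a flag.
    """
    out = AveragedGeometry({}, {})

    def collect(getter, names: set[str]) -> dict[str, BaseGeometry]:
        result: dict[str, BaseGeometry] = {}
        for name in sorted(names):
            curves = [getter(g, name) for g in aligned if getter(g, name) is not None]
            if len(curves) < 2:
                result[name] = curves[0]
                out.flags[name] = f"present in {len(curves)} case(s); passed through"
                continue
            closed = isinstance(curves[0], Polygon)
            arrays = []
            for c in curves:
                if isinstance(c, Polygon):
                    arrays.append(np.asarray(orient(c).exterior.coords))
                else:
                    arrays.append(np.asarray(c.coords))
            res = [resample_polyline(a, n_points + (1 if closed else 0)) for a in arrays]
            ref = res[0]
            aligned_curves = [ref] + [_align_resampled(ref, r, closed) for r in res[1:]]
            mean = np.mean(aligned_curves, axis=0)
            result[name] = Polygon(mean) if closed else LineString(mean)
        return result

    bnames = {n for g in aligned for n in g.field_boundaries}
    out.boundaries = collect(
        lambda g, n: g.field_boundaries[n].geometry if n in g.field_boundaries else None,
        bnames,
    )
    snames = {n for g in aligned for n in g.sulci}
    out.sulci = collect(lambda g, n: g.sulci.get(n), snames)
    return out


# ---------------------------------------------------------------------------
# Consensus (overlap-depth) maps


@dataclass
class ConsensusMap:
    """Per-pixel overlap depth of one movement across aligned cases."""

    movement: str
    resolution_mm: float
    origin: tuple[float, float]  # (x, y) of the center of pixel [0, 0]
    grid: np.ndarray  # int depth, shape (ny, nx); row i -> y = origin[1] + i*res
    n_cases: int
    averaged_geometry: AveragedGeometry | None = None

    def depth_histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.grid, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def depth_weighted_area_mm2(self) -> float:
        """Sum over pixels of depth x pixel area; equals the summed
        per-case movement areas up to rasterization error."""
        return float(self.grid.sum()) * self.resolution_mm**2

    def area_at_least_mm2(self, depth: int) -> float:
        return float((self.grid >= depth).sum()) * self.resolution_mm**2

    def iso_depth_contours(self, depth: int) -> list[np.ndarray]:
        """Iso-depth contour polylines (mm coordinates) for grid >= depth."""
        from skimage import measure

        mask = (self.grid >= depth).astype(float)
        padded = np.pad(mask, 1, constant_values=0.0)
        contours = measure.find_contours(padded, 0.5)
        out = []
        for c in contours:  # c is (row, col) in padded pixel space
            ys = self.origin[1] + (c[:, 0] - 1) * self.resolution_mm
            xs = self.origin[0] + (c[:, 1] - 1) * self.resolution_mm
            out.append(np.column_stack([xs, ys]))
        return out

    def to_grid_csv(self, path: str | Path) -> None:
        """Plain-text raster export: header with origin/resolution, then
        one row of depths per grid row."""
        with open(path, "w") as fh:
            fh.write(f"# movement={self.movement} n_cases={self.n_cases}\n")
            fh.write(
                f"# origin_x={self.origin[0]:.6f} origin_y={self.origin[1]:.6f} "
                f"resolution_mm={self.resolution_mm}\n"
            )
            np.savetxt(fh, self.grid, fmt="%d", delimiter=",")

    def contours_to_geojson(self, path: str | Path) -> None:
        features = []
        for depth in range(1, self.n_cases + 1):
            for line in self.iso_depth_contours(depth):
                features.append(
                    {
                        "type": "Feature",
                        "properties": {
                            "kind": "iso-depth",
                            "movement": self.movement,
                            "depth": depth,
                            "n_cases": self.n_cases,
                        },
                        "geometry": mapping(LineString(line)),
                    }
                )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def consensus(
    maps: Sequence[CaseMap],
    movement,
    resolution_mm: float = 0.05,
    averaged_geometry: AveragedGeometry | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> ConsensusMap:
    """Rasterized overlap-depth map of ``movement`` across aligned cases.

    Each pixel counts the cases whose matching labelled cells cover the
    pixel center.  ``maps`` must already share a common frame.
    """
    if not maps:
        raise RegistrationError("need at least one case map")
    pred = _as_predicate(movement)
    name = movement if isinstance(movement, str) else getattr(movement, "__name__", "selector")
    if bounds is None:
        xs0 = [m.region.bounds for m in maps]
        minx = min(b[0] for b in xs0) - resolution_mm
        miny = min(b[1] for b in xs0) - resolution_mm
        maxx = max(b[2] for b in xs0) + resolution_mm
        maxy = max(b[3] for b in xs0) + resolution_mm
    else:
        minx, miny, maxx, maxy = bounds
    nx = max(1, int(math.ceil((maxx - minx) / resolution_mm)))
    ny = max(1, int(math.ceil((maxy - miny) / resolution_mm)))
    xs = minx + (np.arange(nx) + 0.5) * resolution_mm
    ys = miny + (np.arange(ny) + 0.5) * resolution_mm
    XX, YY = np.meshgrid(xs, ys)
    depth = np.zeros((ny, nx), dtype=np.int32)
    for cm in maps:
        geoms = [c.polygon for c in cm.cells if any(pred(l) for l in c.labels)]
        if not geoms:
            continue
        u = unary_union(geoms)
        mask = shapely.contains_xy(u, XX.ravel(), YY.ravel()).reshape(ny, nx)
        depth += mask.astype(np.int32)
    return ConsensusMap(
        movement=name,
        resolution_mm=resolution_mm,
        origin=(float(xs[0]), float(ys[0])),
        grid=depth,
        n_cases=len(maps),
        averaged_geometry=averaged_geometry,
    )
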