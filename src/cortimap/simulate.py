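"""Seeded generator of galago-like LT-ICMS mapping cases.

A simulated case is a jittered grid of electrode sites over a flattened
map of roughly 10 x 18 mm, partitioned rostrocaudally into field strips
(PM, M1, 3a, 3b, 1/2, PPC) and mediolaterally into somatotopic bands
(hindlimb medial, then trunk, forelimb, face lateral).  Each responsive
site draws its evoked body part(s) from a band-conditioned composition
table (fracture is modelled as independent per-site draws), a direction
from the taxonomy, and occasionally bilaterality; its threshold is drawn
from a per-field log-normal, snapped to the 10/50 uA staircase grid, and
emitted as a trial staircase that the threshold estimator recovers
exactly by construction.  Field-specific nonresponse and an optional
medial-3b dropout factor (raising thresholds and nonresponse medially,
as under deepening anesthesia) shape the nonresponsive sites.

Cases within a study share the planted truth; each case gets its own
similarity transform into a case-local frame and its own landmark jitter,
so registration and consensus are exercised end to end.  Identical
(params, case_index) pairs produce bit-identical cases.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from shapely.geometry import LineString, Polygon, box

from .geometry import FieldBoundary, RegionGeometry
from .protocol import StimProtocol, StimTrial
from .registration import Transform2D
from .sites import StimSite, write_site_table
from .taxonomy import MovementLabel, MovementTaxonomy, default_taxonomy
from .thresholds import FIELD_GROUPS


class SimulationError(ValueError):
    pass


_DEFAULT_FIELD_LAYOUT = (
    ("PM", 2.5),
    ("M1", 3.0),
    ("3a", 2.0),
    ("3b", 6.5),
    ("1/2", 1.5),
    ("PPC", 2.5),
)

_DEFAULT_SOMATOTOPY = (
    ("hindlimb", 0.23),
    ("trunk", 0.10),
    ("forelimb", 0.32),
    ("face", 0.35),
)

# per-band categorical over body parts, conditional on a responsive site;
# rows sum to <= 1 (any remainder is additional nonresponse)
_DEFAULT_COMPOSITION = {
    "hindlimb": {
        "hip": 0.30,
        "knee": 0.18,
        "ankle": 0.18,
        "toe": 0.16,
        "trunk": 0.08,
        "shoulder": 0.10,
    },
    "trunk": {"trunk": 0.45, "shoulder": 0.40, "hip": 0.10, "elbow": 0.05},
    "forelimb": {
        "shoulder": 0.65,
        "elbow": 0.12,
        "digit": 0.12,
        "wrist": 0.06,
        "trunk": 0.05,
    },
    "face": {
        "tongue": 0.75,
        "lips": 0.10,
        "jaw": 0.04,
        "ear": 0.03,
        "eyelid": 0.03,
        "eye": 0.02,
        "shoulder": 0.03,
    },
}

_DEFAULT_NONRESPONSE = {
    "PM": 0.10,
    "M1": 0.08,
    "3a": 0.08,
    "3b": 0.12,
    "1/2": 0.30,
    "PPC": 0.35,
}

# per field-group log-normal threshold model (median uA, sigma of log);
# medians follow the observed field ordering: 3a < PM/M1 < 3b < 1/2/PPC
_DEFAULT_THRESHOLDS = {
    "PM/M1": (32.0, 0.5),
    "3a": (20.0, 0.5),
    "3b": (55.0, 0.5),
    "1/2/PPC": (80.0, 0.5),
}


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study (distances mm, currents uA)."""

    n_sites: int | None = 160
    grid_pitch_mm: float = 0.7
    extent_mm: tuple[float, float] = (10.0, 18.0)  # (mediolateral, rostrocaudal)
    field_layout: tuple[tuple[str, float], ...] = _DEFAULT_FIELD_LAYOUT
    somatotopy: tuple[tuple[str, float], ...] = _DEFAULT_SOMATOTOPY
    composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COMPOSITION.items()}
    )
    p_multi: float = 0.35
    p_bilateral: float = 0.08
    p_direction: float = 0.8
    p_nonresponsive: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NONRESPONSE)
    )
    threshold_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_THRESHOLDS)
    )
    medial_dropout: float = 1.75
    jitter_mm: float = 0.3
    case_transforms: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        widths = [w for _, w in self.field_layout]
        if any(w <= 0 for w in widths):
            raise SimulationError("field strip widths must be positive")
        if abs(sum(w for _, w in self.field_layout) - self.extent_mm[1]) > 1e-6:
            raise SimulationError("field strip widths must sum to the rostrocaudal extent")
        fracs = [f for _, f in self.somatotopy]
        if abs(sum(fracs) - 1.0) > 1e-6 or any(f <= 0 for f in fracs):
            raise SimulationError("somatotopy band fractions must be positive and sum to 1")
        for band, row in self.composition.items():
            total = sum(row.values())
            if total > 1.0 + 1e-9:
                raise SimulationError(
                    f"composition row for band {band!r} sums to {total:.3f} > 1"
                )
            if any(p < 0 for p in row.values()):
                raise SimulationError(f"negative probability in band {band!r}")
        for name, p in self.p_nonresponsive.items():
            if not 0 <= p <= 1:
                raise SimulationError(f"p_nonresponsive[{name!r}] must be in [0, 1]")
        for p in (self.p_multi, self.p_bilateral, self.p_direction):
            if not 0 <= p <= 1:
                raise SimulationError("probabilities must be in [0, 1]")

    @staticmethod
    def flat(
        composition: Mapping[str, float],
        *,
        p_nonresponsive: float = 0.15,
        **overrides,
    ) -> "SimParams":
        """Spatially uniform variant: one band, one composition row —
        convenient for parameter-recovery experiments where the planted
        per-part probabilities should be the map-wide marginals."""
        return SimParams(
            somatotopy=(("all", 1.0),),
            composition={"all": dict(composition)},
            p_nonresponsive={f: p_nonresponsive for f, _ in _DEFAULT_FIELD_LAYOUT},
            p_multi=overrides.pop("p_multi", 0.0),
            **overrides,
        )


@dataclass
class CaseSim:
    """One simulated case plus its planted truth."""

    case_id: str
    sites: list[StimSite]
    geometry: RegionGeometry
    truth: dict


@dataclass
class StudyBundle:
    params: SimParams
    cases: list[CaseSim]
    manifest: dict


def _field_of_y(y: float, layout, extent_y: float) -> str:
    """Field strip containing rostrocaudal coordinate y (y=extent_y rostral)."""
    top = extent_y
    for name, width in layout:
        if y >= top - width - 1e-12:
            return name
        top -= width
    return layout[-1][0]


def _band_of_x(x: float, somatotopy, extent_x: float) -> str:
    left = 0.0
    for name, frac in somatotopy:
        right = left + frac * extent_x
        if x <= right + 1e-12:
            return name
        left = right
    return somatotopy[-1][0]


def _group_of_field(field_name: str) -> str:
    for gname, members in FIELD_GROUPS.items():
        if field_name in members:
            return gname
    raise SimulationError(f"field {field_name!r} belongs to no threshold group")


def _snap_threshold(
    t: float, protocol: StimProtocol
) -> tuple[float, list[StimTrial]] | None:
    """Snap a drawn threshold onto the staircase midpoint grid and emit the
    bracketing staircase; None when the threshold exceeds the ceiling."""
    if t >= protocol.max_current_ua:
        return None
    lo, hi, bp = protocol.step_low_ua, protocol.step_high_ua, protocol.step_breakpoint_ua
    if t < lo:
        return lo, [StimTrial(lo, True)]  # floor: movement at the lowest tested current
    if t < bp:
        n = min(max(math.floor(t / lo) * lo, lo), bp - lo)
        l = n + lo
    else:
        n = min(bp + math.floor((t - bp) / hi) * hi, protocol.max_current_ua - hi)
        l = n + hi
    return 0.5 * (n + l), [StimTrial(n, False), StimTrial(l, True)]


def _draw_part(rng: np.random.Generator, row: Mapping[str, float]) -> str | None:
    """Categorical draw from a composition row; None lands in the
    nonresponsive remainder."""
    u = rng.random()
    acc = 0.0
    for part, p in row.items():
        acc += p
        if u < acc:
            return part
    return None


def simulate_case(
    params: SimParams,
    case_index: int,
    taxonomy: MovementTaxonomy | None = None,
    protocol: StimProtocol | None = None,
) -> CaseSim:
    """Simulate one case: sites with full trial staircases plus geometry.

    Deterministic: the same (params, case_index) always yields the same
    case, and distinct case indices draw independently.
    """
    taxonomy = taxonomy or default_taxonomy()
    protocol = protocol or StimProtocol()
    rng = np.random.default_rng([params.seed & 0x7FFFFFFF, case_index])
    case_id = f"SIM-{case_index + 1:02d}"
    W, H = params.extent_mm

    # --- site grid (truth frame), jittered, optionally subsampled
    xs = np.arange(params.grid_pitch_mm / 2, W, params.grid_pitch_mm)
    ys = np.arange(params.grid_pitch_mm / 2, H, params.grid_pitch_mm)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    jit = rng.uniform(-0.15, 0.15, size=grid.shape) * params.grid_pitch_mm
    grid = grid + jit
    grid[:, 0] = np.clip(grid[:, 0], 0.05, W - 0.05)
    grid[:, 1] = np.clip(grid[:, 1], 0.05, H - 0.05)
    if params.n_sites is not None and params.n_sites < len(grid):
        keep = np.sort(rng.choice(len(grid), size=params.n_sites, replace=False))
        grid = grid[keep]

    medial_extent = sum(
        frac for name, frac in params.somatotopy if name in ("hindlimb", "trunk")
    ) * W

    # --- geometry in the truth frame, origin at the FS caudal tip
    fs_x = 0.62 * W
    fs_tip = np.array([fs_x, H - 3.5])
    sulci_raw = {
        "FS": [(fs_x, H), (fs_x, H - 3.5)],
        "IPS": [(0.50 * W, 0.0), (0.50 * W, 3.0)],
        "LS": [(0.97 * W, 0.0), (0.85 * W, 5.0)],
    }
    landmarks_raw = {
        "FS-caudal-tip": (fs_x, H - 3.5),
        "IPS-rostral-tip": (0.50 * W, 3.0),
        "LS-rostral-tip": (0.85 * W, 5.0),
        "medial-rostral-corner": (0.0, H),
        "medial-caudal-corner": (0.0, 0.0),
    }
    field_polys: dict[str, Polygon] = {}
    top = H
    for name, width in params.field_layout:
        field_polys[name] = box(0.0, top - width, W, top)
        top -= width

    def to_origin(xy):
        return (xy[0] - fs_tip[0], xy[1] - fs_tip[1])

    # --- per-case similarity transform into the case-local frame
    if params.case_transforms and case_index > 0:
        transform = Transform2D(
            rotation=float(rng.uniform(-0.15, 0.15)),
            scale=float(rng.uniform(0.93, 1.07)),
            translation=(float(rng.uniform(-2, 2)), float(rng.uniform(-2, 2))),
        )
    else:
        transform = Transform2D.identity()

    def place(xy) -> tuple[float, float]:
        out = transform.apply([to_origin(xy)])[0]
        return (float(out[0]), float(out[1]))

    sites: list[StimSite] = []
    site_truth: dict[str, dict] = {}
    for i, (x, y) in enumerate(grid):
        site_id = f"s{i + 1:03d}"
        field_name = _field_of_y(y, params.field_layout, H)
        band = _band_of_x(x, params.somatotopy, W)
        in_medial_3b = field_name == "3b" and x < medial_extent

        p_nr = params.p_nonresponsive.get(field_name, 0.0)
        if in_medial_3b:
            p_nr = min(1.0, p_nr * params.medial_dropout)
        parts: list[str] = []
        if rng.random() >= p_nr:
            row = params.composition.get(band, {})
            primary = _draw_part(rng, row)
            if primary is not None:
                parts.append(primary)
                while len(parts) < 3 and rng.random() < params.p_multi:
                    extra = _draw_part(rng, row)
                    if extra is not None and extra not in parts:
                        parts.append(extra)

        median, sigma = params.threshold_model[_group_of_field(field_name)]
        if in_medial_3b:
            median *= params.medial_dropout
        movements: dict[MovementLabel, tuple[StimTrial, ...]] = {}
        planted: dict[str, float] = {}
        for part in parts:
            direction = None
            dirs = taxonomy.directions.get(part, ())
            if dirs and rng.random() < params.p_direction:
                direction = dirs[rng.integers(len(dirs))]
            laterality = "bilateral" if rng.random() < params.p_bilateral else "contralateral"
            label = taxonomy.validate(MovementLabel(part, direction, laterality))
            t_drawn = float(rng.lognormal(math.log(median), sigma))
            snapped = _snap_threshold(t_drawn, protocol)
            if snapped is None:
                continue  # threshold above ceiling: movement never observed
            thr, staircase = snapped
            movements[label] = tuple(sorted(staircase, key=lambda t: t.current_ua))
            planted[str(label)] = thr

        site = StimSite(
            case_id=case_id,
            site_id=site_id,
            position=place((x, y)),
            depth_um=1800.0,
            field=field_name,
            movements=frozenset(movements),
            trials=movements,
            max_current_ua=protocol.max_current_ua,
        )
        sites.append(site)
        site_truth[site_id] = {
            "field": field_name,
            "band": band,
            "parts": sorted({m.body_part for m in movements}),
            "thresholds_ua": planted,
            "threshold_ua": min(planted.values()) if planted else None,
        }

    boundaries = {
        name: FieldBoundary(transform.apply_geometry(_shift_poly(poly, fs_tip)))
        for name, poly in field_polys.items()
    }
    sulci = {
        name: transform.apply_geometry(LineString([to_origin(p) for p in coords]))
        for name, coords in sulci_raw.items()
    }
    landmarks = {}
    for name, xy in landmarks_raw.items():
        px, py = place(xy)
        landmarks[name] = (
            px + float(rng.normal(0, params.jitter_mm)),
            py + float(rng.normal(0, params.jitter_mm)),
        )
    geometry = RegionGeometry(
        case_id=case_id,
        field_boundaries=boundaries,
        sulci=sulci,
        craniotomy=transform.apply_geometry(_shift_poly(box(0, 0, W, H), fs_tip)),
        landmarks=landmarks,
    )
    truth = {
        "case_id": case_id,
        "transform": {
            "rotation": transform.rotation,
            "scale": transform.scale,
            "translation": list(transform.translation),
        },
        "sites": site_truth,
    }
    return CaseSim(case_id, sites, geometry, truth)


def _shift_poly(poly: Polygon, origin: np.ndarray) -> Polygon:
    coords = np.asarray(poly.exterior.coords) - origin
    return Polygon(coords)


def simulate_study(
    params: SimParams,
    n_cases: int = 4,
    taxonomy: MovementTaxonomy | None = None,
    protocol: StimProtocol | None = None,
) -> StudyBundle:
    """Simulate ``n_cases`` cases sharing the planted truth, with
    independent per-case transforms and landmark jitter."""
    if n_cases < 1:
        raise SimulationError("n_cases must be >= 1")
    cases = [simulate_case(params, i, taxonomy, protocol) for i in range(n_cases)]
    manifest = {
        "seed": params.seed,
        "n_cases": n_cases,
        "composition": {k: dict(v) for k, v in params.composition.items()},
        "threshold_model": {k: list(v) for k, v in params.threshold_model.items()},
        "cases": {c.case_id: c.truth for c in cases},
    }
    return StudyBundle(params, cases, manifest)


def write_study(bundle: StudyBundle, outdir: str | Path) -> dict[str, list[str]]:
    """Write site CSVs, geometry GeoJSON and the truth manifest; returns
    the file listing."""
    from .geometry import write_region_geometry

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    listing: dict[str, list[str]] = {"sites": [], "geometry": []}
    for case in bundle.cases:
        spath = outdir / f"sites_{case.case_id}.csv"
        gpath = outdir / f"geometry_{case.case_id}.geojson"
        write_site_table(case.sites, spath)
        write_region_geometry(case.geometry, gpath)
        listing["sites"].append(spath.name)
        listing["geometry"].append(gpath.name)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1)
    listing["manifest"] = ["truth.json"]
    return listing
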