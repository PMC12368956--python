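#!/usr/bin/env python
"""Align the synthetic cases and build consensus (overlap) movement maps.

Cases are registered into the landmark-wise mean frame with least-squares
similarity transforms; field boundaries and sulci are averaged; and for
each movement of interest a raster counts, per 0.05 mm pixel, in how many
cases that movement was evoked there (the n-of-4 shading of averaged
maps).  Writes contour GeoJSON, plain-grid CSV and shaded SVG per
movement under results/consensus/.
"""

import glob
from pathlib import Path

import numpy as np

from cortimap.geometry import read_region_geometry
from cortimap.quantify import movement_area
from cortimap.registration import (
    align_cases,
    average_geometry,
    consensus,
    mean_landmark_frame,
    transform_case_map,
    transform_geometry,
)
from cortimap.render import consensus_svg
from cortimap.taxonomy import default_taxonomy
from cortimap.tessellation import case_map_from_geojson

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "results" / "study"
MAPS = ROOT / "results" / "maps"
OUT = ROOT / "results" / "consensus"

MOVEMENTS = ["tongue", "shoulder", "digit"]


def main() -> None:
    taxonomy = default_taxonomy()
    OUT.mkdir(parents=True, exist_ok=True)
    map_paths = sorted(glob.glob(str(MAPS / "map_*.geojson")))
    if not map_paths:
        raise SystemExit("no maps found; run 03_build_maps.py first")
    maps = [case_map_from_geojson(p, taxonomy) for p in map_paths]
    geoms = [
        read_region_geometry(STUDY / f"geometry_{m.case_id}.geojson") for m in maps
    ]
    fits = align_cases(geoms, mean_landmark_frame(geoms))
    for m, (t, residuals) in zip(maps, fits):
        rms = float(np.sqrt(np.mean([r**2 for r in residuals.values()])))
        print(f"{m.case_id}: scale {t.scale:.3f}, alignment RMS {rms:.2f} mm")
    aligned = [transform_case_map(m, t) for m, (t, _) in zip(maps, fits)]
    avg_geom = average_geometry([transform_geometry(g, t) for g, (t, _) in zip(geoms, fits)])

    for mv in MOVEMENTS:
        cmap = consensus(aligned, mv, resolution_mm=0.05, averaged_geometry=avg_geom)
        cmap.to_grid_csv(OUT / f"consensus_{mv}.grid.csv")
        cmap.contours_to_geojson(OUT / f"consensus_{mv}.geojson")
        consensus_svg(cmap, OUT / f"consensus_{mv}.svg")
        total = sum(movement_area(m, mv) for m in aligned)
        dw = cmap.depth_weighted_area_mm2()
        hist = {k: v for k, v in cmap.depth_histogram().items() if k > 0}
        core = cmap.area_at_least_mm2(cmap.n_cases)
        print(
            f"{mv}: depth histogram {hist}; depth-weighted {dw:.1f} mm^2 "
            f"(case sum {total:.1f}, rel err {abs(dw - total) / max(total, 1e-9):.2%}); "
            f"evoked in all {cmap.n_cases} cases over {core:.1f} mm^2"
        )
    print(f"\nconsensus outputs in {OUT}")


if __name__ == "__main__":
    main()
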