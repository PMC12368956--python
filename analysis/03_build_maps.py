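#!/usr/bin/env python
"""Tessellate each synthetic case into its Voronoi movement map.

Each electrode site gets the polygon of cortex nearer to it than to any
other site, clipped to the craniotomy; responsive cells carry the site's
evoked-movement labels, nonresponsive cells stay blank (drawn as X marks).
Writes map GeoJSON + SVG per case under results/maps/ and reports area
conservation.
"""

import glob
from pathlib import Path

from cortimap.geometry import assign_fields, read_region_geometry
from cortimap.protocol import StimProtocol
from cortimap.render import case_map_svg
from cortimap.sites import read_site_table
from cortimap.taxonomy import default_taxonomy
from cortimap.tessellation import build_case_map, case_map_to_geojson

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "maps"


def main() -> None:
    taxonomy, protocol = default_taxonomy(), StimProtocol()
    OUT.mkdir(parents=True, exist_ok=True)
    site_paths = sorted(glob.glob(str(STUDY / "sites_*.csv")))
    if not site_paths:
        raise SystemExit("no study found; run 01_simulate_study.py first")
    for spath in site_paths:
        sites = read_site_table(spath, taxonomy, protocol)
        case_id = sites[0].case_id
        geometry = read_region_geometry(STUDY / f"geometry_{case_id}.geojson")
        sites, report = assign_fields(sites, geometry)
        cm = build_case_map(sites, geometry, protocol)
        case_map_to_geojson(cm, OUT / f"map_{case_id}.geojson")
        case_map_svg(cm, OUT / f"map_{case_id}.svg")
        conservation = abs(
            sum(c.area_mm2 for c in cm.cells) - cm.region.area
        ) / cm.region.area
        print(
            f"{case_id}: {len(cm.cells)} cells, excitable {cm.excitable_area_mm2:.1f} mm^2, "
            f"area conservation rel err {conservation:.1e}, "
            f"{len(report.conflicts)} field conflicts"
        )
    print(f"\nmaps written to {OUT}")


if __name__ == "__main__":
    main()
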