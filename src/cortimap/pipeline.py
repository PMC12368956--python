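"""End-to-end pipeline: site tables + geometry in, report bundle out.

One call runs the whole analysis: read and field-assign the sites,
estimate thresholds and build the site/threshold summary, tessellate each
case into a movement map (GeoJSON + SVG), quantify per-movement areas and
percentages, align cases on shared landmarks and build consensus maps for
the requested movements.  Every run writes its resolved configuration
next to its outputs and is byte-deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .geometry import RegionGeometry, assign_fields, read_region_geometry
from .protocol import StimProtocol, protocol_from_dict
from .quantify import area_table, cross_case_summary, site_count_summary
from .registration import align_cases, average_geometry, consensus, mean_landmark_frame, transform_case_map, transform_geometry
from .render import case_map_svg, consensus_svg
from .sites import StimSite, read_site_table
from .taxonomy import MovementTaxonomy, default_taxonomy, taxonomy_from_dict
from .tessellation import build_case_map, case_map_to_geojson
from .thresholds import summary_table, threshold_summary

log = logging.getLogger("cortimap")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run."""

    protocol: StimProtocol = field(default_factory=StimProtocol)
    taxonomy: MovementTaxonomy = field(default_factory=default_taxonomy)
    movements: tuple[str, ...] = ("shoulder", "digit", "tongue")
    consensus_resolution_mm: float = 0.05
    reference: str = "mean"  # "mean" landmark frame, or "first"
    output_dir: str = "cortimap_out"
    log_level: str = "INFO"
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        if "protocol" in cfg:
            kwargs["protocol"] = protocol_from_dict(cfg["protocol"])
        if "taxonomy" in cfg:
            kwargs["taxonomy"] = taxonomy_from_dict(cfg["taxonomy"])
        for key in ("movements", "consensus_resolution_mm", "reference", "output_dir", "log_level", "seed"):
            if key in cfg:
                kwargs[key] = tuple(cfg[key]) if key == "movements" else cfg[key]
        return PipelineConfig(**kwargs)

    def resolved_dict(self) -> dict:
        return {
            "version": __version__,
            "protocol": dataclasses.asdict(self.protocol),
            "taxonomy": {
                "body_parts": list(self.taxonomy.body_parts),
                "body_regions": dict(self.taxonomy.body_regions),
                "directions": {k: list(v) for k, v in self.taxonomy.directions.items()},
            },
            "movements": list(self.movements),
            "consensus_resolution_mm": self.consensus_resolution_mm,
            "reference": self.reference,
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
            "seed": self.seed,
        }


@dataclass
class ReportBundle:
    """Paths of everything a pipeline run wrote."""

    output_dir: Path
    map_geojson: dict[str, Path]
    map_svg: dict[str, Path]
    table2_csv: Path
    table3_csv: Path
    sidecar_json: Path
    consensus_geojson: dict[str, Path]
    consensus_grid_csv: dict[str, Path]
    consensus_svg: dict[str, Path]
    config_yaml: Path
    run_log: Path


def run_pipeline(
    config: PipelineConfig,
    site_tables: Sequence[str | Path] | Mapping[str, Sequence[StimSite]],
    geometries: Sequence[str | Path] | Mapping[str, RegionGeometry],
) -> ReportBundle:
    """Run the full analysis and write the report bundle.

    ``site_tables`` and ``geometries`` are file paths or already-loaded
    per-case objects; cases are matched by case id, and a case without
    geometry aborts the run naming that case.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"cortimap {__version__} seed={config.seed}"]

    if not isinstance(site_tables, Mapping):
        loaded: dict[str, list[StimSite]] = {}
        for path in site_tables:
            sites = read_site_table(path, config.taxonomy, config.protocol)
            for s in sites:
                loaded.setdefault(s.case_id, []).append(s)
        site_tables = loaded
    if not isinstance(geometries, Mapping):
        geometries = {g.case_id: g for g in (read_region_geometry(p) for p in geometries)}
    if not site_tables:
        raise PipelineError("no cases in input")

    cases: dict[str, list[StimSite]] = {}
    geoms: dict[str, RegionGeometry] = {}
    for case_id, sites in sorted(site_tables.items()):
        if case_id not in geometries:
            raise PipelineError(f"case {case_id!r}: no region geometry supplied")
        geom = geometries[case_id]
        assigned, report = assign_fields(sites, geom)
        if report.conflicts:
            log_lines.append(f"{case_id}: {len(report.conflicts)} field-assignment conflict(s)")
        cases[case_id] = assigned
        geoms[case_id] = geom
        log.info("case %s: %d sites", case_id, len(assigned))

    # --- thresholds and site bookkeeping
    summaries = threshold_summary(cases, config.protocol)
    table2 = summary_table(summaries)
    table2_csv = outdir / "table_thresholds.csv"
    table2.round(1).to_csv(table2_csv)
    counts = site_count_summary(cases)

    # --- per-case maps
    maps = {}
    map_geojson: dict[str, Path] = {}
    map_svg: dict[str, Path] = {}
    for case_id, sites in cases.items():
        try:
            cm = build_case_map(sites, geoms[case_id], config.protocol)
        except Exception as exc:  # noqa: BLE001 - abort naming the case
            raise PipelineError(f"case {case_id!r}: map construction failed: {exc}") from exc
        maps[case_id] = cm
        map_geojson[case_id] = outdir / f"map_{case_id}.geojson"
        map_svg[case_id] = outdir / f"map_{case_id}.svg"
        case_map_to_geojson(cm, map_geojson[case_id])
        case_map_svg(cm, map_svg[case_id])

    # --- areas and percentages
    table = area_table(list(maps.values()), list(config.movements))
    summary = cross_case_summary(table)
    table3 = table.reported()
    table3.loc["all cases (mean %)"] = {f"{mv}_pct": summary[mv] for mv in table.areas.columns}
    table3_csv = outdir / "table_areas.csv"
    table3.to_csv(table3_csv)

    sidecar = {
        "site_counts": counts.to_dict(),
        "areas_mm2_full_precision": table.areas.to_dict(),
        "all_mm2": table.all_mm2.to_dict(),
        "percent_full_precision": table.percent.to_dict(),
        "cross_case_mean_pct": summary.to_dict(),
    }
    sidecar_json = outdir / "tables_full_precision.json"
    with open(sidecar_json, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)

    # --- alignment and consensus
    case_ids = list(maps)
    geom_list = [geoms[c] for c in case_ids]
    if len(case_ids) >= 3 and config.reference == "mean":
        ref = mean_landmark_frame(geom_list)
    else:
        ref = 0
    fits = align_cases(geom_list, ref)
    aligned_maps = [transform_case_map(maps[c], t) for c, (t, _) in zip(case_ids, fits)]
    aligned_geoms = [transform_geometry(geoms[c], t) for c, (t, _) in zip(case_ids, fits)]
    for c, (_, residuals) in zip(case_ids, fits):
        rms = (sum(r**2 for r in residuals.values()) / len(residuals)) ** 0.5
        log_lines.append(f"{c}: alignment RMS residual {rms:.3f} mm")
    avg_geom = average_geometry(aligned_geoms) if len(aligned_geoms) >= 2 else None

    consensus_geojson: dict[str, Path] = {}
    consensus_grid: dict[str, Path] = {}
    consensus_svgs: dict[str, Path] = {}
    for mv in config.movements:
        cmap = consensus(
            aligned_maps, mv, config.consensus_resolution_mm, averaged_geometry=avg_geom
        )
        consensus_grid[mv] = outdir / f"consensus_{mv}.grid.csv"
        consensus_geojson[mv] = outdir / f"consensus_{mv}.geojson"
        consensus_svgs[mv] = outdir / f"consensus_{mv}.svg"
        cmap.to_grid_csv(consensus_grid[mv])
        cmap.contours_to_geojson(consensus_geojson[mv])
        consensus_svg(cmap, consensus_svgs[mv])
        log_lines.append(
            f"consensus {mv}: depth-weighted area {cmap.depth_weighted_area_mm2():.2f} mm^2"
        )

    config_yaml = outdir / "config_resolved.yaml"
    with open(config_yaml, "w") as fh:
        yaml.safe_dump(config.resolved_dict(), fh, sort_keys=True)
    run_log = outdir / "run_log.txt"
    run_log.write_text("\n".join(log_lines) + "\n")

    return ReportBundle(
        output_dir=outdir,
        map_geojson=map_geojson,
        map_svg=map_svg,
        table2_csv=table2_csv,
        table3_csv=table3_csv,
        sidecar_json=sidecar_json,
        consensus_geojson=consensus_geojson,
        consensus_grid_csv=consensus_grid,
        consensus_svg=consensus_svgs,
        config_yaml=config_yaml,
        run_log=run_log,
    )
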