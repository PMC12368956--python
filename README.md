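# cortimap

Movement-map analysis for **long-train intracortical microstimulation
(LT-ICMS)** cortical mapping studies.

In an LT-ICMS experiment, a microelectrode delivers 500 ms trains of
biphasic pulses at a grid of sites across the flattened cortical surface,
and observers record which body-part movements each site evokes and at
what current. The analysis that turns those per-site records into a
quantitative account of motor organization is what this package
implements:

- **Threshold estimation.** A movement's threshold is the average of the
  lowest current at which the movement was observed and the next-lowest
  tested current at which it was not, with a staircase of 10 µA steps for
  thresholds below 150 µA and 50 µA steps at or above, up to a 300 µA
  ceiling. Per-field summaries (site counts and mean thresholds, pooled
  into PM/M1, 3a, 3b and 1/2/PPC) mirror the classic study-table layout.
- **Voronoi movement maps.** Each site is surrounded by its Voronoi cell
  — the cortex nearer to it than to any other site — clipped to the
  excitable region (craniotomy polygon, or the dilated convex hull of the
  sites). Cells carry the site's suprathreshold movement labels;
  nonresponsive sites keep blank cells.
- **Magnification tables.** A movement's representation is the summed
  area (mm²) of cells labelled with it; percentages are taken against the
  union of movement-evoking cells, so the magnification of, say, the
  tongue is `100 · A(tongue) / A(all)`. Multi-movement cells count fully
  toward each of their movements. Cross-case summaries are simple means
  of the per-case reported percentages.
- **Registration and consensus.** Cases are aligned by a least-squares
  similarity transform fitted to named landmarks (sulcal tips, field
  boundary corners); boundaries and sulci are averaged pointwise after
  arc-length resampling; and a consensus raster counts, per 0.05 mm
  pixel, in how many cases a movement was evoked at that location — the
  "2/4"-style shading of averaged movement maps.
- **Synthetic cases.** A seeded generator emulates galago-like cases
  (medial→lateral hindlimb→trunk→forelimb→face somatotopy, fractured
  multi-movement sites, field-specific log-normal thresholds, medial-3b
  dropout, per-case similarity transforms and landmark jitter), with a
  planted-truth manifest so every stage is testable without raw electrode
  data.

## Worked example

```python
from cortimap.simulate import SimParams, simulate_study
from cortimap.tessellation import build_case_map
from cortimap.quantify import area_table, cross_case_summary

study = simulate_study(SimParams(seed=42, n_sites=160), n_cases=4)
maps = [build_case_map(c.sites, c.geometry) for c in study.cases]
table = area_table(maps, ["shoulder", "digit", "tongue"])
print(table.reported())
print(cross_case_summary(table))
```

prints, for the default four-case study,

```
        all_mm2  shoulder_mm2  shoulder_pct  digit_mm2  digit_pct  tongue_mm2  tongue_pct
SIM-01    149.3          51.8          34.7        2.7        1.8        47.5        31.8
SIM-02    165.2          58.7          35.5        8.0        4.8        49.5        29.9
SIM-03    160.2          40.0          25.0        8.3        5.2        48.5        30.3
SIM-04    143.7          46.4          32.3        4.7        3.3        43.1        30.0
shoulder    31.9
digit        3.8
tongue      30.5
```

i.e. per case, the excitable denominator, and each movement's absolute
area and share of excitable cortex; then the cross-case mean
percentages. The default parameters yield the magnification ranking
characteristic of galago sensorimotor maps — a large shoulder and tongue
representation and a very small digit representation.

The numbered scripts under `analysis/` run the same pipeline as a
narrative: `01_simulate_study.py` (generate the study),
`02_threshold_summary.py` (threshold table), `03_build_maps.py`
(movement-map GeoJSON/SVG), `04_quantify_representations.py`
(magnification tables, including the published-measurement arithmetic),
`05_consensus_maps.py` (aligned overlap maps). Outputs land under
`results/`. A `cortimap` CLI exposes the same stages
(`simulate`, `thresholds`, `build-map`, `quantify`, `consensus`, `run`).

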