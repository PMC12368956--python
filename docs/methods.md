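# Methods

This note documents the models, estimators and numerical choices behind
`cortimap`, and what its synthetic data can and cannot stand in for.

## Coordinate frame and inputs

All geometry lives in millimetres on the flattened cortical surface:
x increases lateral, y increases rostral, and each case's origin is the
declared landmark `FS-caudal-tip` (the caudal tip of the frontal sulcus)
unless the input declares otherwise. Field boundaries, sulci, craniotomy
and landmarks arrive as GeoJSON in the same frame as the site table;
histological boundary drawing itself is out of scope — boundaries are
taken as given input geometry, with a `solid`/`dashed` confidence
attribute preserved from input to output.

Site tables are one CSV row per stimulation trial. Movement labels use
the grammar `body_part[:direction][:bilateral]` against a configurable
closed taxonomy (15 body parts across face/forelimb/hindlimb/trunk by
default). Unknown labels are hard errors: silently dropping a
misspelled movement would bias every downstream area.

## Threshold estimation

The estimator implements the midpoint rule: threshold = ½(L + N), where
L is the lowest current at which the movement was observed and N the
highest tested current below L at which it was not. The staircase tests
in `step_low` = 10 µA steps below the `breakpoint` = 150 µA and
`step_high` = 50 µA steps at or above, with a `max_current` = 300 µA
ceiling; these live in `StimProtocol` and are configurable.

Decisions the rule itself leaves open:

- **Applicable step for a bracket.** The regime (10 vs 50 µA) is chosen
  by the midpoint's position relative to the breakpoint. A bracket gap
  *larger* than the applicable step leaves the threshold `unresolved` —
  never interpolated — while a finer gap than required is accepted
  (better data is not worse data).
- **Floor.** Movement at the lowest tested current with nothing below
  reports that current with flag `floor` (no sub-grid midpoint is
  invented). Floor values enter group means at face value.
- **Per-site threshold** is the minimum over the site's per-movement
  thresholds.
- Contradictory trials (observed and not observed at one current) are
  errors; off-grid currents warn but are processed.

Group summaries count movement sites per field group (PM/M1, 3a, 3b,
1/2/PPC — areas 1/2 and PPC are pooled because their boundary is
indistinct in flattened preparations) and average thresholds unweighted
over the threshold-bearing sites of the group. Nonresponsive and
unresolved sites count toward totals but never toward means.

## Movement maps

The excitable region is the craniotomy polygon when supplied; otherwise
the convex hull of the sites dilated by half the median
nearest-neighbour distance. Dilation gives boundary sites cells of
sensible width and guarantees 2D extent even for degenerate (collinear)
site layouts.

Voronoi cells are computed with scipy's Voronoi diagram plus a ring of
16 guard generators placed far outside the region (10× its diameter), so
every real cell is bounded before clipping to the region with exact
shapely intersections. Sites coincident within 10⁻⁶ mm merge (with a
warning) and share a cell. Conservation — cell areas summing to the
region area within 10⁻⁶ relative — is asserted in the tests and holds to
machine precision.

Cell labels follow suprathreshold-map semantics: a movement labels its
cell if it was observed at any current up to the protocol ceiling.
Nonresponsive sites are tessellation generators (they bound their
neighbours) but contribute no area to any movement and are excluded from
the excitable denominator.

## Magnification arithmetic

`movement_area` sums the areas of cells whose label set matches a
selector; body-part selectors deliberately ignore direction and
laterality. A multi-movement cell contributes its full area to each of
its movements, so percentages over movements can exceed 100 in sum —
that is the intended overlap semantics, and the denominator ("All") is
the union of movement-evoking cells, which cells' disjoint interiors
reduce to a plain sum.

Reporting rounds half away from zero to one decimal; full precision is
retained internally and exported in a machine-readable sidecar. The
cross-case mean is the simple mean of the per-case *reported*
percentages, again rounded — this mirrors how summary tables are built
from their own printed cells, and it is the convention under which the
published galago measurements bundled in `cortimap.datasets` reproduce
their printed all-cases means exactly.

## Registration and consensus

Alignment fits a similarity transform (rotation, uniform scale,
translation) to landmark correspondences matched by name, via the
closed-form orthogonal-Procrustes solution. Similarity rather than full
affine: landmarks are shape features, and uniform scale absorbs
brain-size differences without shearing the somatotopy. The reference
frame is the landmark-wise mean over cases when three or more cases
share landmarks, else the first case. Per-landmark residuals are always
returned; an exact similarity is recovered to ≤10⁻⁹ residual.

Boundary/sulcus averaging resamples each named curve to 100
arc-length-uniform points (rings are cyclically aligned to the first
case, open polylines orientation-aligned) and takes the pointwise mean.
Curves present in fewer than two cases pass through flagged. Resampling
cuts corners at the scale of one sample spacing; tests therefore compare
averaged curves geometrically (Hausdorff distance), not vertex-by-vertex.

Consensus maps rasterize at 0.05 mm (about a tenth of the default
inter-site spacing): each pixel counts the cases whose matching labelled
cells cover its centre. Rasterization was chosen over exact polygon
boolean stacking for simplicity and tolerance-bounded error; the
depth-weighted area identity (Σ depth · pixel area = Σ per-case areas)
holds within 1% at the default resolution, and exactly scales with
identical inputs (n identical cases give depth n on labelled cells,
pixel for pixel). Iso-depth contours come from marching squares on the
padded depth grid.

## Synthetic study conditions

The generator's defaults describe the study the package emulates, chosen
once from the study's reported envelope:

| parameter | default | rationale |
| --- | --- | --- |
| map extent | 10 × 18 mm | within the reported ~9–12 × 15–22 mm envelope |
| grid pitch | 0.7 mm | inferred from ~160 sites per case over that extent; configurable |
| sites per case | 160 | reported per-case totals were 113–176 |
| field strips (rostral→caudal) | PM 2.5, M1 3.0, 3a 2.0, 3b 6.5, 1/2 1.5, PPC 2.5 mm | reproduces the approximate per-field movement-site shares |
| somatotopy bands (medial→lateral) | hindlimb .23, trunk .10, forelimb .32, face .35 | hindlimb-medial to face-lateral gradient |
| threshold medians (µA) | 3a 20 < PM/M1 32 < 3b 55 < 1/2/PPC 80, σ_log 0.5 | the observed field ordering of mean thresholds |
| nonresponse per field | PM .10, M1 .08, 3a .08, 3b .12, 1/2 .30, PPC .35 | ≈85% of sites responsive overall |
| p(multi-movement) | 0.35 | most sites evoke synergies of more than one part |
| p(bilateral) | 0.08 | bilateral movements are a small minority |
| medial-3b dropout | ×1.75 on nonresponse odds and threshold median | the anesthesia-sensitivity of medial 3b |
| landmark jitter σ | 0.3 mm | inter-case morphological variability |

Composition rows are per-band categoricals over body parts, conditional
on a responsive site (row sums ≤ 1; any remainder is additional
nonresponse). Fracture is modelled as independent per-site draws — the
minimal model of a "fractured but broadly topographic" map. The default
composition puts the study qualitatively in the galago regime (tongue
and shoulder each near a third of excitable cortex, digits a few
percent) without claiming exact reproduction of any measured map.
`SimParams.flat` gives a spatially uniform variant used for
parameter-recovery experiments, where the planted per-part probabilities
are the map-wide marginals by construction.

Thresholds are drawn log-normal (positive, right-skewed) and snapped to
the staircase's midpoint grid; the emitted trial staircase brackets the
snapped threshold, so the estimator recovers every planted threshold
exactly — an internal-consistency invariant the tests assert site by
site. Draws above the ceiling render that movement unobserved.

What the generator does **not** emulate: spatially correlated movement
territories (real maps have contiguous patches beyond what independent
draws produce), curved or uncertain field boundaries, oblique
penetration depths, anesthesia drift over the session, and any
within-train kinematics. Passing tests on synthetic data therefore
demonstrate the correctness of the estimators and geometry on data with
the study's statistical envelope, not fidelity of any particular map's
spatial detail.

## Problem sizes used in checks

The bundled checks run at deliberately compact sizes: 1,000 random
staircases for estimator/oracle equivalence, 30-site instances against a
1000×1000 nearest-site raster, 25 random landmark sets for registration
recovery, a 100-site case for consensus identities, and 20 seeds × 500
sites for composition recovery (mean recovered within ±5 percentage
points of the planted 30/35/5% tongue/shoulder/digit split). These sizes
make the whole suite run in well under a minute while leaving all
tolerances comfortably non-binding.

## Known limitations

- Field assignment on a drawn boundary is genuinely ambiguous; the
  deterministic tie-break (fixed field order, flagged) is a convention,
  not a claim about the true assignment.
- The published summary table the datasets module carries is internally
  inconsistent in one respect (its per-field site counts total the
  movement-site count while the caption describes threshold sites); the
  package reproduces the printed totals and structure, not that
  arithmetic tension.
- Rasterized consensus error grows linearly with resolution; at coarse
  resolutions (> 0.2 mm) the 1% depth-weighted identity is not
  guaranteed.
- The similarity model cannot absorb anisotropic flattening distortion;
  an affine fit is a straightforward extension but is intentionally not
  the default.
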