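# Methods and numerical conventions

This document defines what each operator measures, how the synthetic ground
truth is produced, and the discretization conventions that determine the
accuracy you can expect. All defaults and problem sizes named here are the
package's own choices.

## 1. Zoned cartilage and subchondral-plate morphometry

A section is four ordered boundary polylines (µm coordinates): `surface`,
`tidemark`, `cement_line`, `trab_junction`.

**ROI and zones.** The chord joining the first and last *surface* vertex
defines a local frame (u along the chord, v perpendicular). The chord
extent is restricted to the common u-support of all four traces and split
into four equal-width zones Z1–Z4. Working in the chord frame makes every
measurement exactly invariant under rigid motions of the traced section
(verified to 1e-9 relative in the test-suite).

**Thickness.** For each layer pair, `n_rays` (default 100) rays per zone
are cast perpendicular to the chord at midpoint-rule u positions; a ray's
length is the difference of the linearly interpolated v-coordinates of the
two polylines. Rays outside either trace's u-support are excluded and
counted; a zone with more than 50 % excluded rays is flagged unmeasurable
(NaN). All three layers share the same ray positions, and
`Cg.Th = nCg.Th + cCg.Th` is computed as the literal sum, so layer
additivity holds to machine precision by construction.

**Fibrillation index.** The surface polyline is clipped to each zone in the
chord frame (with interpolated endpoints); FI is its arclength divided by
the zone's chord width. FI = 1 exactly for a straight surface and grows
with undulation and fissuring. The µm excess `L − W` is kept as a
secondary output.

**Section phantoms.** The generator builds all four boundaries from
closed-form functions: a sinusoid of chosen amplitude/wavelength on the
surface, flat deeper layers, and seeded band-limited roughness (a sum of 32
cosine modes with wavelengths in 50–200 µm) added to every boundary.
Because the roughness is part of the generating function — with an analytic
derivative — the per-zone ground truth (trapezoid quadrature of layer
differences, midpoint quadrature of the surface arclength, both at 16×
finer stepping) includes it exactly, and is never computed from the emitted
polylines. White per-vertex noise is deliberately *not* used: it is
unphysical for traced smooth boundaries and would make the polyline
arclength diverge with the sampling step. If a roughness draw makes
adjacent boundaries cross, the phantom is regenerated with the roughness SD
halved (with a warning).

Measured-vs-truth behaviour at the defaults (1 µm sampling, 100 rays/zone):
layer thickness within ~2e-5 relative, FI within ~1e-5 absolute.

## 2. 2D diagonal-intercept trabecular stereology

ROIs follow the histological convention: 2.5 × 1.5 mm (femur) or
1.5 × 1.5 mm (tibia), cropped by `place_roi` from larger rasters.

* **Tb.A (%)** — bone pixel fraction of the ROI.
* The ROI's corner-to-corner diagonal is sampled at half-pixel steps; runs
  of equal phase become intercepts, with run boundaries placed midway
  between the samples flanking each phase change, so run lengths sum to the
  diagonal length `L = √(w² + h²)` *exactly*.
* **Tb.N** — number of bone runs; **Tb.Th (mm)** — their mean length;
  **Tb.Sp (mm)** — `(L / Tb.N) − Tb.Th`. The identity
  `Tb.N·(Tb.Th + Tb.Sp) = L` therefore holds to machine precision, and an
  all-bone ROI yields Tb.N = 1, Tb.Sp = 0.
* Runs touching the diagonal endpoints can be excluded
  (`include_clipped=False`); `which="both"` averages the two diagonals.

**Oriented-secant bias.** A straight line crosses a plate of thickness t at
`t/|cos φ|` (φ between the line and the plate normal), so diagonal-intercept
Tb.Th is biased *high* against model-independent 3D thickness — a property
of the measurement that the tests exercise explicitly (2D ≥ 3D on oblique
plates). Caveat: for plates digitized at steep in-plane angles (≳15° between
the plate trace and the raster axes at these resolutions), staircase edges
can fragment diagonal runs and break that inequality; the guaranteed-bias
regime used in the tests is shallow obliquity (plates tilted 0–10° from the
axis, crossed by the 45° diagonal).

## 3. 3D maximal-sphere microarchitecture

Volumes are binary voxel grids (bone = True, isotropic voxels, (z, y, x)
order). Analysis runs in cylindrical VOIs (axis along z; 2.5 mm diameter
with 2.5 mm depth for femoral and 1.5 mm for tibial compartments) placed at
anterior/central/posterior, medial/lateral positions. VOIs that do not fit
the volume are rejected, reporting the contained fraction.

* **BV/TV (%)** — bone voxels over in-VOI voxels (voxel-centre inclusion
  test).
* **Tb.Th / Tb.Sp (mm)** — volume-weighted mean maximal-inscribed-sphere
  ("local") thickness of the bone / marrow phase: for every point, the
  diameter of the largest sphere containing it that fits inside the phase.
* **Tb.N (1/mm)** — plate-model `(BV/TV)/Tb.Th` by default;
  `1/(Tb.Th + Tb.Sp)` available.

**Algorithm.** Local thickness is computed as: Euclidean distance transform
of the phase (scipy) → pruning of sphere centres whose sphere lies inside a
26-neighbour's sphere (`R ≥ r + d`) → "sphere painting" of each remaining
centre's diameter into every covered phase voxel, keeping the maximum
(numba kernels). A 240³ plate phantom takes well under a minute for both
phases on one CPU.

**Discretization conventions and their consequences.**

* The painted diameter is `2·D_edt` voxels, where `D_edt` is the distance
  to the nearest background *voxel centre*. For an axis-aligned slab this
  convention is exact when the slab spans an even number of voxels and one
  voxel high when it spans an odd number (±1-voxel parity bias). Recovery
  is therefore exact when structural dimensions are an even voxel count —
  e.g. plates of 0.16/0.32 mm at 10 µm voxels, or 0.15/0.30 mm at 7.5 µm —
  and within one voxel otherwise. The same logic puts a rod's measured
  diameter within one voxel of 2r, exact when the rod axis falls on a
  voxel centre.
* Out-of-VOI voxels belong to neither phase: they bound both distance
  transforms, so inscribed spheres never extend across the VOI wall. The
  crop is padded with one out-of-VOI layer so this holds even when in-VOI
  voxels touch the crop's bounding box. (Whole-volume analysis without a
  VOI treats out-of-array space as open, so a slab spanning the array keeps
  its nominal thickness.)
* Tilted plates acquire a small positive bias from staircase digitization
  (≈5 % at 30° tilt and 7.5 µm voxels) — orientation robustness, not
  exactness, is the property tested off-axis.

`central_plane_section` extracts the mid-axis x–z plane of a central VOI in
the site's 2D ROI convention, enabling coupled 2D/3D measurements of the
same synthetic specimen (Delesse: areal fraction tracks volume fraction).

## 4. Trabecular phantoms

All renderers sample geometry at pixel/voxel centres; ground truth comes
from the generating parameters, never from the raster.

* **plates** — parallel plates, thickness t, spacing s, normal tilted
  `orientation_deg` from the stacking axis (towards x in 3D). The pattern
  is phase-shifted by half a gap so no plate is cut by the domain face
  (a face-cut plate would have a one-sided distance transform). Truth:
  BV/TV = t/(t+s), Tb.Th = t, Tb.Sp = s, Tb.N = 1/(t+s); the BV/TV truth
  is exact when the domain spans an integer number of periods.
* **rods** — z-aligned cylinders of radius r on a square lattice of pitch
  p. Truth: BV/TV = πr²/p², Tb.Th = 2r, Tb.N = 1/p.
* **random_field** — Gaussian white noise smoothed at the requested
  correlation length (periodic boundaries) and thresholded at the quantile
  that yields the target bone fraction (exact by construction up to one
  voxel's worth of mass). For coupled 2D/3D studies, a short correlation
  length (0.05 mm at 20 µm voxels) keeps enough independent structure in a
  single plane for the plane fraction to track the volume fraction tightly;
  long correlation lengths make single-plane estimates noisy.
* **solid** — all-bone, for boundary cases.

Validation rejects unresolvable requests (pixel ≥ t, pixel ≥ 2r) and warns
when the pixel is coarser than t/5.

## 5. Synthetic cohorts

`gen_cohort` draws a long-format measurement table from a per-cell
(group, joint, compartment, zone, parameter) → (mean, SD) map; the packaged
reference table (576 cells) encodes a three-group rabbit knee-OA design
(SHAM / untreated-OA / treated-OA, 8 animals each — SHAM reducible to 7 —
operated OA vs contralateral healthy HT joint, four femorotibial
compartments, four zones, plus site-level 2D trabecular parameters). Each
cell is drawn independently from a zero-truncated normal (every measured
quantity is positive); SD = 0 yields the mean. Consequently simulated
`Cg.Th` is *not* forced to equal simulated `nCg.Th + cCg.Th` — additivity
is a property of the measurement operators, not of the table-level
simulation, and the tables carry no covariance information (between-zone
correlation is configurable and defaults to 0).

## 6. Statistics

* **Gating** — a comparison runs parametrically iff every group passes
  Shapiro–Wilk at α *and* Levene's test (mean-centred, i.e. classical
  Levene rather than Brown–Forsythe) passes at α. Groups with n < 3 or
  zero variance force the nonparametric route with a warning.
* **Two groups** — Student's t, or two-sided Mann–Whitney U with the exact
  null distribution when both n ≤ 10 without ties; paired variants
  (paired t / Wilcoxon) for within-animal OA-vs-HT designs.
* **Three groups** — one-way ANOVA with pairwise t contrasts under
  Holm–Šidák step-down, or Kruskal–Wallis with tie-corrected Dunn z
  contrasts under the same step-down.
* **2D↔3D agreement** — Pearson r of specimen-matched parameters (Tb.A is
  paired with BV/TV), with per-modality means ± SDs; fewer than three
  complete pairs or zero variance yields NaN with a warning.

Calibration is verified empirically: the gated two-group pipeline's type-I
error at α = 0.05, n = 8 sits within [0.035, 0.065] over 2000 null
draws, Holm–Šidák reproduces its closed form
(`{0.01, 0.04} → {0.0199, 0.04}`), and the exact Mann–Whitney p for fully
separated n = 8, 8 samples equals the enumeration value 2/C(16,8).

**Limitation:** significance is per (compartment, zone, parameter) cell; no
correction is applied across the many cells of a cohort sweep.

## 7. Pipeline and determinism

`run_pipeline(RunConfig(...))` executes four stages — section sweep,
trabecular phantoms, cohort + statistics, coupled 2D/3D — writing tidy CSVs
plus the echoed config and a structured `run.json` (package version, seed,
per-stage warnings). All randomness flows from the single config seed
through explicit sub-seeds; floats are written with a fixed format, so a
saved config re-executes to byte-identical CSV outputs. A stage failure
aborts with the stage name; outputs of earlier stages are retained.

Default problem sizes keep the full run in the minutes range on one CPU:
7.5 µm voxels for the 3D plate stage (even voxel counts per plate and gap,
see §3), 1.8 mm plate domains (integer periods), 20 µm voxels with a
0.05 mm correlation length for the coupled stage.

## 8. Known limitations

* Local thickness carries the ±1-voxel parity bias of the voxel-centre
  distance-transform convention (§3); choose voxel sizes that divide the
  structural dimensions evenly when exactness matters.
* Diagonal-intercept 2D metrics are oriented-secant measures: biased high
  for oblique structures by construction, and subject to run fragmentation
  on steeply digitized edges (§2).
* The cohort simulator draws cells independently; it reproduces printed
  means/SDs but no cross-parameter covariance (§5).
* FI is computed on the traced polyline; tracing resolution bounds the
  recoverable surface detail (vertical-tangent features such as notch rims
  need sub-µm sampling for 1e-3 accuracy).
* Statistics are per-cell; family-wise error across cells is not
  controlled (§6).
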