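# Methods

`atriarecon` measures left-atrial (LA) volume and function from a handful of
arbitrarily oriented 2D cine slices — the situation produced by a single
breath-hold multi-slice acquisition of two long-axis and three short-axis
views. This note records the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Slice geometry

Each slice is described by its DICOM-style header: the patient-space
position of the centre of pixel (0, 0), the unit direction cosines of the
column and row axes, and the pixel spacing (default 1.5 × 1.5 mm²). All
patient coordinates are LPS. Pixel indices are 0-based, refer to pixel
centres and may be fractional. Direction cosines off unit length or
orthogonality by less than 10⁻³ (rounded headers) are silently
re-orthonormalised; larger deviations are rejected. The in-plane/out-of-
plane decomposition `(u, v, d)` of a patient point underpins everything
downstream; the round trip is exact to < 10⁻⁹ mm.

## Contours

Contours are closed fractional-pixel (row, col) polygons. From binary
masks they are extracted by marching squares at iso-level 0.5 on the
largest connected component (configurable to reject multi-component
masks). Smoothing is periodic penalised least squares: both coordinate
channels are filtered with a circulant second-difference penalty in the
FFT basis, the penalty weight chosen by generalised cross-validation
("auto"), with up to five bisquare reweighting passes to resist outlier
vertices. Periodicity removes endpoint artefacts; zero smoothing is the
identity. The GCV choice is recorded in run metadata. Inside/outside tests
use the even-odd rule with boundary points counted inside, so the
indicator below is deterministic.

All metric geometry happens in mm after applying pixel spacing; areas are
mm², volumes ml.

## Non-model-based reconstruction

Each contoured slice defines an indicator: +1 inside the contour, −1
outside, the contour its zero set. The chamber surface is the zero set of
an interpolation of this indicator into 3D; the chamber volume is the
enclosed volume of the triangle mesh extracted from that zero set. No
ellipsoidal or other shape model enters, which is why the measurement is
insensitive to slice orientation.

**Indicator carrier.** The default carrier is the in-plane signed distance
to the contour, clamped at ±τ (default τ = 15 mm): graded values near the
wall, saturated far away. τ must be well above the slice spacing scale —
with a small clamp the carrier degenerates to the binary ±1 field and
inherits its geometric bias (below). The literal binary carrier is
retained as `mode="binary"`.

**Interpolation.** Two routes are implemented.

* `rbf` (default): a single smooth thin-plate-spline interpolant
  `F: R³ → R` (degree-1 polynomial tail) is fitted through, per slice,
  48 exact zero constraints on the contour and clamped signed-distance
  samples on a 5 mm in-plane lattice (lattice samples within 1.5 mm of
  the contour are dropped; the zero constraints already pin the surface
  there). The interpolant reproduces every slice's field at its
  constraints and relaxes smoothly between slices, so the surface closes
  off between and beyond the slices rather than being extruded along
  them. On the noise-free five-phantom × three-strategy suite at a 1 mm
  grid this reconstructs volumes with max |error| 1.3 % and mean |error|
  0.5 %.
* `idw`: the transparent pointwise scheme
  `F(p) = Σⱼ wⱼ fⱼ(πⱼ(p)) / Σⱼ wⱼ`, `wⱼ = 1/(dⱼ² + ε²)`, with `πⱼ`
  orthogonal projection onto slice j and `dⱼ` the out-of-plane distance.
  It reproduces each plane's field exactly on the plane and is the route
  used for the binary carrier. Its known limitation is a convexity bias:
  along directions between widely spaced planes, the orthogonal
  projection of a point just outside the chamber still lands inside every
  cross-section, so all planes vote "inside" and the surface bulges
  (≈ +14 % on the 55 ml sphere phantom with the five-slice protocol).
  It is kept as the reference formulation and for parallel-stack data,
  where the bias is negligible; accuracy claims in this package refer to
  the default route.

**Surface extraction.** The interpolant is sampled on a regular isotropic
grid (default 1 mm) over the contour bounding box padded by 10 % of its
diagonal. The rbf route evaluates a 4 mm coarse pass first and re-evaluates
exactly only in a band around the approximate zero crossing (the far field
only needs the correct sign). The outermost grid layer is forced outside
so the surface is always closed — the mitral "opening" is capped by the
long-axis contours themselves. Marching cubes at level 0 (grid nodes at
exactly 0 count as outside, for deterministic meshes) yields the surface;
the largest watertight component is kept, oriented outward, and its
volume computed by the divergence theorem (`Σ a·(b×c)/6`). Volumes
converge monotonically under grid refinement 4 → 2 → 1 mm and are rigid-
motion invariant to < 0.5 %.

A cine set is reconstructed frame by frame; frames missing contours are
flagged in the curve metadata, never interpolated.

## Model-based comparator: bi-plane area-length

`V = 0.848 · A₁ · A₂ / ((L₁ + L₂)/2)`, with the areas of the two
orthogonal long-axis views and each length the maximum distance from the
mitral valve mid-position to the opposite wall. The constant is kept at
the conventional printed 0.848, not 8/(3π) ≈ 0.84883; for an ellipsoid
sliced through its principal axes the ratio to the true volume is exactly
0.848/(8/(3π)) = 0.99906. Contours are resampled to ≥ 256 vertices before
the length search (discretisation error < 0.1 mm); lengths are measured on
smoothed contours; the mitral landmark is an explicit input and must lie
within 2 mm of the contour.

## LA function indices

From a one-cycle time-volume curve: `v_max`, `v_min` (after `v_max` in
cyclic order) and the pre-contraction volume `v_pre_a` at diastasis.
Total emptying (total conduit volume) = `v_max − v_min`; passive =
`v_max − v_pre_a`; active = `v_pre_a − v_min`; total EF = 100·total/`v_max`;
passive/active fractions of total; phase rates = phase volume / phase
duration in ml/ms (mean rates, not peak dV/dt — peak rates are a
documented alternative, not used by default); "passive LA flow" =
LV stroke volume − total emptying. Absent atrial contraction (e.g. a
fibrillating or paced atrium) is encoded as `v_pre_a = None`: active
emptying 0, passive fraction 100 %, active rate undefined.

When not supplied, `v_pre_a` is located as the flattest point (minimal
|dV/dt|, periodic central differences) on the emptying limb, restricted to
volumes at least 5 % of the excursion away from both extremes so plateaus
around `v_max`/`v_min` are not mistaken for diastasis; a limb with no
genuine shoulder yields a low-confidence flag. Indices are invariant to
rotation of the curve's starting frame.

## Synthetic phantoms

Five implicit solids spanning typical LA morphology, all deformed
ellipsoids with closed-form volume (4/3)π·a·b·c, calibrated exactly to
their reference volumes: large oval 54 ml and small oval 51 ml (axis
ratios 1.5 : 1.2 : 1.0), oblique oval 61 ml (ratios 1.6 : 1.1 : 1.0,
long-axis shear 0.45 ≈ 24° tilt relative to the mitral plane — volume
preserved, unit shear determinant), sphere 55 ml (radius 23.59 mm), and
curved 70 ml (ratios 1.8 : 1.0 : 0.95 bent along a 70 mm arc — volume
preserved exactly because each cross-section's centroid rides the neutral
arc, the slab-wise Pappus argument; a 0.5 mm voxelisation oracle confirms
this in the tests). The phantoms are closed solids; the mitral plane is a
labelled landmark at the valve end of the long axis, not an open boundary.

Slicing strategies mirror the three planning rows per shape: row 1
long-axis planes aligned with the true LA axis, short-axis perpendicular;
row 2 aligned but short-axis tilted 20°; row 3 long-axis rotated 25° off
the true axis (anchored at the mitral mid-point, as a mis-planned
acquisition still crosses the mitral centre), short-axis perpendicular to
the acquired axis. Each strategy produces 2 long-axis + 3 short-axis
slices at 1.5 mm pixel spacing; short-axis planes sit at fractions 0.2,
0.5, 0.8 of the chamber's span along the stack normal (proximal, mid,
distal — placed over the visible chamber, as an operator would, which
keeps the distal cap sampled even for mis-aligned acquisitions). The
misalignment and tilt angles are parameters, not constants.

Contours are cut from the implicit functions by in-plane marching squares
(default 0.75 mm sampling; section areas converge as O(step²)). Optional
i.i.d. Gaussian vertex noise is driven by a single seeded generator
recorded in the dataset metadata; identical seeds give bit-identical
datasets.

Cine phantoms scale the base shape self-similarly so the enclosed volume
tracks a prescribed curve exactly: cosine segments from `v_min` up to
`v_max` (reservoir), down to `v_pre_a` (conduit, zero slope at the
diastasis shoulder), and down to `v_min` (booster), default 34 frames at
30 ms. Pure scaling is sufficient for validating a volume pipeline; it has
no regional wall motion, no through-plane motion artefacts and no
segmentation error, so passing it bounds only the reconstruction error,
not image-related error sources in real data.

## Agreement statistics

Bland-Altman limits of agreement are mean ± 2·SD of the paired
differences (the convention of the validation plots this package mirrors,
not 1.96·SD); percent differences use the pairwise mean as denominator.
The 2 × 2 repeated-measures ANOVA (alignment × method, subjects = phantom
shapes, aligned = mean of rows 1–2, not-aligned = row 3) is computed by
exact within-subject contrasts — for a 2 × 2 design each effect's F equals
the squared paired-t statistic of the corresponding contrast, the
interaction using the double difference. A general repeated-measures ANOVA
implementation serves as an independent oracle in the tests.

Endocardial border sharpness: 8 rays at 45° from a user point inside the
contour; each intensity profile is sampled at 0.25 px over ±10 px around
the wall crossing; per-ray sharpness is the reciprocal of the 20–80 %
edge-transition width in pixels, capped at 1; the EBS is the mean over
rays, with rays that exit the image dropped and counted. For a linear ramp
of width w the closed form is 1/(0.6·w).

## What the validation shows

On noise-free analytic contours at a 1 mm grid, across all five shapes and
three strategies: per-case volume error < 2 %, per-shape spread across
strategies < 2 % of reference, while the bi-plane area-length volume drops
by 22–46 % under 25° misalignment on the elongated shapes, giving a
strongly significant alignment × method interaction — the same qualitative
behaviour as the published phantom experiment, whose printed cells
reproduce the reported agreement statistics exactly and show the same
interaction. The residual −0.5 % mean bias of the reconstruction is grid-
and smoothing-related, not orientation-related. None of this bounds
segmentation error, through-plane motion, or partial-volume effects in
real images.

## Problem sizes and runtime

Default validation runs use the 1 mm reconstruction grid (the full
15-case suite takes ~40 s on one core); cine demonstrations use 20 frames
at a 2 mm grid (~15 s), where per-frame volume error stays below 1.7 %.

## Known limitations

* Two slices are the formal minimum; accuracy claims hold for the
  five-slice protocol the phantoms emulate.
* The binary-carrier projection route is faithful to the simplest
  formulation but volumetrically biased for convex chambers; it is not
  used for quantitative work here.
* The thin-plate-spline system is dense (≈ 1.5 k constraints per frame);
  very large FOVs or many more slices would need centre subsampling.
* `v_pre_a` detection assumes a single-peaked curve with an emptying limb;
  severe arrhythmia (multiple peaks) requires the explicit override.
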