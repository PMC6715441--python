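# Methods

This note documents the models, parameter choices and numerical decisions
behind `raftsense`, and what its synthetic validation does and does not
demonstrate.

## Sensing model

Adherent, unlabeled cells on a transparent substrate are nearly invisible
in a single focused bright-field image, but their appearance — punctate
intracellular spots and a halo at the cell perimeter — changes strongly
with focus, while the substrate's appearance does not. The pipeline turns
this physical asymmetry into contrast in four steps.

**1. Illumination correction.** Each plane is divided by a smooth flat
field (mean filter over 256 px blocks, then Gaussian smoothing with a
100 px standard deviation) and rescaled to the mean intensity of the first
image of the series. The flat field is computed on a decimated grid and
resampled back: both filter scales are hundreds of pixels, so the
difference to the dense computation is orders of magnitude below the 1–2%
contracts the operation carries. The field is estimated per plane;
whether per-plane or per-scan estimation is the better model of a real
instrument is left configurable.

**2. Registration.** The pre-seeding background stack is registered onto
the signal stack with a rigid transform: translation by single-step DFT
cross-correlation with 1/20 px resolution (`upsample=20`), rotation by
iterating the translation over −0.5°…0.5°. The angular grid (default step
0.05°, ≤¼ of the smallest rotation that moves an array corner by one pixel
at default geometry) is searched coarse-to-fine on downsampled planes, with
only the final translation solved at full resolution; rotations this small
move even image corners by a few pixels, so the correlation error metric
resolves the angle equally well at reduced resolution. One transform per
stack is estimated on the middle focal plane, since planes of a z-stack
are acquired without stage motion. Resampling is bilinear about the image
center; pixels resampled from outside the frame are flagged invalid and
excluded from all downstream histograms rather than zero-filled, so Otsu
statistics are never polluted by fabricated borders.

**3. B-SDP.** Registered background planes are subtracted pixelwise from
signal planes at matched focal offsets, and the per-pixel standard
deviation along z is projected. Population standard deviation is the
default; with three planes the sample/population choice is a constant
factor absorbed by the subsequent Otsu threshold, so masks are unaffected
either way — the option exists for completeness, not because it matters.

**4. Enhancement and segmentation.** In order:

- *White top-hat*, rectangular structuring element 2 × 33 µm (one sixth of
  a raft side) at 0° and 90°, combined by **pixelwise minimum**: a long
  straight edge survives the top-hat parallel to it, so only the minimum
  suppresses microraft wall edges in both orientations. White rather than
  black top-hat because cells are bright in the B-SDP.
- *Local entropy* over a 14 µm disk, after quantizing the image to 256
  gray levels by min–max scaling over valid pixels (local entropy requires
  a discrete alphabet; the fixed alphabet also makes the stage invariant
  to affine intensity rescaling of the inputs).
- *Opening by reconstruction* with a 40 µm disk: removes debris-scale
  responses while preserving the shape of surviving colonies exactly.
- The entropy and reconstruction stages operate at a working resolution of
  3.25 µm/px (image downscaled, result resampled back). Their structuring
  scales (14/40 µm) are an order of magnitude above pixel scale, so the
  masks are essentially unchanged, and the chain stays fast on full-array
  scans.
- *Otsu threshold* over valid pixels, computed per image field.
- *Hole filling*: all interior holes by default. Dense epithelial colonies
  make interior holes artifactual; a `fill_min_radius` parameter restricts
  filling to holes above a radius for sparser cell types.
- *8 µm contraction*, implemented as erosion with an 8 µm-radius disk: the
  stated purpose of thinning is to compensate the dilated appearance of
  cells in SDPs, which is a uniform boundary contraction, not topological
  thinning.
- *Majority filter*, 3 × 3 px, one pass.
- *Size exclusion*: components smaller than (25 µm)² are removed as
  debris; 25 µm is the smallest colony radius the cytometry quantifies.

All sizes are specified in micrometers and converted to odd pixel extents
at run time, which makes the chain invariant (IoU ≥ 0.8 in tests) to 2×
pixel-size changes.

**Cell-free-field guard.** On a field with no cells the B-SDP contains
only noise; Otsu would still split that noise and can leave
debris-threshold-sized false components. Focus-varying content gives the
B-SDP a heavy bright tail, so the pipeline computes the ratio of its
99.9th percentile to its median: ≈3 for pure noise, >30 with colonies
present in every condition measured. Below `min_focus_contrast = 8` the
field is declared cell-free and the mask is empty. The statistic is a
ratio, so affine intensity invariance is preserved.

## Grid indexing and tracking

Quads are segmented from a corrected bright-field plane by Otsu
thresholding (rafts are brighter than PDMS), hole filling, border-object
removal, removal of speckle islands smaller than (10 µm)², morphological
closing with a 20 µm-radius disk (bridges the 30 µm intra-quad gap, never
the 100 µm barrier), and size exclusion to 0.5–1.5× the nominal quad area.

Index assignment fits a global lattice: rotation and pitch from
nearest-neighbor displacement vectors (gated to 0.75–1.25× the nominal
pitch so diagonal neighbors at √2 × pitch can never contaminate the
estimate — with heavy site deletion they are often the nearest survivors),
then a full affine refinement with one round of outlier rejection at
3 MAD. Each centroid takes the index of its nearest lattice site; on a
collision the nearer detection wins. Indices are shifted so the top-left
site is (0, 0). Duplicate centroids closer than 430 µm (0.8 quad pitches)
are consolidated by transitive averaging, iterated to a fixed point so the
output satisfies the minimum-separation contract exactly.

Missing sites are interpolated piecewise-linearly along their row and
column in segments of 8 mm (15 quads at 530 µm pitch) — short enough to
follow smooth array distortion — and the two estimates averaged with equal
weight. When a segment holds fewer than two anchors it widens to
neighboring segments; a site with no row or column anchors at all falls
back to the fitted global lattice. Grids from successive timepoints are
matched by index after resolving a per-timepoint integer index offset
(minimum median displacement of shared detected sites against the first
timepoint).

## Cytometry

Each labeled colony is assigned to the quad containing its centroid (via
the inverse lattice map). Coverage of each sub-raft is the covered pixel
fraction of that raft's footprint — the fitted 430 µm quad split into four
200 µm squares, with the 30 µm cross assigned to PDMS. A raft counts as
covered at ≥50%, giving the 1–4-raft class. PDMS coverage is normalized
over the intra-quad cross plus the half-barrier ring around the quad
(configurable to the cross only); per-raft PDMS outgrowth partitions that
footprint by nearest raft, which the release planner uses. A colony
spanning two quads is assigned to the quad under its centroid, with its
off-quad pixels counted as overgrowth.

Doubling times come from a least-squares fit of log₂(area) against time
over a 72 h window, with the confidence interval from the slope CI at
α = 5%; non-positive slopes are flagged as undefined rather than returned
as infinities. Biomarker positivity is the thresholded marker area over
the thresholded nuclear (Hoechst) area, Otsu per channel by default.

## Release planning and control

A quad is eligible for biopsy when ≥2 of its rafts have coverage strictly
above 0.5 (the threshold is strict at exactly 0.5, as printed); among the
covered rafts, the one with least adjacent-PDMS outgrowth is targeted.
Targets are ordered by a greedy Nearest-Neighbor tour from the array's
top-left scan origin; ties in the tour and in target selection break
lexicographically by (row, col, sub-raft) — deterministic replays matter
more than tour optimality.

The dislodgement extent of an attempt is 1 − (remaining material area in
the well / well area). Material pixels are classified by Otsu on the
pooled in-well intensities of the pre- and post-release frames — pooling
anchors the intact-raft mode so a fully cleared well still classifies
correctly — with the operating threshold placed at the midpoint of the two
class means, which is stable wherever in the inter-mode gap the Otsu split
lands. A unimodal pool means the post frame is indistinguishable from the
intact pre frame, i.e. extent 0. Re-aiming uses the intensity-weighted
centroid of remaining material; this makes the >80% extent rule and the
"aim at the undislodged raft" rule mutually consistent. The loop halts on
success (extent > 0.8), after 8 attempts, when the residual centroid has
drifted more than 70 µm from its position before the *first* attempt
(cumulative, not per-attempt), or when more than 1/3 of the raft's nominal
area lies outside the well.

The simulated ejector models a per-attempt full-clear probability that
decays with aim error (default 0.95·exp(−(d/80 µm)²/2), aim noise σ=3 µm,
in the few-micrometer range of a well-calibrated stage), with partial
clears and residual drift on misses; it renders every frame through the
single-well renderer so the loop exercises the same measurement path as
hardware would.

## The synthetic scene generator

The generator emulates what the sensing method depends on, with exact
ground truth:

- regular quad lattice (200 µm rafts, 30 µm gaps, 100 µm barriers, 530 µm
  pitch; 41 × 41 quads full-size, 8 × 8 by default for desk-scale scenes;
  1.625 µm/px, i.e. a 6.5 µm sensor pixel behind a 4× objective);
- distinct mean intensities for raft interior (1.0), intra-quad PDMS
  (0.78), barrier (0.70) and a bright 1.18 ring at raft walls, on a
  background mean of ~1 — values chosen to make the Otsu separations
  nontrivial, since no radiometry is implied by the method itself;
- fine static texture tied to the array surface (so it shifts with the
  stage and cancels under registration + subtraction), **identical across
  focal planes**;
- cells only inside the drawn mask: a ±25% punctate modulation plus a
  perimeter halo. Per-plane appearance is a phase rotation between two
  fixed random fields, with phase (π/2)·tanh(offset/10 µm): appearance
  decorrelates with defocus but saturates within roughly one objective
  depth of focus, so ±57 µm planes are fully decorrelated while planes a
  few µm apart are nearly identical (and zero spacing gives an exactly
  empty SDP);
- smooth illumination gradients (±10%), Gaussian sensor noise (σ = 0.02 of
  the background mean), sub-pixel stage misregistration between scans
  (±5 µm, ±0.15°), and a low-frequency sinusoidal lattice distortion
  (default 5 µm amplitude in rendered scenes, 20 µm in the tracking
  fixtures, 4 mm wavelength).

Colonies grow radially from a per-colony center offset up to ±90 µm from
the quad center, which realizes any requested per-raft coverage pattern
exactly (to one pixel) as a connected region. Random scenes draw covered
rafts from U(0.55, 1.0) and uncovered ones from {0} ∪ U(0.05, 0.45):
colonies in culture either spread onto a raft or barely touch it, rather
than hovering at the 50% boundary.

**What passing tests show — and don't.** The synthetic scenes validate the
*algorithmic* contracts: that the chain separates focus-varying from
focus-invariant structure under noise, misregistration, illumination
gradients and distortion, and that indexing, cytometry and release logic
are correct against exact truth. They do not model real optics (no PSF or
defocus convolution), fluorescence photophysics, cell-type-specific
morphology, condensation/debris artifacts, or gasket occlusion — so
absolute performance on real microscopy may differ, and hardware-bound
quantities (absolute SNR gains, release efficiency, attempt counts,
biomarker percentages) are outside what the synthetic suite can certify.

## Problem sizes

Desk-scale defaults keep the whole validation on one CPU: 8 × 8-quad
scenes (≈2600² px at three planes) for segmentation batches, 4 × 4 scenes
for the defocus sweep, the full 41 × 41 lattice (points, not images) for
tracking, and a ≥200-colony batch for cytometry. The full-size array
renderer exists behind the geometry parameters for larger runs.

## Known limitations

- Background texture is focus-invariant by construction; a real array has
  residual focus dependence that would leak into the B-SDP floor.
- Quad detection relies on rafts being brighter than PDMS after
  correction; heavy confluent overgrowth of the barriers (not modeled)
  would erode that margin.
- The lattice model is affine-plus-smooth-distortion; it does not model
  tears or local folds in the array.
- The release simulator's clear-probability model is a one-parameter
  stand-in for needle/substrate mechanics; only the control logic around
  it is validated, not the mechanics.
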