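# Methods

This note records the models behind `elysa_quant`, the parameters that
matter, the numerical conventions, and what the synthetic validation does
and does not establish about real data.

## Coordinate and digitisation conventions

Stacks are stored in `(z, c, y, x)` order with voxel sizes `(dz, dy, dx)`
in micrometres. The physical position of voxel `(k, j, i)` is its *center*,
`((k+0.5)·dz, (j+0.5)·dy, (i+0.5)·dx)`; indices are 0-based. Distances are
always computed in micrometres with anisotropic voxel sizes, never in voxel
units. Physical coordinates map back to voxel indices by floor division, so
a coordinate exactly on a voxel edge belongs to the higher-index voxel.

A voxel belongs to a rasterised solid iff its center lies inside the
analytic shape. This rule is brute-force checkable and makes digitisation
truth unambiguous: an object's "true volume" is its voxel count times the
voxel volume. Partial-volume effects enter only through the PSF blur at
render time. A phantom too small to capture any voxel center falls back to
the single voxel containing its analytic center, so every phantom appears
in the ground truth exactly once.

## The synthetic scene generator

The generator emulates single-cell confocal acquisitions of oocytes and
early embryos:

* **Cell**: a sphere of 75 µm diameter (the size of a mouse oocyte)
  centered in the field, with an optional uniform cytosolic signal per
  channel (default 100 counts) over a field background (default 20 counts).
* **Assemblies**: spheres, ellipsoids, or chains of overlapping spheres
  (the transient concatenated morphology seen at cell division), with
  equivalent diameters 0.2–10 µm. Placement draws a uniformly random
  direction and a radial distance from a stage-specific range, rejecting
  draws until the phantom clears the cell surface by ≥ 1 µm and every other
  phantom by ≥ 3 µm surface-to-surface (so rendered objects never merge).
* **Acquisition regimes**: 81 z-planes at 1 µm with 0.35 µm pixels
  (immunostaining-style) and 41 z-planes at 2 µm with 0.7 µm pixels
  (live ratio-imaging-style).
* **Forward model**: per channel,
  `image = Poisson(blur(field, PSF) + background) + N(0, σ_read)`, with a
  separable Gaussian PSF given in physical units and converted to per-axis
  voxel sigmas (default: one voxel per axis). Poisson-then-Gaussian is the
  standard confocal approximation; the seed fully determines the output
  bits.

### Stage presets

| stage | sub-µm puncta | large assemblies | placement of large |
|-------|---------------|------------------|--------------------|
| GV    | 120 × 0.2–0.8 µm | 5 × 3–5 µm   | medial (distal < 25 µm) |
| MII   | 17 × 0.2–0.8 µm  | 8 × 3–7 µm   | peripheral (distal > 30 µm) |
| E2C   | 60 × 0.2–0.8 µm  | 12 × 1–3 µm + one 3-sphere chain | spread |
| L2C   | 40 × 0.2–0.8 µm  | 8 × 1–3 µm   | spread |

These magnitudes are qualitative emulations of the published stage
distributions (many small structures before maturation, few giant
peripheral ones at MII, intermediate sizes after fertilization); no public
dataset pins the exact per-stage abundances, so the counts were fixed once
at values a microscopist would call representative and are not revisited.
Channel membership: LAMP1 on every assembly; RAB5 on an exact 30% subset
(drawn without replacement, so recovery tests measure the pipeline rather
than binomial noise); LC3 preferentially (85%) on structures ≥ 2 µm and
rarely (5%) below — mirroring the observation that small lysosomal
structures are seldom LC3-positive.

**Intensity tiers.** Resolved assemblies (≥ 3 µm) carry a plateau intensity
of 2000 counts; sub-resolution puncta carry 20000 counts. The boost keeps a
diffraction-limited punctum's PSF-blurred peak (≈ 6% of its nominal
intensity) above the segmentation threshold, just as real immunostained
puncta are detected by brightness rather than apparent size.

### What the generator does not emulate

Spectral bleed-through, photobleaching, depth-dependent PSF broadening,
refractive-index mismatch, non-spherical cells, the zona pellucida and
polar body, and time-lapse motion. Passing the recovery tests therefore
shows the *measurement chain* is correct on data obeying the stated forward
model; it does not certify threshold choices for any particular microscope.

## Segmentation parameters

* `threshold` (default 900, working range 600–1200 counts): one global
  strict `>` threshold after background subtraction. For the synthetic
  recovery runs the value 800 is used: a pure half-plateau threshold (1000)
  systematically undersizes barely-resolved 3 µm assemblies, whose blurred
  peak falls below the plateau because of the 1 µm axial PSF; 800 balances
  that dimming against edge dilation (maximum equivalent-diameter error
  2.6% across seeds, versus 11.6% at 1000). This calibration against
  digitisation truth is the synthetic analogue of choosing the threshold
  manually per dataset. An Otsu-based automatic mode exists as a clearly
  labelled extension.
* `blur_sigma_px` (default 1): light Gaussian smoothing for noisy real
  acquisitions. Recovery runs on synthetic stacks use 0 — the rendered data
  are already band-limited by the PSF, and further smoothing only dims
  sub-resolution puncta toward the threshold.
* `background_mode`: mean of ≥ 1 blank regions outside the cell (default:
  four 16-px corner boxes over the full z-extent), a low percentile, or
  none. Subtraction clamps at zero; fluorescence counts cannot be negative.
* `connectivity` (default 26, the convention of classical 3D object
  counting; 6 and 18 available): labels are contiguous from 1 in
  raster-scan order of each component's first voxel, a deterministic
  tie-break that makes runs byte-reproducible.
* `volume_filter_um3` (default `(0, 5000]`): removes plasma-membrane sheets
  and debris. `boundary_exclusion_um` (default 0 = off) additionally drops
  objects whose centroid lies within the given distance of the cell-mask
  boundary — a deterministic surrogate for manual erasing of cortical
  signal, which cannot live in a reproducible pipeline.

Centroids are unweighted means of member-voxel centers ("geometric
center"), not intensity-weighted; the two differ for objects with internal
intensity gradients, and the unweighted form matches the volume-based
morphometry.

## Cell geometry

The cell's center plane is the midpoint of the first and last z-planes
carrying above-threshold signal (≥ 16 px per plane, guarding against lone
noise voxels). The cell mask is the filled largest bright region of that
plane after Otsu thresholding; bright organelles are clipped to the 99.5th
percentile first so Otsu separates cytosol from outside rather than
organelle from cytosol. The 3D cell center combines the mask centroid with
the plane height and is recovered within one voxel on phantom cells.

## Distal distance

`distal = ‖centroid − cell_center‖₂ + mean_surface_distance`, where the
surface is the set of member voxels with a face-adjacent (6-neighbourhood)
non-member — the standard digital surface, used regardless of the labeling
connectivity. A single-voxel object has surface distance 0, so distal
equals centroid distance exactly there and strictly exceeds it everywhere
else. On digitised spheres the surface term converges to the true radius
from below as voxels shrink. Zone cutoffs are strict on both sides
(peripheral > 30 µm, medial < 25 µm); the 25–30 µm band is reported as
`intermediate`, never silently discarded.

## Colocalization

The default test is partner-center-inside-reference-object: the voxel
containing the partner's geometric center must carry a nonzero reference
label. This is the standard object-based criterion; it is monotone under
reference dilation (lowering the reference threshold can only gain hosts)
and is verified against exhaustive point-in-label lookup. A stricter
center-to-center distance variant (`method="center_distance"`, default gate
1 µm) is available but not the default, since a small partner structure on
the shoulder of a large assembly should count as colocalized even though
the two centers are far apart.

## Ratio imaging

Ratio images are computed on mean z-projections (the standard 2D analysis;
the channels share optics, so the projection dilutes numerator and
denominator equally and leaves per-pixel ratios intact). Each channel's
background is estimated independently from the same blank regions and
subtracted with clamping at zero. Pixels whose corrected denominator is at
or below a floor — default three times the blank-region standard deviation
of the denominator channel — are masked invalid instead of divided, which
replaces near-zero-division blow-ups with explicit missingness;
per-structure statistics use valid pixels only and structures with no valid
pixel are flagged rather than numbered. Display uses a fixed 32-point
"fire" color table interpolated to 256 entries, with invalid pixels black.
Exact invariants (scale equivariance, channel-swap reciprocity) hold in the
zero-background limit; with estimated backgrounds they hold to the
precision of the background estimate.

## Group statistics

The statistical unit is the cell: per-object values within one cell are
not independent, so ANOVA and Tukey HSD run on per-cell summaries, with
mean ± SEM reported per group. The compact letter display uses the
insert-and-absorb algorithm: start with one bucket holding all groups, and
for every significantly different pair split any bucket containing both,
discarding buckets contained in others. Degenerate input (all values
identical) is reported as "no differences" with a note instead of a failed
F-test. Two same-distribution groups (n = 10) retain Tukey p > 0.05 in
≈ 95% of replicates, the expected type-I behaviour.

## Problem sizes used in validation

The standard recovery scene is the MII preset: 256 × 256 × 81 voxels at
0.35 × 0.35 × 1.0 µm with 25 phantoms — large enough to contain a full
75 µm cell at realistic sampling while a complete render-and-quantify cycle
stays in seconds on one CPU. Oracle checks use 100 random 20³ volumes
(p = 0.2) for labeling and 50 random two-channel scenes for colocalization;
ratio recovery uses the 41-plane live regime; the type-I check uses 100
seeded two-group replicates. `scripts/acceptance.py` reruns all of these
from scratch for any seed.

## Known limitations

* Sub-resolution objects are detected and counted correctly but their
  threshold-based volumes are inflated by the PSF (a property of confocal
  imaging, not of this implementation); size-resolved statements are
  therefore made for objects ≥ 1 µm.
* One global threshold per channel assumes roughly uniform staining
  efficiency across the cell; depth-dependent attenuation is not modelled
  or corrected.
* The cell model is a sphere; strongly aspherical or dividing cells will
  bias the single-center distal distance (each blastomere would need its
  own center, which the pipeline does not yet compute).
* Chains count as single objects; no attempt is made to decompose them
  into constituent spheres.
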