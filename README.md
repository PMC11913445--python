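# elysa-quant

Single-cell 3D quantification of giant endosomal–lysosomal assemblies
(ELYSAs) from multi-channel confocal z-stacks.

Mouse oocytes concentrate their endosomes and lysosomes into large (up to
7–8 µm) spherical assemblies that migrate to the cell cortex during
maturation and disassemble after fertilization. Quantifying this behaviour
from confocal stacks of single oocytes/embryos requires a specific chain of
measurements: reconstructing every labelled organelle as a 3D object,
expressing its size as an equivalent-sphere diameter, measuring how far it
reaches toward the cell surface, testing which assemblies carry additional
markers, and reading out their acidification state from dye ratios. This
package implements that chain as a tested, scriptable pipeline for
cell-biology labs working on oocyte/embryo organelle remodelling — together
with a synthetic scene generator that renders phantom cells with exactly
known ground truth, so every stage of the pipeline can be validated
quantitatively.

## The measurements

**3D object reconstruction.** Per channel: subtract a scalar background
(mean of blank regions outside the cell), optionally smooth (Gaussian,
σ = 1 px), apply one global intensity threshold (strict `>`, typical range
600–1200 counts), label 26-connected components, and filter by volume
(objects in `(0, 5000]` µm³ by default, which removes plasma-membrane
sheets). Each object gets its voxel count, volume `V`, integrated and mean
intensity, and unweighted geometric centroid in µm.

**Equivalent-sphere diameter.** Sizes are reported as

```
d = (6 V / π)^(1/3)
```

and binned on a fine partition (0.2, 0.4, 0.6, 0.8, 1, 2, …, 10 µm) from
which any coarser size class is a sum of bins.

**Distal distance and zones.** For an object with centroid `c`, cell center
`o` and mean centroid-to-surface distance `s̄` (mean Euclidean distance from
the centroid to the centers of its face-exposed surface voxels),

```
distal distance = ‖c − o‖₂ + s̄
```

The surface term prevents under-estimating how far a *large* assembly
extends. Objects are classified `peripheral` (> 30 µm), `medial` (< 25 µm)
or `intermediate` (the band in between, reported explicitly).

**Object-based colocalization.** A partner-channel object (RAB5, LC3, …)
is colocalized when the voxel containing its geometric center carries a
reference-channel (LAMP1) label; reference objects hosting at least one
partner center are "double positive" and summarised by count, volume and
mean ± SEM diameter.

**Ratiometric acidification.** Two acidity channels are mean-projected,
background-corrected from the same blank regions and divided pixel by
pixel; pixels whose denominator stays below a noise floor are masked
invalid rather than divided. Per-structure medians, line profiles and
"fire"-LUT renderings come from the valid pixels only.

**Group statistics.** Per-cell summary values (the cell, not the object, is
the statistical unit) are compared by one-way ANOVA with Tukey's HSD and a
compact letter display: groups sharing no letter differ at p < 0.05.

## Worked example

Render a metaphase-II-like phantom cell (75 µm diameter, 25 assemblies with
known sizes and positions, 81 z-planes at 1 µm, Poisson + read noise) and
quantify it:

```python
from elysa_quant.synthetic_scene import preset_stage_scene, render_scene
from elysa_quant.segmentation3d import (SegmentationParams, segment_stack,
                                        filter_objects, find_cell_geometry)
from elysa_quant.spatial_distribution import add_distal_columns, zone_counts
from elysa_quant.morphometry import bin_by_diameter, volume_fraction_above

spec = preset_stage_scene("MII", seed=1)
stack, truth = render_scene(spec)
vol = stack.channel("LAMP1")
size = stack.voxel_size_um

params = SegmentationParams(threshold=800.0, blur_sigma_px=0.0)
geometry = find_cell_geometry(vol, size)
labels, table, background = segment_stack(vol, size, params)
table = filter_objects(table, params, geometry, size)
table = add_distal_columns(table, geometry.center_um)
```

Printing the headline quantities gives:

```
objects: 25 (truth: 25)
background: 20.0 counts
cell center (z, y, x): (40.5, 44.8, 44.8) um
volume fraction in structures > 3 um: 97.2 %
objects > 4 um by zone: 7 peripheral, 0 medial, 0 intermediate
 bin_lo_um  bin_hi_um  count  volume_um3
       1.0        2.0     17     21.3150
       3.0        4.0      1     25.3575
       4.0        5.0      3    155.3300
       5.0        6.0      1     71.0500
       6.0        7.0      3    497.8400
```

Every phantom is recovered (25/25), the background estimate matches the
programmed 20 counts, the recovered cell center sits at the true grid
center, and all giant (> 4 µm) assemblies are classified peripheral — the
hallmark MII arrangement. The 17 sub-micrometre puncta appear in the 1–2 µm
bin because a diffraction-limited spot cannot measure smaller than the PSF;
the resolved assemblies bin at their true sizes.

The same flows are available from the shell:

```bash
elysa-quant simulate --stage MII --seed 1 --out scene/
elysa-quant segment --input scene/scene.ome.tif --channel LAMP1 \
    --threshold 800 --blur-sigma 0 --out seg/
elysa-quant analyze --config run.yaml
elysa-quant compare --input per_cell_values.csv
```

## Layout

```
src/elysa_quant/        library (synthetic_scene, stack_io, segmentation3d,
                        morphometry, spatial_distribution, colocalization,
                        acidification_ratio, pipeline, stats, cli)
tests/                  pytest suite, including end-to-end acceptance tests
scripts/acceptance.py   from-scratch recomputation of the headline numbers
docs/methods.md         models, parameters, numerical conventions, limits
```
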