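"""Synthetic confocal scenes of single cells with known ground truth.

A scene is a roughly spherical cell (default 75 um diameter, the size of a
mouse oocyte) containing organellar-assembly phantoms: spheres, ellipsoids
or chains of overlapping spheres, 0.2-10 um in equivalent diameter, placed
at controlled radial distances from the cell center.  Each phantom carries
per-channel intensities (LAMP1 on every assembly; RAB5/LC3 on subsets;
acidity-dye channels with programmed ratios).  Rendering follows the
standard confocal forward model:

    image = Poisson( blur(intensity field, PSF) + background ) + read noise

with a separable anisotropic Gaussian PSF given in physical units and
converted to per-axis voxel sigmas.  The same seed always reproduces the
scene bit for bit.

Voxel-inclusion rule: a voxel belongs to a solid iff its *center* lies
inside the analytic shape; partial-volume effects enter only through the PSF
blur.  Ground truth (label volume and per-phantom table) is recorded from
this pre-blur digitisation, so "true volume" means voxel count times voxel
volume -- the quantity a perfect segmentation of the digitised scene would
recover.  A phantom too small to capture any voxel center falls back to the
single voxel containing its center, so every phantom id appears in the
ground truth.

Two acquisition regimes are preset, matching common immunostaining
(81 z-planes at 1 um) and live ratio imaging (41 z-planes at 2 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .morphometry import equivalent_diameter
from .spatial_distribution import mean_surface_distance
from .stack_io import ImageStack, write_label_volume, write_stack


class PlacementError(ValueError):
    """A phantom does not fit in the grid or collides with another."""


class SceneConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """One assembly to place in the cell.

    ``center_offset_um`` is the (z, y, x) offset of the phantom center from
    the cell center, in micrometres.  For ellipsoids, ``axis_ratios`` are
    per-axis (z, y, x) semi-axis ratios, normalised internally so that
    ``diameter_um`` remains the equivalent-sphere diameter.  For chains,
    ``chain_diameters_um`` lists the member sphere diameters laid out along
    ``chain_axis`` with consecutive centers ``(r_i + r_j) * (1 - overlap)``
    apart; overlap must lie in [0, 0.5).
    """

    id: int
    shape: str = "sphere"                 # sphere | ellipsoid | chain
    diameter_um: float = 1.0
    center_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_intensities: Mapping[str, float] = field(default_factory=dict)
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    chain_diameters_um: tuple[float, ...] = ()
    chain_overlap: float = 0.25
    chain_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "chain"):
            raise SceneConfigError(f"unknown phantom shape {self.shape!r}")
        if self.shape == "chain":
            if not self.chain_diameters_um:
                raise SceneConfigError("chain phantom needs chain_diameters_um")
            if any(d <= 0 for d in self.chain_diameters_um):
                raise SceneConfigError("chain diameters must be positive")
            if not 0.0 <= self.chain_overlap < 0.5:
                raise SceneConfigError("chain overlap fraction must be in [0, 0.5)")
        elif self.diameter_um <= 0:
            raise SceneConfigError(f"phantom {self.id}: diameter must be positive")
        if any(v < 0 for v in self.channel_intensities.values()):
            raise SceneConfigError(f"phantom {self.id}: negative channel intensity")

    # -- geometry helpers --------------------------------------------------
    def _semi_axes(self) -> np.ndarray:
        ratios = np.asarray(self.axis_ratios, dtype=float)
        ratios = ratios / np.cbrt(ratios.prod())
        return self.diameter_um / 2.0 * ratios

    def _chain_centers_radii(self):
        radii = np.asarray(self.chain_diameters_um, dtype=float) / 2.0
        axis = np.asarray(self.chain_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        pos = np.zeros(len(radii))
        for i in range(1, len(radii)):
            pos[i] = pos[i - 1] + (radii[i - 1] + radii[i]) * (1.0 - self.chain_overlap)
        # recenter so the chain's physical extremes straddle the phantom center
        mid = 0.5 * ((pos[0] - radii[0]) + (pos[-1] + radii[-1]))
        centers = (pos - mid)[:, None] * axis[None, :]
        return centers, radii

    def extent_um(self) -> np.ndarray:
        """Per-axis (z, y, x) half-extent of the solid around its center."""
        if self.shape == "sphere":
            return np.full(3, self.diameter_um / 2.0)
        if self.shape == "ellipsoid":
            return self._semi_axes()
        centers, radii = self._chain_centers_radii()
        return np.max(np.abs(centers) + radii[:, None], axis=0)

    def max_radius_um(self) -> float:
        """Radius of the bounding sphere around the phantom center."""
        if self.shape == "sphere":
            return self.diameter_um / 2.0
        if self.shape == "ellipsoid":
            return float(self._semi_axes().max())
        centers, radii = self._chain_centers_radii()
        return float(np.max(np.linalg.norm(centers, axis=1) + radii))


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic cell acquisition."""

    grid_shape: tuple[int, int, int]                 # (nz, ny, nx)
    voxel_size_um: tuple[float, float, float]        # (dz, dy, dx)
    cell_diameter_um: float = 75.0
    channels: tuple[str, ...] = ("LAMP1",)
    phantoms: tuple[PhantomSpec, ...] = ()
    psf_sigma_um: tuple[float, float, float] = (1.0, 0.35, 0.35)
    background_counts: float = 20.0
    cytosol_counts: Mapping[str, float] = field(default_factory=dict)
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise SceneConfigError("grid_shape entries must be positive")
        if any(s <= 0 for s in self.voxel_size_um):
            raise SceneConfigError("voxel sizes must be positive")
        if self.cell_diameter_um <= 0:
            raise SceneConfigError("cell diameter must be positive")
        if self.background_counts < 0 or self.read_noise_sd < 0:
            raise SceneConfigError("background and read noise must be non-negative")
        if any(s < 0 for s in self.psf_sigma_um):
            raise SceneConfigError("PSF sigmas must be non-negative")
        ids = [p.id for p in self.phantoms]
        if len(set(ids)) != len(ids):
            raise SceneConfigError("phantom ids must be unique")
        extent = self.physical_extent_um
        if self.cell_diameter_um > min(extent):
            raise SceneConfigError(
                f"cell of {self.cell_diameter_um} um does not fit in grid extent {extent}")

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_size_um))

    @property
    def cell_center_um(self) -> tuple[float, float, float]:
        return tuple(e / 2.0 for e in self.physical_extent_um)

    @property
    def cell_radius_um(self) -> float:
        return self.cell_diameter_um / 2.0


@dataclass
class GroundTruth:
    """Exact digitisation truth of a rendered scene.

    ``label_volume`` holds 0 for background and the phantom id elsewhere;
    ``table`` has one row per phantom (volumes, centroids, radial/distal
    distances, channel memberships), mutually consistent with the labels.
    """

    label_volume: np.ndarray
    table: pd.DataFrame
    cell_center_um: tuple[float, float, float]
    cell_radius_um: float

    def validate(self) -> None:
        """Assert the id bijection between label volume and table."""
        in_volume = set(np.unique(self.label_volume)) - {0}
        in_table = set(int(i) for i in self.table["id"])
        if in_volume != in_table:
            raise AssertionError(
                f"label/table id mismatch: {in_volume ^ in_table}")


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _axis_centers(n: int, step: float, lo: int, hi: int) -> np.ndarray:
    return (np.arange(lo, hi) + 0.5) * step


def _rasterize_bbox(spec: PhantomSpec, scene: SceneSpec):
    """Rasterise one phantom into its bounding box.

    Returns ``(submask, lo)``: a boolean array and the index of its origin
    corner in the scene grid.
    """
    size = np.asarray(scene.voxel_size_um, dtype=float)
    shape = np.asarray(scene.grid_shape, dtype=int)
    center = np.asarray(scene.cell_center_um) + np.asarray(spec.center_offset_um)
    extent = spec.extent_um()
    phys = np.asarray(scene.physical_extent_um)
    if np.any(center - extent < 0) or np.any(center + extent > phys):
        raise PlacementError(
            f"phantom {spec.id} extends beyond the grid "
            f"(center {tuple(np.round(center, 2))}, extent {tuple(np.round(extent, 2))})")

    lo = np.maximum(0, np.floor((center - extent) / size - 0.5).astype(int))
    hi = np.minimum(shape, np.ceil((center + extent) / size + 0.5).astype(int))
    zz = _axis_centers(shape[0], size[0], lo[0], hi[0])[:, None, None]
    yy = _axis_centers(shape[1], size[1], lo[1], hi[1])[None, :, None]
    xx = _axis_centers(shape[2], size[2], lo[2], hi[2])[None, None, :]

    if spec.shape == "sphere":
        r2 = (spec.diameter_um / 2.0) ** 2
        inside = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                  + (xx - center[2]) ** 2) <= r2
    elif spec.shape == "ellipsoid":
        a = spec._semi_axes()
        inside = (((zz - center[0]) / a[0]) ** 2 + ((yy - center[1]) / a[1]) ** 2
                  + ((xx - center[2]) / a[2]) ** 2) <= 1.0
    else:
        centers, radii = spec._chain_centers_radii()
        inside = np.zeros(tuple(hi - lo), dtype=bool)
        for c, r in zip(centers, radii):
            cc = center + c
            inside |= ((zz - cc[0]) ** 2 + (yy - cc[1]) ** 2
                       + (xx - cc[2]) ** 2) <= r ** 2

    if not inside.any():
        # sub-voxel phantom: fall back to the voxel containing the center
        idx = np.minimum(np.floor(center / size).astype(int), shape - 1)
        lo = idx
        inside = np.ones((1, 1, 1), dtype=bool)
    return inside, lo


def rasterize_phantom(spec: PhantomSpec, scene: SceneSpec) -> np.ndarray:
    """Boolean voxel mask of one phantom on the scene grid.

    A voxel is included iff its physical center lies inside the analytic
    solid; chains are unions of their member spheres.  Raises
    :class:`PlacementError` if the phantom extends beyond the grid.  An
    analytically non-empty phantom that captures no voxel center (possible
    below the voxel size) falls back to the voxel containing its center.
    """
    inside, lo = _rasterize_bbox(spec, scene)
    mask = np.zeros(scene.grid_shape, dtype=bool)
    hi = lo + np.asarray(inside.shape)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    return mask


def cell_mask_volume(scene: SceneSpec) -> np.ndarray:
    """Boolean mask of the spherical cell body on the scene grid."""
    size = np.asarray(scene.voxel_size_um, dtype=float)
    nz, ny, nx = scene.grid_shape
    zz = ((np.arange(nz) + 0.5) * size[0])[:, None, None]
    yy = ((np.arange(ny) + 0.5) * size[1])[None, :, None]
    xx = ((np.arange(nx) + 0.5) * size[2])[None, None, :]
    c = scene.cell_center_um
    return ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            <= scene.cell_radius_um ** 2)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def digitize_scene(scene: SceneSpec) -> tuple[GroundTruth, dict]:
    """Rasterise all phantoms and build the ground truth, without rendering.

    Returns ``(truth, masks)`` where ``masks`` maps phantom id to a
    ``(submask, lo)`` pair: the phantom's boolean bounding-box mask and the
    grid index of its origin corner.  Overlapping phantoms raise
    :class:`PlacementError` so the label/table bijection always holds.
    """
    size = np.asarray(scene.voxel_size_um, dtype=float)
    vox_vol = float(size.prod())
    cell_center = np.asarray(scene.cell_center_um)

    labels = np.zeros(scene.grid_shape, dtype=np.int32)
    rows = []
    masks: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for spec in scene.phantoms:
        sub, lo = _rasterize_bbox(spec, scene)
        hi = lo + np.asarray(sub.shape)
        view = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        clash = view[sub]
        if np.any(clash):
            other = int(clash[clash != 0][0])
            raise PlacementError(f"phantoms {other} and {spec.id} overlap")
        view[sub] = spec.id
        masks[spec.id] = (sub, lo)

        count = int(sub.sum())
        volume = count * vox_vol
        idx = np.argwhere(sub) + lo
        centroid = (idx.mean(axis=0) + 0.5) * size
        msd = (mean_surface_distance(sub, centroid - lo * size, size)
               if count > 1 else 0.0)
        radial = float(np.linalg.norm(centroid - cell_center))
        row = {
            "id": spec.id,
            "shape": spec.shape,
            "nominal_diameter_um": (spec.diameter_um if spec.shape != "chain"
                                    else np.nan),
            "voxel_count": count,
            "volume_um3": volume,
            "equivalent_diameter_um": equivalent_diameter(volume),
            "centroid_z_um": centroid[0],
            "centroid_y_um": centroid[1],
            "centroid_x_um": centroid[2],
            "radial_distance_um": radial,
            "mean_surface_distance_um": msd,
            "distal_distance_um": radial + msd,
        }
        for ch in scene.channels:
            inten = float(spec.channel_intensities.get(ch, 0.0))
            row[f"member_{ch}"] = inten > 0
            row[f"intensity_{ch}"] = inten
        rows.append(row)

    table = pd.DataFrame(rows)
    if table.empty:
        cols = ["id", "shape", "nominal_diameter_um", "voxel_count", "volume_um3",
                "equivalent_diameter_um", "centroid_z_um", "centroid_y_um",
                "centroid_x_um", "radial_distance_um", "mean_surface_distance_um",
                "distal_distance_um"]
        for ch in scene.channels:
            cols += [f"member_{ch}", f"intensity_{ch}"]
        table = pd.DataFrame({c: [] for c in cols})

    truth = GroundTruth(labels, table, tuple(cell_center), scene.cell_radius_um)
    return truth, masks


def render_scene(scene: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render all channels of a scene and return the stack plus ground truth.

    Per channel: the noiseless intensity field (cell-wide cytosolic level
    inside the cell mask, plus each member phantom's programmed intensity) is
    blurred with the Gaussian PSF, offset by the background, Poisson-sampled
    and degraded with additive Gaussian read noise.  Identical specs (same
    seed) produce bit-identical stacks.  Ground truth comes from
    :func:`digitize_scene`, i.e. the pre-blur rasterisation.
    """
    size = np.asarray(scene.voxel_size_um, dtype=float)
    rng = np.random.default_rng(scene.seed)
    truth, masks = digitize_scene(scene)
    cell = cell_mask_volume(scene)

    sigma_vox = np.asarray(scene.psf_sigma_um) / size
    data = np.empty((scene.grid_shape[0], len(scene.channels),
                     scene.grid_shape[1], scene.grid_shape[2]), dtype=np.float32)
    cytosol = dict(scene.cytosol_counts)
    for ci, ch in enumerate(scene.channels):
        field_ = np.zeros(scene.grid_shape, dtype=float)
        cyto = float(cytosol.get(ch, 0.0))
        if cyto > 0:
            field_[cell] = cyto
        for spec in scene.phantoms:
            inten = float(spec.channel_intensities.get(ch, 0.0))
            if inten > 0:
                sub, lo = masks[spec.id]
                hi = lo + np.asarray(sub.shape)
                view = field_[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                view[sub] = inten
        if np.any(sigma_vox > 0):
            field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox)
        field_ += scene.background_counts
        img = rng.poisson(field_).astype(np.float32)
        if scene.read_noise_sd > 0:
            img += rng.normal(0.0, scene.read_noise_sd,
                              size=img.shape).astype(np.float32)
        data[:, ci] = img

    stack = ImageStack(data, tuple(scene.voxel_size_um), tuple(scene.channels))
    return stack, truth


# ---------------------------------------------------------------------------
# stage presets
# ---------------------------------------------------------------------------

#: Acquisition regimes: (grid_shape, voxel_size_um, psf_sigma_um)
PRESET_REGIMES = {
    "immuno": ((81, 256, 256), (1.0, 0.35, 0.35), (1.0, 0.35, 0.35)),
    "live": ((41, 128, 128), (2.0, 0.7, 0.7), (2.0, 0.7, 0.7)),
}

STAGES = ("GV", "MII", "E2C", "L2C")

#: Plateau intensity of resolved (>= 3 um) assemblies and boosted intensity
#: of sub-resolution puncta, in photon counts.  The boost keeps
#: diffraction-limited puncta above a half-plateau threshold after PSF blur.
ELYSA_INTENSITY = 2000.0
PUNCTA_INTENSITY = 20000.0
CYTOSOL_COUNTS = 100.0
BACKGROUND_COUNTS = 20.0
READ_NOISE_SD = 2.0

#: Fraction of assemblies carrying early-endosome (RAB5) signal; assigned as
#: an exact fraction of the phantom list so recovery tests measure the
#: pipeline, not binomial noise.
RAB5_FRACTION = 0.3

_MIN_GAP_UM = 3.0        # surface-to-surface separation between phantoms
_EDGE_MARGIN_UM = 1.0    # clearance from the cell surface


def _intensity_for(diameter: float) -> float:
    return ELYSA_INTENSITY if diameter >= 3.0 else PUNCTA_INTENSITY


def _place_phantoms(rng, sizes_radials, max_tries: int = 2000):
    """Rejection-sample (offset, radius) placements: directions uniform on
    the sphere, radial distance from each phantom's stated range, rejected
    until the phantom fits in the cell and clears previously placed ones."""
    placed = []          # (offset vector, bounding radius)
    offsets = []
    r_cell = 37.5
    for bound_r, (r_lo, r_hi) in sizes_radials:
        for _ in range(max_tries):
            direction = rng.normal(size=3)
            norm = np.linalg.norm(direction)
            if norm < 1e-12:
                continue
            direction /= norm
            radial = rng.uniform(r_lo, r_hi)
            if radial + bound_r > r_cell - _EDGE_MARGIN_UM:
                continue
            offset = radial * direction
            ok = all(np.linalg.norm(offset - o) >= br + bound_r + _MIN_GAP_UM
                     for o, br in placed)
            if ok:
                placed.append((offset, bound_r))
                offsets.append(offset)
                break
        else:
            raise PlacementError("could not place phantom after rejection sampling; "
                                 "scene too crowded")
    return offsets


def preset_stage_scene(stage: str, seed: int, regime: str = "immuno") -> SceneSpec:
    """Build the SceneSpec emulating one developmental stage.

    * ``GV``  -- many 0.2-0.8 um puncta spread through the cytoplasm plus a
      few 3-5 um assemblies placed medially (distal distance < 25 um).
    * ``MII`` -- fewer puncta; several 3-7 um assemblies placed so their
      distal distance exceeds 30 um (peripheral, just beneath the plasma
      membrane).
    * ``E2C`` / ``L2C`` -- the giant assemblies are replaced by 1-3 um
      structures; E2C additionally carries one concatenated-sphere chain,
      the transient division-stage morphology.

    Channel memberships: LAMP1 on every phantom, RAB5 on an exact 30%
    subset, LC3 preferentially on structures >= 2 um.  Same stage and seed
    always return the identical spec.
    """
    stage = stage.upper()
    if stage not in STAGES:
        raise SceneConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if regime not in PRESET_REGIMES:
        raise SceneConfigError(f"unknown regime {regime!r}")
    grid, voxel, psf = PRESET_REGIMES[regime]
    rng = np.random.default_rng(seed)

    chain = None
    if stage == "GV":
        n_small, small_range = 120, (0.2, 0.8)
        n_large, large_range, large_radial = 5, (3.0, 5.0), (5.0, 18.0)
    elif stage == "MII":
        n_small, small_range = 17, (0.2, 0.8)
        n_large, large_range, large_radial = 8, (3.0, 7.0), (30.2, 32.0)
    elif stage == "E2C":
        n_small, small_range = 60, (0.2, 0.8)
        n_large, large_range, large_radial = 12, (1.0, 3.0), (3.0, 30.0)
        chain = ((5.0, 5.0, 5.0), 0.25, (8.0, 14.0))
    else:  # L2C
        n_small, small_range = 40, (0.2, 0.8)
        n_large, large_range, large_radial = 8, (1.0, 3.0), (3.0, 30.0)

    diam_large = rng.uniform(*large_range, size=n_large)
    diam_small = rng.uniform(*small_range, size=n_small)
    requests = [(d / 2.0, large_radial) for d in diam_large]
    requests += [(d / 2.0, (3.0, 30.0)) for d in diam_small]
    chain_spec_geom = None
    if chain is not None:
        diams, overlap, radial_rng = chain
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        probe = PhantomSpec(id=0, shape="chain", chain_diameters_um=diams,
                            chain_overlap=overlap, chain_axis=tuple(axis))
        requests.append((probe.max_radius_um(), radial_rng))
        chain_spec_geom = (diams, overlap, tuple(axis))

    offsets = _place_phantoms(rng, requests)
    diameters = list(diam_large) + list(diam_small)

    n_total = len(requests)
    n_rab5 = int(round(RAB5_FRACTION * n_total))
    rab5_ids = set(rng.choice(n_total, size=n_rab5, replace=False).tolist())

    phantoms = []
    for i in range(n_total):
        pid = i + 1
        is_chain = chain_spec_geom is not None and i == n_total - 1
        d = 4.0 if is_chain else diameters[i]   # chains count as large for LC3
        intens = {"LAMP1": _intensity_for(5.0 if is_chain else d)}
        if i in rab5_ids:
            intens["RAB5"] = _intensity_for(5.0 if is_chain else d)
        lc3_p = 0.85 if d >= 2.0 else 0.05
        if rng.random() < lc3_p:
            intens["LC3"] = _intensity_for(5.0 if is_chain else d)
        if is_chain:
            diams, overlap, axis = chain_spec_geom
            phantoms.append(PhantomSpec(
                id=pid, shape="chain", chain_diameters_um=diams,
                chain_overlap=overlap, chain_axis=axis,
                center_offset_um=tuple(offsets[i]),
                channel_intensities=intens))
        else:
            phantoms.append(PhantomSpec(
                id=pid, shape="sphere", diameter_um=float(diameters[i]),
                center_offset_um=tuple(offsets[i]),
                channel_intensities=intens))

    return SceneSpec(
        grid_shape=grid,
        voxel_size_um=voxel,
        cell_diameter_um=75.0,
        channels=("LAMP1", "RAB5", "LC3"),
        phantoms=tuple(phantoms),
        psf_sigma_um=psf,
        background_counts=BACKGROUND_COUNTS,
        cytosol_counts={"LAMP1": CYTOSOL_COUNTS, "RAB5": CYTOSOL_COUNTS,
                        "LC3": CYTOSOL_COUNTS},
        read_noise_sd=READ_NOISE_SD,
        seed=seed,
    )


def save_scene(out_dir, stack: ImageStack, truth: GroundTruth) -> dict:
    """Write a rendered scene: OME-TIFF stack, 16-bit label TIFF and the
    ground-truth CSV.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "scene.ome.tif",
        "labels": out / "truth_labels.tif",
        "table": out / "truth_objects.csv",
    }
    write_stack(stack, paths["stack"])
    write_label_volume(truth.label_volume, paths["labels"])
    truth.table.to_csv(paths["table"], index=False)
    return paths
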