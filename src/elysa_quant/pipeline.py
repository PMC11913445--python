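"""Configuration-driven orchestration over one or many cells.

A run takes a list of cells (each either a stack on disk or a simulated
stage/seed), segments the reference channel, measures and filters objects,
computes distal distances and zones, bins the size distribution, runs
object-based colocalization against the partner channels, and optionally
builds a ratio image from a designated channel pair.  All tabular outputs
are written as CSV with stable column order, and a manifest records every
written file with a SHA-256 checksum, so a seeded run is reproducible byte
for byte.

A failure in one cell is logged with the cell id and stage name; the other
cells continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import colocalization, morphometry, spatial_distribution, synthetic_scene
from .acidification_ratio import make_ratio_image, per_object_ratio
from .segmentation3d import (SegmentationParams, filter_objects,
                             find_cell_geometry, segment_stack)
from .stack_io import ImageStack, read_stack, write_label_volume
from .stats import GroupComparison, compare_groups  # noqa: F401  (public API)

log = logging.getLogger("elysa_quant.pipeline")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CellInput:
    """One cell: either a TIFF path or a simulated stage + seed."""

    cell_id: str
    group: str
    stage: str | None = None
    seed: int | None = None
    path: str | None = None
    regime: str = "immuno"

    def __post_init__(self) -> None:
        if (self.stage is None) == (self.path is None):
            raise ConfigError(
                f"cell {self.cell_id!r}: exactly one of stage or path is required")


@dataclass(frozen=True)
class RunConfig:
    cells: tuple[CellInput, ...]
    reference: str = "LAMP1"
    partners: tuple[str, ...] = ()
    ratio_pair: tuple[str, str] | None = None
    seg_params: dict = field(default_factory=dict)   # channel -> SegmentationParams
    bin_edges: tuple[float, ...] = morphometry.DEFAULT_BIN_EDGES
    zones: spatial_distribution.ZoneParams = spatial_distribution.ZoneParams()
    large_d_min_um: float = 4.0
    out_dir: str = "elysa_out"
    seed: int = 0
    save_volumes: bool = False
    voxel_size_um: tuple[float, float, float] | None = None   # override for files

    def __post_init__(self) -> None:
        if not self.cells:
            raise ConfigError("config lists no cells")
        if not self.reference:
            raise ConfigError("a reference channel is required")
        if self.reference in self.partners:
            raise ConfigError("reference channel cannot also be a partner")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ConfigError("cell ids must be unique")

    def params_for(self, channel: str) -> SegmentationParams:
        if channel in self.seg_params:
            return self.seg_params[channel]
        return self.seg_params.get("default", SegmentationParams())

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cells = tuple(CellInput(**c) for c in d.pop("cells"))
        zones = d.pop("zones", None)
        if isinstance(zones, dict):
            zones = spatial_distribution.ZoneParams(**zones)
        seg = {}
        for ch, p in d.pop("seg_params", {}).items():
            seg[ch] = p if isinstance(p, SegmentationParams) else SegmentationParams(**p)
        kwargs = dict(cells=cells, seg_params=seg)
        if zones is not None:
            kwargs["zones"] = zones
        for key in ("reference", "partners", "ratio_pair", "bin_edges",
                    "large_d_min_um", "out_dir", "seed", "save_volumes",
                    "voxel_size_um"):
            if key in d:
                v = d.pop(key)
                if key in ("partners", "bin_edges") and v is not None:
                    v = tuple(v)
                if key in ("ratio_pair", "voxel_size_um") and v is not None:
                    v = tuple(v)
                kwargs[key] = v
        if d:
            raise ConfigError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CellResult:
    cell_id: str
    group: str
    objects: pd.DataFrame
    distribution: morphometry.BinnedDistribution
    cell_center_um: tuple[float, float, float]
    coloc: dict                     # partner -> summary dict
    ratio_objects: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    cells: dict                     # cell_id -> CellResult
    summary: pd.DataFrame
    errors: list
    manifest: dict
    out_dir: Path


def _load_cell_stack(cell: CellInput, config: RunConfig):
    if cell.path is not None:
        stack = read_stack(cell.path, voxel_size_um=config.voxel_size_um)
        return stack, None
    seed = cell.seed
    if seed is None:
        import zlib

        seed = int((config.seed * 7919
                    + zlib.crc32(cell.cell_id.encode())) % 2 ** 31)
    spec = synthetic_scene.preset_stage_scene(cell.stage, seed, regime=cell.regime)
    stack, truth = synthetic_scene.render_scene(spec)
    return stack, truth


def _process_cell(cell: CellInput, config: RunConfig, out: Path):
    stack, _truth = _load_cell_stack(cell, config)
    if config.reference not in stack.channels:
        raise ConfigError(
            f"cell {cell.cell_id!r}: reference channel {config.reference!r} "
            f"not among {stack.channels}")
    ref_vol = stack.channel(config.reference)
    size = stack.voxel_size_um

    geometry = find_cell_geometry(ref_vol, size)
    ref_params = config.params_for(config.reference)
    ref_labels, ref_table, ref_bg = segment_stack(ref_vol, size, ref_params)
    log.info("cell %s: background %.1f, %d raw objects",
             cell.cell_id, ref_bg, len(ref_table))
    ref_table = filter_objects(ref_table, ref_params, geometry, size)
    ref_table = spatial_distribution.add_distal_columns(
        ref_table, geometry.center_um, config.zones)

    dist = morphometry.bin_by_diameter(ref_table, config.bin_edges)
    coloc_summaries = {}
    for partner in config.partners:
        if partner not in stack.channels:
            log.warning("cell %s: partner channel %r missing; skipped",
                        cell.cell_id, partner)
            continue
        p_params = config.params_for(partner)
        _, p_table, _ = colocalization.segment_partner(
            stack.channel(partner), size, p_params)
        p_table = filter_objects(p_table, p_params, geometry, size)
        res = colocalization.centers_in_objects(p_table, ref_labels, size)
        coloc_summaries[partner] = colocalization.double_positive_summary(
            res, ref_table, config.bin_edges)

    ratio_objects = None
    if config.ratio_pair is not None:
        ch_a, ch_b = config.ratio_pair
        if ch_a in stack.channels and ch_b in stack.channels:
            from .segmentation3d import auto_blank_regions
            from .stack_io import project
            from skimage.filters import threshold_otsu
            from .segmentation3d import label_components  # 2D via scipy below
            from scipy import ndimage as ndi

            regions2d = [r[1:] for r in auto_blank_regions(
                (stack.nz, stack.ny, stack.nx))]
            ratio = make_ratio_image(stack.channel(ch_a), stack.channel(ch_b),
                                     regions2d)
            proj_b = project(stack.channel(ch_b), mode="mean")
            mask2d = proj_b > threshold_otsu(np.minimum(
                proj_b, np.percentile(proj_b, 99.5)))
            labels2d, _ = ndi.label(mask2d)
            ratio_objects = per_object_ratio(ratio, labels2d)
        else:
            log.warning("cell %s: ratio channels %r missing; skipped",
                        cell.cell_id, config.ratio_pair)

    if config.save_volumes:
        write_label_volume(ref_labels, out / f"{cell.cell_id}_labels.tif")

    return CellResult(cell.cell_id, cell.group, ref_table, dist,
                      geometry.center_um, coloc_summaries, ratio_objects)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage for every cell and write CSV outputs + manifest.

    Deterministic given the config and seed.  Returns the in-memory results
    alongside the output paths; per-cell failures are collected in
    ``result.errors`` as ``(cell_id, stage, message)`` without aborting the
    remaining cells.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, CellResult] = {}
    errors: list[tuple[str, str, str]] = []
    written: list[Path] = []

    for cell in config.cells:
        try:
            res = _process_cell(cell, config, out)
        except Exception as exc:   # noqa: BLE001 - per-cell isolation
            stage_name = type(exc).__name__
            log.error("cell %s failed (%s): %s", cell.cell_id, stage_name, exc)
            errors.append((cell.cell_id, stage_name, str(exc)))
            continue
        results[cell.cell_id] = res

        obj_path = out / f"{cell.cell_id}_objects.csv"
        res.objects.to_csv(obj_path, index=False)
        written.append(obj_path)
        dist_path = out / f"{cell.cell_id}_distribution.csv"
        res.distribution.to_frame().to_csv(dist_path, index=False)
        written.append(dist_path)
        if res.ratio_objects is not None:
            rp = out / f"{cell.cell_id}_ratio_objects.csv"
            res.ratio_objects.to_csv(rp, index=False)
            written.append(rp)

    # per-cell summary table (the ANOVA unit is the cell)
    rows = []
    for cell in config.cells:
        if cell.cell_id not in results:
            continue
        res = results[cell.cell_id]
        t = res.objects
        n_peri, n_med, n_inter = spatial_distribution.zone_counts(
            t, config.large_d_min_um, config.zones)
        row = {
            "cell_id": cell.cell_id,
            "group": res.group,
            "n_objects": len(t),
            "total_volume_um3": float(t["volume_um3"].sum()) if len(t) else 0.0,
            "volume_fraction_gt3um": (morphometry.volume_fraction_above(t, 3.0)
                                      if len(t) else np.nan),
            f"n_peripheral_gt{config.large_d_min_um:g}um": n_peri,
            f"n_medial_gt{config.large_d_min_um:g}um": n_med,
            f"n_intermediate_gt{config.large_d_min_um:g}um": n_inter,
        }
        for partner, summ in res.coloc.items():
            row[f"dp_count_{partner}"] = summ["count"]
            row[f"dp_mean_diameter_{partner}"] = summ["mean_diameter_um"]
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)
    written.append(summary_path)

    manifest = {
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
        "n_cells": len(results),
        "errors": errors,
        "parameters": {
            "reference": config.reference,
            "partners": list(config.partners),
            "seed": config.seed,
            "zones": {"peripheral_min_um": config.zones.peripheral_min_um,
                      "medial_max_um": config.zones.medial_max_um},
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(results, summary, errors, manifest, out)
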