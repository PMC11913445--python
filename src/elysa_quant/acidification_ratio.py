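"""Ratiometric acidification imaging.

Acidotropic dye pairs (a pH-insensitive tracker over a pH-sensitive sensor,
or vice versa) report the relative acidification of endolysosomal
compartments.  The procedure implemented here mirrors the classical Fiji
workflow: average-project each channel over z, estimate each channel's
background as the mean of several cellular blank regions, subtract it
(clamping at zero), and divide channel A by channel B into a 32-bit float
ratio image.

Instead of letting near-zero denominators blow up, pixels whose corrected
denominator falls at or below a noise floor (default: three times the
blank-region standard deviation of channel B) are masked invalid and carry
no ratio value.  Per-structure statistics are then taken over valid pixels
only, and display uses a fixed "fire"-style lookup table with invalid
pixels rendered black.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation3d import blank_region_sd, estimate_background
from .stack_io import ImageStack, project


@dataclass
class RatioImage:
    """2D float ratio image with background bookkeeping and validity mask.

    ``values`` is defined (non-NaN) exactly where ``valid_mask`` is true,
    i.e. where the background-corrected denominator exceeds ``floor``.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    background_a: float
    background_b: float
    floor: float
    warning: str | None = None


def _as_projection(stack, mode="mean") -> np.ndarray:
    if isinstance(stack, ImageStack) or np.asarray(stack).ndim == 3:
        return np.asarray(project(stack, mode=mode), dtype=float)
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image or a 3D single-channel stack")
    return arr


def make_ratio_image(stack_a, stack_b, blank_regions,
                     floor: float | None = None) -> RatioImage:
    """Background-corrected A/B ratio image of two congruent channels.

    ``stack_a`` / ``stack_b`` may be 3D stacks (mean-projected internally,
    the standard 2D analysis) or pre-projected 2D images.  ``blank_regions``
    index the projection (tuples of slices placed outside the cell) and feed
    each channel's own background estimate.  ``floor`` defaults to three
    times the blank-region standard deviation of the projected denominator.
    An all-invalid result carries a warning instead of raising.
    """
    a = _as_projection(stack_a)
    b = _as_projection(stack_b)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    bg_a = estimate_background(a, blank_regions)
    bg_b = estimate_background(b, blank_regions)
    if floor is None:
        floor = 3.0 * blank_region_sd(b, blank_regions)
    ac = np.clip(a - bg_a, 0.0, None)
    bc = np.clip(b - bg_b, 0.0, None)
    valid = bc > floor
    values = np.full(a.shape, np.nan)
    np.divide(ac, bc, out=values, where=valid)
    warning = None
    if not valid.any():
        warning = "denominator never exceeds the floor; ratio image is empty"
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    return RatioImage(values, valid, float(bg_a), float(bg_b), float(floor),
                      warning)


def per_object_ratio(ratio: RatioImage, labels_2d: np.ndarray) -> pd.DataFrame:
    """Median and mean ratio per labelled 2D object, over valid pixels only.

    Objects without a single valid pixel are flagged (``valid`` False) and
    carry NaN statistics rather than a number.
    """
    labels_2d = np.asarray(labels_2d)
    if labels_2d.shape != ratio.values.shape:
        raise ValueError("label image and ratio image are not congruent")
    rows = []
    for lab in np.unique(labels_2d):
        if lab == 0:
            continue
        sel = (labels_2d == lab) & ratio.valid_mask
        vals = ratio.values[sel]
        rows.append({
            "label": int(lab),
            "n_valid_pixels": int(sel.sum()),
            "median_ratio": float(np.median(vals)) if vals.size else np.nan,
            "mean_ratio": float(vals.mean()) if vals.size else np.nan,
            "valid": vals.size > 0,
        })
    return pd.DataFrame(rows, columns=["label", "n_valid_pixels",
                                       "median_ratio", "mean_ratio", "valid"])


def line_profile(image: np.ndarray, p0_um, p1_um, n_samples: int,
                 pixel_size_um) -> pd.DataFrame:
    """Intensity profile along a straight line between two physical points.

    Samples ``n_samples`` evenly spaced positions from ``p0_um`` (distance
    0) to ``p1_um`` inclusive, with bilinear interpolation; pixel centers
    sit at ``(j + 0.5) * dy, (i + 0.5) * dx``.  Both endpoints must lie
    inside the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("line_profile expects a 2D image")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    p0 = np.asarray(p0_um, dtype=float)
    p1 = np.asarray(p1_um, dtype=float)
    size = np.asarray(pixel_size_um, dtype=float)      # (dy, dx)
    extent = np.asarray(image.shape) * size
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > extent):
            raise ValueError(f"endpoint {tuple(p)} outside image extent {tuple(extent)}")
    t = np.linspace(0.0, 1.0, n_samples)
    points = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    coords = (points / size) - 0.5                      # pixel-center frame
    vals = ndimage.map_coordinates(image, coords.T, order=1, mode="nearest")
    return pd.DataFrame({
        "distance_um": t * float(np.linalg.norm(p1 - p0)),
        "intensity": vals,
    })


# ---------------------------------------------------------------------------
# "fire" lookup table
# ---------------------------------------------------------------------------

# 32 control points of the classic "fire" color table (black -> violet ->
# red -> yellow -> white), linearly interpolated to 256 entries.
_FIRE_R = (0, 0, 1, 25, 49, 73, 98, 122, 146, 162, 173, 184, 195, 207, 217,
           229, 240, 252, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255,
           255, 255, 255, 255)
_FIRE_G = (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 14, 35, 57, 79, 101, 117,
           133, 147, 161, 175, 190, 205, 219, 234, 248, 255, 255, 255, 255)
_FIRE_B = (0, 61, 96, 130, 165, 192, 220, 227, 210, 181, 151, 122, 93, 64,
           35, 5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 98, 160, 223, 255)


def fire_lut() -> np.ndarray:
    """The 256x3 uint8 fire color table."""
    x = np.linspace(0, len(_FIRE_R) - 1, 256)
    xp = np.arange(len(_FIRE_R))
    lut = np.stack([np.interp(x, xp, _FIRE_R),
                    np.interp(x, xp, _FIRE_G),
                    np.interp(x, xp, _FIRE_B)], axis=1)
    return np.round(lut).astype(np.uint8)


def export_fire_lut(ratio: RatioImage, display_range) -> np.ndarray:
    """Render a ratio image through the fire LUT as an RGB uint8 array.

    ``display_range = (lo, hi)``: ``lo`` maps to the first LUT color, ``hi``
    to the last, values outside are clipped; invalid pixels are black.  The
    mapping is deterministic: identical input and range give identical
    bytes.
    """
    lo, hi = (float(v) for v in display_range)
    if not hi > lo:
        raise ValueError("display range must satisfy lo < hi")
    lut = fire_lut()
    scaled = np.clip((ratio.values - lo) / (hi - lo), 0.0, 1.0)
    idx = np.zeros(ratio.values.shape, dtype=int)
    np.multiply(scaled, 255, out=scaled, where=ratio.valid_mask)
    idx[ratio.valid_mask] = np.round(scaled[ratio.valid_mask]).astype(int)
    rgb = lut[idx]
    rgb[~ratio.valid_mask] = 0
    return rgb
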