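"""Reading, writing and projecting multi-channel confocal z-stacks.

The in-memory container is :class:`ImageStack`: a float/int voxel grid in
fixed internal axis order ``(z, c, y, x)`` plus physical voxel sizes in
micrometres, ordered ``(dz, dy, dx)``.  All downstream modules consume this
order only.

Coordinate convention (fixed across the package): voxel ``(k, j, i)`` has its
physical *center* at ``((k + 0.5) * dz, (j + 0.5) * dy, (i + 0.5) * dx)``.
Indices are 0-based.  Keeping physical coordinates at voxel centers makes
centroid arithmetic exact and brute-force testable.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile


class StackIOError(RuntimeError):
    """Raised for unreadable files, ambiguous axes or missing voxel sizes."""


@dataclass
class ImageStack:
    """Multi-channel 3D image with physical voxel sizes.

    Parameters
    ----------
    voxels:
        Array of shape ``(nz, nc, ny, nx)``.  Use :meth:`from_array` to
        normalise 2D/3D inputs.
    voxel_size_um:
        ``(dz, dy, dx)`` in micrometres, all positive.
    channels:
        Ordered channel names, one per channel axis entry.
    dtype_bits:
        Bit depth of the source data (bookkeeping only).
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channels: tuple[str, ...] = ("ch0",)
    dtype_bits: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("ImageStack.voxels must be (z, c, y, x); "
                             "use ImageStack.from_array to normalise")
        if len(self.voxel_size_um) != 3 or any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive reals (dz, dy, dx)")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.voxels.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.voxels.shape[1]} channels")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_array(cls, arr, voxel_size_um, channels=None, dtype_bits=16) -> "ImageStack":
        """Build a stack from a 2D ``(y, x)``, 3D ``(z, y, x)`` or 4D
        ``(z, c, y, x)`` array, inserting singleton axes as needed."""
        arr = np.asarray(arr)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        elif arr.ndim != 4:
            raise ValueError(f"cannot interpret {arr.ndim}-dimensional array as a stack")
        if channels is None:
            channels = tuple(f"ch{i}" for i in range(arr.shape[1]))
        return cls(arr, tuple(voxel_size_um), tuple(channels), dtype_bits)

    # -- basic geometry ----------------------------------------------------
    @property
    def nz(self) -> int:
        return self.voxels.shape[0]

    @property
    def nc(self) -> int:
        return self.voxels.shape[1]

    @property
    def ny(self) -> int:
        return self.voxels.shape[2]

    @property
    def nx(self) -> int:
        return self.voxels.shape[3]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid, ``(nz*dz, ny*dy, nx*dx)``."""
        dz, dy, dx = self.voxel_size_um
        return (self.nz * dz, self.ny * dy, self.nx * dx)

    def channel(self, name: str) -> np.ndarray:
        """3D ``(z, y, x)`` view of one named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None
        return self.voxels[:, idx]


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF I/O
# ---------------------------------------------------------------------------

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _voxel_size_from_ome(xml_text: str):
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    for px in root.iter():
        if px.tag.endswith("Pixels"):
            try:
                dz = float(px.attrib.get("PhysicalSizeZ", "nan"))
                dy = float(px.attrib.get("PhysicalSizeY", "nan"))
                dx = float(px.attrib.get("PhysicalSizeX", "nan"))
            except ValueError:
                return None
            if np.isnan(dy) or np.isnan(dx):
                return None
            if np.isnan(dz):
                dz = 1.0
            return (dz, dy, dx)
    return None


def _channel_names_from_ome(xml_text: str):
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    names = [ch.attrib.get("Name") for ch in root.iter() if ch.tag.endswith("Channel")]
    if names and all(n is not None for n in names):
        return tuple(names)
    return None


def read_stack(path, voxel_size_um=None, channels=None) -> ImageStack:
    """Read a single- or multi-page TIFF / OME-TIFF into internal order.

    Voxel size is taken from OME metadata unless ``voxel_size_um`` overrides
    it; a file with no voxel-size metadata and no override is an error.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.upper()
            ome = tf.ome_metadata
    except (OSError, ValueError, IndexError) as exc:
        raise StackIOError(f"cannot read TIFF stack {path!r}: {exc}") from exc

    # normalise axes to (z, c, y, x)
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if len(axes) != data.ndim or any(a not in "ZCYX" for a in axes):
        raise StackIOError(f"ambiguous TIFF axes {series.axes!r} in {path!r}")
    for missing in "ZC":
        if missing not in axes:
            data = data[None]
            axes = missing + axes
    order = [axes.index(a) for a in "ZCYX"]
    data = np.transpose(data, order)

    meta_size = _voxel_size_from_ome(ome) if ome else None
    size = tuple(voxel_size_um) if voxel_size_um is not None else meta_size
    if size is None:
        raise StackIOError(
            f"{path!r} carries no voxel-size metadata; pass voxel_size_um explicitly")

    if channels is None:
        meta_names = _channel_names_from_ome(ome) if ome else None
        if meta_names is not None and len(meta_names) == data.shape[1]:
            channels = meta_names
        else:
            channels = tuple(f"ch{i}" for i in range(data.shape[1]))
    bits = data.dtype.itemsize * 8
    return ImageStack(data, size, tuple(channels), dtype_bits=bits)


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with voxel size and channel
    names in the metadata.  Round-trips voxel-identically through
    :func:`read_stack` for integer and float data."""
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        stack.voxels,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channels)},
        },
    )


def write_label_volume(labels: np.ndarray, path) -> None:
    """Write an integer label volume as an (up to) 16-bit label TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) < 2 ** 16:
        labels = labels.astype(np.uint16)
    else:
        labels = labels.astype(np.uint32)
    tifffile.imwrite(path, labels)


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

def project(stack, mode: str = "max", z_range=None) -> np.ndarray:
    """Project a stack along z.

    Parameters
    ----------
    stack:
        :class:`ImageStack` or a bare 3D ``(z, y, x)`` array.
    mode:
        ``"max"`` (per-pixel maximum intensity, as in whole-cell overview
        figures) or ``"mean"`` (averaged intensity, used for ratio imaging).
    z_range:
        Optional ``(z0, z1)`` half-open plane range; default all planes.

    Returns
    -------
    ``(y, x)`` for single-channel input, ``(c, y, x)`` for multi-channel.
    """
    if isinstance(stack, ImageStack):
        data = stack.voxels
        multi = data.shape[1] > 1
    else:
        data = np.asarray(stack)
        if data.ndim == 3:
            data = data[:, None]
            multi = False
        elif data.ndim == 4:
            multi = data.shape[1] > 1
        else:
            raise ValueError("project expects a 3D or 4D array or an ImageStack")

    nz = data.shape[0]
    if z_range is None:
        z0, z1 = 0, nz
    else:
        z0, z1 = z_range
        if not (0 <= z0 < z1 <= nz):
            raise ValueError(f"empty or out-of-range z_range {z_range!r} for {nz} planes")
    sel = data[z0:z1]
    if mode == "max":
        out = sel.max(axis=0)
    elif mode == "mean":
        out = sel.mean(axis=0)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return out if multi else out[0]


def save_png(image: np.ndarray, path, vmin=None, vmax=None) -> None:
    """Export a 2D image (grayscale) or RGB array as 8-bit PNG."""
    import imageio.v3 as iio

    image = np.asarray(image)
    if image.dtype == np.uint8:
        iio.imwrite(path, image)
        return
    lo = float(image.min() if vmin is None else vmin)
    hi = float(image.max() if vmax is None else vmax)
    span = hi - lo if hi > lo else 1.0
    scaled = np.clip((image.astype(float) - lo) / span, 0, 1)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
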