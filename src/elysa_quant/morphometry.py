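"""Equivalent-sphere diameter morphometry and per-cell size distributions.

Each segmented object's size is expressed as the diameter of the sphere with
the same volume,

    d = (6 V / pi) ** (1/3),

the standard way of reporting organelle sizes when shapes range from spheres
to concatenated-sphere chains.  Objects are binned by equivalent diameter on
one fine canonical partition (default edges 0.2, 0.4, 0.6, 0.8, 1, 2, ..., 10
micrometres); the coarse verbal size classes used in the literature
(0.2-0.8, 3-7, 5-7, 9-10 um, ...) are sums of these fine bins, so one
partition serves every view.

Bin rule: half-open ``[lo, hi)`` with the last bin closed ``[lo, hi]``.
Objects outside the edge range are counted separately, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical fine bin edges in micrometres.
DEFAULT_BIN_EDGES: tuple[float, ...] = (
    0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)


def equivalent_diameter(volume_um3):
    """Diameter of the sphere with the given volume, ``(6 V / pi) ** (1/3)``.

    Accepts scalars or arrays; every volume must be strictly positive.
    """
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("equivalent_diameter requires volume > 0")
    d = np.cbrt(6.0 * v / np.pi)
    return float(d) if np.isscalar(volume_um3) else d


def sphere_volume(diameter_um):
    """Inverse of :func:`equivalent_diameter`: ``pi/6 * d**3``."""
    d = np.asarray(diameter_um, dtype=float)
    v = np.pi / 6.0 * d ** 3
    return float(v) if np.isscalar(diameter_um) else v


@dataclass
class BinnedDistribution:
    """Per-cell object counts and summed volumes binned by equivalent diameter.

    ``counts[i]`` / ``volumes_um3[i]`` cover diameters in
    ``[bin_edges_um[i], bin_edges_um[i+1])`` (last bin closed).  Objects with
    diameters outside the edge range are tallied in ``n_below`` / ``n_above``
    (and ``volume_below`` / ``volume_above``).
    """

    bin_edges_um: tuple[float, ...]
    counts: np.ndarray
    volumes_um3: np.ndarray
    n_below: int = 0
    n_above: int = 0
    volume_below: float = 0.0
    volume_above: float = 0.0

    def __post_init__(self) -> None:
        self.bin_edges_um = tuple(float(e) for e in self.bin_edges_um)
        if len(self.counts) != len(self.bin_edges_um) - 1:
            raise ValueError("len(counts) must equal len(edges) - 1")

    @property
    def total_count(self) -> int:
        return int(self.counts.sum()) + self.n_below + self.n_above

    def to_frame(self) -> pd.DataFrame:
        e = self.bin_edges_um
        return pd.DataFrame({
            "bin_lo_um": e[:-1],
            "bin_hi_um": e[1:],
            "count": self.counts,
            "volume_um3": self.volumes_um3,
        })


def _bin_index(diameters: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per diameter; -1 below range, ``nbins`` above range.
    ``[lo, hi)`` everywhere, last bin closed at the top edge."""
    idx = np.searchsorted(edges, diameters, side="right") - 1
    idx[diameters == edges[-1]] = len(edges) - 2     # closed last bin
    idx[diameters < edges[0]] = -1
    idx[diameters > edges[-1]] = len(edges) - 1
    return idx


def bin_by_diameter(table: pd.DataFrame, edges=DEFAULT_BIN_EDGES) -> BinnedDistribution:
    """Bin an object table by its ``equivalent_diameter_um`` column.

    Every object lands in exactly one fine bin, or in the explicit
    below/above-range tallies; the partition property
    ``sum(counts) + n_below + n_above == len(table)`` always holds.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    nbins = len(edges) - 1
    if len(table) == 0:
        return BinnedDistribution(tuple(edges), np.zeros(nbins, int),
                                  np.zeros(nbins, float))
    d = table["equivalent_diameter_um"].to_numpy(dtype=float)
    v = table["volume_um3"].to_numpy(dtype=float)
    idx = _bin_index(d, edges)
    below = idx < 0
    above = idx >= nbins
    inside = ~(below | above)
    counts = np.bincount(idx[inside], minlength=nbins).astype(int)
    volumes = np.bincount(idx[inside], weights=v[inside], minlength=nbins)
    return BinnedDistribution(
        tuple(edges), counts, volumes,
        n_below=int(below.sum()), n_above=int(above.sum()),
        volume_below=float(v[below].sum()), volume_above=float(v[above].sum()))


@dataclass
class BinRatio:
    """Per-bin ratio of two distributions over identical edges.

    ``undefined[i]`` marks 0/0 bins (ratio is NaN there, but explicitly
    flagged rather than silent); a positive numerator over a zero denominator
    yields ``+inf``.
    """

    bin_edges_um: tuple[float, ...]
    ratio: np.ndarray
    undefined: np.ndarray


def stage_ratio(dist_num: BinnedDistribution, dist_den: BinnedDistribution) -> BinRatio:
    """Per-bin count ratio (e.g. MII/GV) of two binned distributions.

    Both distributions must share identical edges.  The inputs may hold
    per-group *mean* counts (floats) as well as raw counts.
    """
    if tuple(dist_num.bin_edges_um) != tuple(dist_den.bin_edges_um):
        raise ValueError("stage_ratio requires identical bin edges")
    num = np.asarray(dist_num.counts, dtype=float)
    den = np.asarray(dist_den.counts, dtype=float)
    undefined = (num == 0) & (den == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio[undefined] = np.nan
    ratio[(den == 0) & (num > 0)] = np.inf
    return BinRatio(tuple(dist_num.bin_edges_um), ratio, undefined)


def volume_fraction_above(table: pd.DataFrame, d_min_um: float) -> float:
    """Fraction of total object volume carried by objects with equivalent
    diameter strictly greater than ``d_min_um`` (in ``[0, 1]``)."""
    if len(table) == 0:
        raise ValueError("volume_fraction_above requires a nonempty table")
    d = table["equivalent_diameter_um"].to_numpy(dtype=float)
    v = table["volume_um3"].to_numpy(dtype=float)
    return float(v[d > d_min_um].sum() / v.sum())


def intensity_per_volume(table: pd.DataFrame, edges=DEFAULT_BIN_EDGES):
    """Integrated intensity per unit volume, per object and per size class.

    Returns ``(per_object, per_bin)`` where ``per_object`` is a Series
    aligned with the table and ``per_bin`` a DataFrame of bin edges and the
    mean intensity/volume of objects in each diameter class (NaN for empty
    bins)."""
    if np.any(table["volume_um3"].to_numpy() <= 0):
        raise ValueError("zero or negative object volume")
    per_object = table["integrated_intensity"] / table["volume_um3"]
    per_object.name = "intensity_per_um3"

    edges = np.asarray(edges, dtype=float)
    nbins = len(edges) - 1
    means = np.full(nbins, np.nan)
    if len(table):
        d = table["equivalent_diameter_um"].to_numpy(dtype=float)
        idx = _bin_index(d, edges)
        vals = per_object.to_numpy(dtype=float)
        inside = (idx >= 0) & (idx < nbins)
        n = np.bincount(idx[inside], minlength=nbins)
        s = np.bincount(idx[inside], weights=vals[inside], minlength=nbins)
        np.divide(s, n, out=means, where=n > 0)
    per_bin = pd.DataFrame({
        "bin_lo_um": edges[:-1], "bin_hi_um": edges[1:],
        "mean_intensity_per_um3": means,
    })
    return per_object, per_bin
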