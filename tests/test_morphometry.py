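import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elysa_quant.morphometry import (DEFAULT_BIN_EDGES, bin_by_diameter,
                                     equivalent_diameter, intensity_per_volume,
                                     sphere_volume, stage_ratio,
                                     volume_fraction_above)


def table_from_diameters(diameters, intensity_per_um3=100.0):
    d = np.asarray(diameters, dtype=float)
    v = sphere_volume(d)
    return pd.DataFrame({
        "label": np.arange(1, len(d) + 1),
        "volume_um3": v,
        "equivalent_diameter_um": d,
        "integrated_intensity": intensity_per_um3 * v,
    })


def test_unit_sphere_and_closed_form():
    assert equivalent_diameter(np.pi / 6) == pytest.approx(1.0, abs=1e-12)
    assert equivalent_diameter(113.0973) == pytest.approx(6.0, abs=1e-4)
    with pytest.raises(ValueError):
        equivalent_diameter(0.0)


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=0.05, max_value=50.0))
def test_diameter_volume_round_trip(d):
    assert equivalent_diameter(sphere_volume(d)) == pytest.approx(d, abs=1e-9)


def test_diameter_is_strictly_increasing_in_volume():
    v = np.linspace(0.01, 500, 200)
    d = equivalent_diameter(v)
    assert np.all(np.diff(d) > 0)


def test_binning_default_edges():
    dist = bin_by_diameter(table_from_diameters([0.3, 0.5, 6.5]))
    edges = np.asarray(DEFAULT_BIN_EDGES)
    assert dist.counts[0] == 1          # [0.2, 0.4)
    assert dist.counts[1] == 1          # [0.4, 0.6)
    assert dist.counts[list(edges).index(6.0)] == 1   # [6, 7)
    assert dist.total_count == 3


def test_binning_boundaries_and_out_of_range():
    dist = bin_by_diameter(table_from_diameters([0.1, 0.2, 10.0, 11.0]))
    assert dist.n_below == 1            # 0.1 < first edge
    assert dist.counts[0] == 1          # 0.2 lands in its half-open bin
    assert dist.counts[-1] == 1         # last bin is closed: 10.0 included
    assert dist.n_above == 1            # 11.0 reported, not dropped


def test_empty_table_gives_all_zero_bins():
    dist = bin_by_diameter(table_from_diameters([]))
    assert dist.counts.sum() == 0 and dist.total_count == 0


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(min_value=0.01, max_value=15.0), max_size=40))
def test_binning_is_a_partition(diams):
    dist = bin_by_diameter(table_from_diameters(diams))
    assert dist.total_count == len(diams)


def test_stage_ratio_values_and_flags():
    a = bin_by_diameter(table_from_diameters([0.3, 0.3, 0.5, 0.5, 6.5, 6.5]))
    b = bin_by_diameter(table_from_diameters([0.3, 0.5, 6.5]))
    r = stage_ratio(a, b)
    defined = ~r.undefined
    assert np.all(r.ratio[defined & np.isfinite(r.ratio)] == 2.0)

    same = stage_ratio(b, b)
    assert np.all(same.ratio[~same.undefined] == 1.0)
    assert same.undefined.sum() == len(DEFAULT_BIN_EDGES) - 1 - 3

    num = bin_by_diameter(table_from_diameters([0.3]))
    den = bin_by_diameter(table_from_diameters([6.5]))
    r2 = stage_ratio(num, den)
    assert np.isposinf(r2.ratio[0])          # 1/0
    assert r2.undefined[2]                    # 0/0 flagged, not silent


def test_stage_ratio_requires_identical_edges():
    a = bin_by_diameter(table_from_diameters([1.0]))
    b = bin_by_diameter(table_from_diameters([1.0]), edges=(0.2, 1.0, 10.0))
    with pytest.raises(ValueError, match="edges"):
        stage_ratio(a, b)


def test_volume_fraction_above():
    t = pd.DataFrame({"volume_um3": [10.0, 10.0, 80.0],
                      "equivalent_diameter_um": [1.0, 1.0, 5.0]})
    assert volume_fraction_above(t, 3.0) == pytest.approx(0.8)
    assert volume_fraction_above(t, 0.0) == 1.0
    # non-increasing in the cutoff
    fr = [volume_fraction_above(t, d) for d in (0.0, 0.5, 1.0, 3.0, 6.0)]
    assert all(a >= b for a, b in zip(fr, fr[1:]))
    with pytest.raises(ValueError):
        volume_fraction_above(t.iloc[:0], 1.0)


def test_volume_fraction_matches_truth_when_objects_are_resolved(tmp_path):
    """Pipeline volume fraction tracks generator truth within 0.05 when every
    object is larger than the PSF (sub-resolution puncta are excluded from
    this contract: thresholding a blurred diffraction-limited spot inflates
    its apparent volume, in synthetic and real confocal data alike)."""
    from test_pipeline import noiseless_five_phantom_scene
    from elysa_quant.synthetic_scene import render_scene
    from elysa_quant.segmentation3d import (SegmentationParams, label_components,
                                            measure_objects)

    stack, truth = render_scene(noiseless_five_phantom_scene())
    labels = label_components(stack.channel("LAMP1") > 800.0, 26)
    table = measure_objects(labels, stack.channel("LAMP1"),
                            stack.voxel_size_um)
    got = volume_fraction_above(table, 3.5)
    want = volume_fraction_above(truth.table, 3.5)
    assert got == pytest.approx(want, abs=0.05)


def test_giant_assemblies_dominate_mii_volume(mii_scene, mii_segmentation):
    """In the MII-like scene, structures > 3 um carry more than half of the
    measured LAMP1-positive volume, as in the mature oocyte."""
    _, _, truth = mii_scene
    measured = mii_segmentation["table"]
    assert volume_fraction_above(measured, 3.0) > 0.5
    assert volume_fraction_above(truth.table, 3.0) > 0.5


def test_intensity_per_volume_linearity():
    t = table_from_diameters([2.0, 4.0], intensity_per_um3=250.0)
    per_obj, per_bin = intensity_per_volume(t)
    assert np.allclose(per_obj, 250.0)
    t2 = t.assign(integrated_intensity=t["integrated_intensity"] * 2)
    per_obj2, _ = intensity_per_volume(t2)
    assert np.allclose(per_obj2, 2 * per_obj)
    assert per_bin["mean_intensity_per_um3"].dropna().tolist() == pytest.approx(
        [250.0, 250.0])


def test_intensity_per_volume_recovers_programmed_intensity():
    """In the unblurred limit, each object's intensity/volume statistic
    recovers its programmed per-voxel photon count within 1%."""
    from test_pipeline import noiseless_five_phantom_scene
    from elysa_quant.synthetic_scene import render_scene
    from elysa_quant.segmentation3d import label_components, measure_objects

    stack, _ = render_scene(noiseless_five_phantom_scene())
    vol = stack.channel("LAMP1")
    size = stack.voxel_size_um
    labels = label_components(vol > 800.0, 26)
    table = measure_objects(labels, vol, size)
    per_obj, _ = intensity_per_volume(table)
    programmed = 2000.0 / float(np.prod(size))      # counts per um^3
    assert np.all(np.abs(per_obj / programmed - 1.0) < 0.01)
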