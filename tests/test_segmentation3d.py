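import numpy as np
import pandas as pd
import pytest

from flood_oracle import flood_fill_components, label_partition

from elysa_quant.segmentation3d import (CellGeometry, SegmentationError,
                                        SegmentationParams,
                                        estimate_background, filter_objects,
                                        find_cell_geometry, label_components,
                                        measure_objects, threshold_stack)
from elysa_quant.synthetic_scene import (PhantomSpec, SceneSpec,
                                         rasterize_phantom, render_scene)


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def test_background_is_mean_of_region_means():
    img = np.zeros((4, 40, 40))
    vals = (10.0, 12.0, 14.0, 16.0)
    regions = []
    for i, v in enumerate(vals):
        sl = (slice(None), slice(0, 4), slice(i * 8, i * 8 + 4))
        img[sl] = v
        regions.append(sl)
    assert estimate_background(img, regions) == pytest.approx(13.0)
    assert estimate_background(np.full((5, 5), 5.0),
                               [(slice(0, 3), slice(0, 3))]) == 5.0
    with pytest.raises(ValueError, match="region"):
        estimate_background(img, [])


def test_background_estimate_on_poisson_field_is_unbiased():
    rng = np.random.default_rng(4)
    img = rng.poisson(10.0, size=(20, 64, 64)).astype(float)
    regions = [(slice(None), slice(0, 16), slice(0, 16)),
               (slice(None), slice(0, 16), slice(48, 64)),
               (slice(None), slice(48, 64), slice(0, 16)),
               (slice(None), slice(48, 64), slice(48, 64))]
    n = 4 * 20 * 16 * 16
    se = np.sqrt(10.0 / n)
    assert abs(estimate_background(img, regions) - 10.0) < 3 * se


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def test_threshold_is_strict_and_monotone():
    const = np.full((3, 3, 3), 600.0)
    assert not threshold_stack(const, 600.0).any()

    rng = np.random.default_rng(7)
    stack = rng.uniform(0, 2000, size=(10, 10, 10))
    lo = threshold_stack(stack, 600.0)
    hi = threshold_stack(stack, 1200.0)
    assert np.all(lo[hi])          # mask(1200) is a subset of mask(600)
    with pytest.raises(ValueError):
        threshold_stack(stack, 0.0)


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def test_single_voxel_and_corner_adjacency():
    vol = np.zeros((3, 3, 3), bool)
    vol[1, 1, 1] = True
    lab = label_components(vol, 26)
    assert lab.max() == 1 and (lab > 0).sum() == 1

    corner = np.zeros((2, 2, 2), bool)
    corner[0, 0, 0] = corner[1, 1, 1] = True
    assert label_components(corner, 26).max() == 1
    assert label_components(corner, 6).max() == 2


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_labeling_matches_flood_fill_on_random_volumes(connectivity):
    rng = np.random.default_rng(100 + connectivity)
    for _ in range(10):
        vol = rng.random((20, 20, 20)) < 0.2
        labels = label_components(vol, connectivity)
        assert label_partition(labels) == flood_fill_components(vol, connectivity)


def test_labels_are_contiguous_and_raster_ordered():
    vol = np.zeros((1, 1, 9), bool)
    vol[0, 0, [0, 4, 8]] = True
    lab = label_components(vol, 6)
    assert lab[0, 0, 0] == 1 and lab[0, 0, 4] == 2 and lab[0, 0, 8] == 3


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def test_cube_volume_and_centroid_convention():
    labels = np.zeros((5, 5, 5), int)
    labels[1:4, 1:4, 1:4] = 1
    table = measure_objects(labels, np.ones((5, 5, 5)), (1.0, 0.4, 0.4))
    row = table.iloc[0]
    assert row["volume_um3"] == pytest.approx(27 * 0.16)
    assert row["mean_intensity"] == 1.0

    one = np.zeros((2, 2, 2), int)
    one[0, 0, 0] = 1
    t = measure_objects(one, np.ones((2, 2, 2)), (1, 1, 1))
    assert tuple(t.iloc[0][["centroid_z_um", "centroid_y_um",
                            "centroid_x_um"]]) == (0.5, 0.5, 0.5)
    assert t.iloc[0]["mean_surface_distance_um"] == 0.0


def test_digitized_sphere_volume_within_two_percent():
    scene = SceneSpec(grid_shape=(40, 40, 40), voxel_size_um=(0.2,) * 3,
                      cell_diameter_um=7.0, psf_sigma_um=(0, 0, 0))
    mask = rasterize_phantom(PhantomSpec(id=1, diameter_um=6.0), scene)
    table = measure_objects(mask.astype(int), np.ones(mask.shape), (0.2,) * 3)
    assert table.iloc[0]["volume_um3"] == pytest.approx(113.097, rel=0.02)
    assert table.iloc[0]["equivalent_diameter_um"] == pytest.approx(6.0, rel=0.01)


def test_measure_rejects_shape_mismatch():
    with pytest.raises(ValueError, match="congruent"):
        measure_objects(np.zeros((2, 2, 2), int), np.zeros((2, 2, 3)), (1, 1, 1))


def test_object_count_and_volume_monotone_in_threshold(mii_scene):
    _, stack, _ = mii_scene
    vol = stack.channel("LAMP1")
    size = stack.voxel_size_um
    prev_n, prev_v = np.inf, np.inf
    for thr in (700.0, 1000.0, 1500.0):
        labels = label_components(threshold_stack(vol, thr), 26)
        table = measure_objects(labels, vol, size)
        assert table["volume_um3"].sum() <= prev_v
        assert len(table) <= prev_n
        prev_v = table["volume_um3"].sum()
        prev_n = len(table)


def test_volume_conservation(mii_segmentation):
    labels = mii_segmentation["labels"]
    size = mii_segmentation["voxel_size"]
    table = measure_objects(labels, np.zeros(labels.shape), size)
    assert table["volume_um3"].sum() == pytest.approx(
        (labels > 0).sum() * np.prod(size))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _table_with_volumes(volumes):
    return pd.DataFrame({
        "label": np.arange(1, len(volumes) + 1),
        "volume_um3": volumes,
        "centroid_z_um": np.ones(len(volumes)),
        "centroid_y_um": np.ones(len(volumes)),
        "centroid_x_um": np.ones(len(volumes)),
    })


def test_volume_filter_window_and_identity():
    table = _table_with_volumes([0.1, 4999.0, 5001.0])
    params = SegmentationParams(threshold=1, volume_filter_um3=(0, 5000))
    kept = filter_objects(table, params)
    assert kept["volume_um3"].tolist() == [0.1, 4999.0]
    everything = SegmentationParams(threshold=1, volume_filter_um3=(0, np.inf))
    assert len(filter_objects(table, everything)) == 3


def test_boundary_exclusion_drops_membrane_hugging_objects():
    # disc mask of radius 10 um (20 px at 0.5 um), fully inside the field;
    # one object 1 um from the rim, one at the center
    yy, xx = np.mgrid[:50, :50]
    mask = (yy - 25) ** 2 + (xx - 25) ** 2 <= 20 ** 2
    geom = CellGeometry(center_plane_z=0, cell_mask=mask,
                        center_um=(0.5, 12.5, 12.5))
    table = pd.DataFrame({
        "label": [1, 2],
        "volume_um3": [5.0, 5.0],
        "centroid_z_um": [0.5, 0.5],
        "centroid_y_um": [12.5, 12.5],
        "centroid_x_um": [21.5, 12.5],      # 1 um from rim vs center
    })
    on = SegmentationParams(threshold=1, boundary_exclusion_um=2.0)
    off = SegmentationParams(threshold=1, boundary_exclusion_um=0.0)
    assert filter_objects(table, on, geom, (1, 0.5, 0.5))["label"].tolist() == [2]
    assert len(filter_objects(table, off, geom, (1, 0.5, 0.5))) == 2


# ---------------------------------------------------------------------------
# cell geometry
# ---------------------------------------------------------------------------

def test_center_plane_is_midpoint_of_signal_extent():
    vol = np.zeros((81, 40, 40))
    vol[10:71, 10:30, 10:30] = 100.0
    geom = find_cell_geometry(vol, (1.0, 1.0, 1.0))
    assert geom.center_plane_z == 40


def test_spherical_cell_center_recovered_within_one_voxel():
    scene = SceneSpec(grid_shape=(41, 96, 96), voxel_size_um=(2.0, 1.0, 1.0),
                      cell_diameter_um=75.0, channels=("ch0",),
                      cytosol_counts={"ch0": 100.0}, background_counts=20.0,
                      psf_sigma_um=(0, 0, 0), read_noise_sd=0.0, seed=9)
    stack, _ = render_scene(scene)
    geom = find_cell_geometry(stack.channel("ch0"), scene.voxel_size_um)
    true = scene.cell_center_um
    for got, want, step in zip(geom.center_um, true, scene.voxel_size_um):
        assert abs(got - want) <= step


def test_stack_without_signal_is_an_error():
    with pytest.raises(SegmentationError):
        find_cell_geometry(np.zeros((10, 10, 10)), (1, 1, 1))


def test_count_recovery_on_noiseless_nontouching_phantoms():
    phantoms = tuple(
        PhantomSpec(id=i + 1, diameter_um=d, center_offset_um=off,
                    channel_intensities={"ch0": 2000.0})
        for i, (d, off) in enumerate([
            (3.0, (0, 0, 0)), (2.0, (0, 8, 0)), (4.0, (0, -8, 0)),
            (2.5, (0, 0, 8)), (1.5, (6, 0, -8))]))
    scene = SceneSpec(grid_shape=(24, 48, 48), voxel_size_um=(1.0, 0.5, 0.5),
                      cell_diameter_um=23.0, channels=("ch0",),
                      phantoms=phantoms, psf_sigma_um=(0, 0, 0),
                      background_counts=0.0, read_noise_sd=0.0, seed=0)
    stack, truth = render_scene(scene)
    labels = label_components(stack.channel("ch0") > 1000.0, 26)
    assert labels.max() == len(phantoms) == len(truth.table)
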