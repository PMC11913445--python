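import numpy as np
import pytest

from elysa_quant.acidification_ratio import (export_fire_lut, fire_lut,
                                             line_profile, make_ratio_image,
                                             per_object_ratio)
from elysa_quant.synthetic_scene import PhantomSpec, SceneSpec, render_scene

CORNERS_2D = [(slice(0, 8), slice(0, 8)), (slice(0, 8), slice(-8, None)),
              (slice(-8, None), slice(0, 8)), (slice(-8, None), slice(-8, None))]


def ratio_phantom_scene(seed=0, ratios=(0.5, 1.0, 3.0), base=3000.0):
    """Two acidity channels; each structure's tracker/sensor ratio is
    programmed via its channel intensities."""
    offsets = [(0.0, 0.0, 22.0), (0.0, 19.0, -11.0), (0.0, -19.0, -11.0)]
    phantoms = tuple(
        PhantomSpec(id=i + 1, diameter_um=8.0, center_offset_um=offsets[i],
                    channel_intensities={"LysoTracker": r * base,
                                         "LysoSensor": base})
        for i, r in enumerate(ratios))
    return SceneSpec(grid_shape=(41, 128, 128), voxel_size_um=(2.0, 0.7, 0.7),
                     cell_diameter_um=75.0,
                     channels=("LysoTracker", "LysoSensor"),
                     phantoms=phantoms, psf_sigma_um=(2.0, 0.7, 0.7),
                     background_counts=20.0, read_noise_sd=2.0, seed=seed)


def truth_labels_2d(truth):
    lab2d = np.zeros(truth.label_volume.shape[1:], int)
    for pid in np.unique(truth.label_volume):
        if pid:
            lab2d[np.any(truth.label_volume == pid, axis=0)] = pid
    return lab2d


def test_uniform_channels_give_constant_ratio():
    # zero-background pair: blank corners empty, uniform signal elsewhere
    a = np.full((40, 40), 200.0)
    b = np.full((40, 40), 100.0)
    a[:4, :4] = b[:4, :4] = 0.0
    r = make_ratio_image(a, b, [(slice(0, 4), slice(0, 4))], floor=1.0)
    assert r.valid_mask.sum() == 40 * 40 - 16
    assert np.allclose(r.values[r.valid_mask], 2.0)


def test_background_subtraction_recovers_unit_ratio():
    a = np.full((30, 30), 50.0)
    b = np.full((30, 30), 20.0)
    a[10:20, 10:20] += 100.0      # signal 100 over background 50
    b[10:20, 10:20] += 100.0      # signal 100 over background 20
    regions = [(slice(0, 5), slice(0, 5)), (slice(0, 5), slice(25, 30))]
    r = make_ratio_image(a, b, regions, floor=1.0)
    assert np.allclose(r.values[10:20, 10:20], 1.0)
    assert r.background_a == 50.0 and r.background_b == 20.0


def test_all_invalid_result_warns_instead_of_crashing():
    a = np.full((10, 10), 5.0)
    b = np.full((10, 10), 5.0)
    with pytest.warns(RuntimeWarning, match="floor"):
        r = make_ratio_image(a, b, [(slice(0, 3), slice(0, 3))], floor=1e6)
    assert not r.valid_mask.any() and r.warning is not None


def test_programmed_structure_ratios_recovered_under_noise():
    scene = ratio_phantom_scene(seed=21)
    stack, truth = render_scene(scene)
    r = make_ratio_image(stack.channel("LysoTracker"),
                         stack.channel("LysoSensor"), CORNERS_2D)
    table = per_object_ratio(r, truth_labels_2d(truth))
    got = dict(zip(table["label"], table["median_ratio"]))
    for pid, want in zip((1, 2, 3), (0.5, 1.0, 3.0)):
        assert got[pid] == pytest.approx(want, rel=0.05)


def test_swapping_channels_inverts_valid_ratios():
    scene = ratio_phantom_scene(seed=22)
    stack, _ = render_scene(scene)
    a = stack.channel("LysoTracker")
    b = stack.channel("LysoSensor")
    fwd = make_ratio_image(a, b, CORNERS_2D)
    rev = make_ratio_image(b, a, CORNERS_2D)
    both = fwd.valid_mask & rev.valid_mask & (fwd.values > 0)
    assert both.sum() > 100
    assert np.allclose(fwd.values[both] * rev.values[both], 1.0, rtol=1e-6)


def test_scale_equivariance_of_ratio_without_background():
    # with zero background the A -> c*A map scales every valid ratio by c
    rng = np.random.default_rng(23)
    a = rng.uniform(0, 500, size=(40, 40))
    b = rng.uniform(1, 300, size=(40, 40))
    a[:6, :6] = b[:6, :6] = 0.0
    regions = [(slice(0, 6), slice(0, 6))]
    r1 = make_ratio_image(a, b, regions, floor=5.0)
    r3 = make_ratio_image(3.0 * a, b, regions, floor=5.0)
    assert np.array_equal(r1.valid_mask, r3.valid_mask)
    both = r1.valid_mask
    assert np.allclose(r3.values[both], 3.0 * r1.values[both], rtol=1e-9)


def test_object_with_no_valid_pixels_is_flagged():
    vals = np.full((10, 10), 2.0)
    valid = np.zeros((10, 10), bool)
    valid[:5] = True
    from elysa_quant.acidification_ratio import RatioImage

    r = RatioImage(np.where(valid, vals, np.nan), valid, 0.0, 0.0, 1.0)
    labels = np.zeros((10, 10), int)
    labels[:5, :5] = 1       # fully valid
    labels[7:, 7:] = 2       # fully invalid
    table = per_object_ratio(r, labels).set_index("label")
    assert table.loc[1, "valid"] and table.loc[1, "median_ratio"] == 2.0
    assert not table.loc[2, "valid"] and np.isnan(table.loc[2, "median_ratio"])


def test_line_profile_constant_ramp_and_peak():
    const = np.full((20, 20), 4.0)
    prof = line_profile(const, (2.0, 2.0), (18.0, 18.0), 25, (1.0, 1.0))
    assert np.allclose(prof["intensity"], 4.0)
    assert prof["distance_um"].iloc[0] == 0.0
    assert prof["distance_um"].iloc[-1] == pytest.approx(np.hypot(16, 16))

    ramp = np.tile(np.arange(30, dtype=float), (5, 1))
    p = line_profile(ramp, (2.5, 0.5), (2.5, 29.5), 30, (1.0, 1.0))
    assert np.allclose(np.diff(p["intensity"]), np.diff(p["intensity"])[0],
                       atol=1e-9)

    yy, xx = np.mgrid[:41, :41]
    blob = np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / 30.0)
    prof = line_profile(blob, (20.5, 0.5), (20.5, 40.5), 41, (1.0, 1.0))
    assert abs(int(prof["intensity"].idxmax()) - 20) <= 1


def test_line_profile_rejects_outside_endpoints():
    with pytest.raises(ValueError, match="outside"):
        line_profile(np.zeros((5, 5)), (0.0, 0.0), (9.0, 1.0), 5, (1.0, 1.0))


def test_fire_lut_mapping_is_deterministic_with_black_invalid():
    from elysa_quant.acidification_ratio import RatioImage

    vals = np.array([[0.0, 1.0], [2.0, np.nan]])
    valid = np.array([[True, True], [True, False]])
    r = RatioImage(vals, valid, 0.0, 0.0, 0.5)
    rgb = export_fire_lut(r, (0.0, 2.0))
    lut = fire_lut()
    assert np.array_equal(rgb[0, 0], lut[0])        # range min -> first color
    assert np.array_equal(rgb[1, 0], lut[255])      # range max -> last color
    assert np.array_equal(rgb[1, 1], (0, 0, 0))     # invalid -> black
    rgb2 = export_fire_lut(r, (0.0, 2.0))
    assert np.array_equal(rgb, rgb2)
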