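import numpy as np
import pytest

from elysa_quant.segmentation3d import (SegmentationParams, filter_objects,
                                        find_cell_geometry, segment_stack)
from elysa_quant.spatial_distribution import add_distal_columns
from elysa_quant.synthetic_scene import preset_stage_scene, render_scene

MII_SEED = 11

#: Parameters for phantom-recovery runs: threshold inside the classical
#: 600-1200 working range, calibrated on digitisation truth (it balances
#: edge dilation of plateau-bright assemblies against axial PSF dimming of
#: barely-resolved 3-um ones); no extra smoothing, since the synthetic
#: stacks are already band-limited by the rendered PSF.
RECOVERY_PARAMS = SegmentationParams(threshold=800.0, blur_sigma_px=0.0)


@pytest.fixture(scope="session")
def mii_scene():
    """One rendered MII-like scene (~25 non-touching phantoms, high SNR)."""
    spec = preset_stage_scene("MII", seed=MII_SEED)
    stack, truth = render_scene(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def mii_segmentation(mii_scene):
    """Full reference-channel reconstruction of the MII scene."""
    _, stack, _ = mii_scene
    vol = stack.channel("LAMP1")
    size = stack.voxel_size_um
    geometry = find_cell_geometry(vol, size)
    labels, table, background = segment_stack(vol, size, RECOVERY_PARAMS)
    table = filter_objects(table, RECOVERY_PARAMS, geometry, size)
    table = add_distal_columns(table, geometry.center_um)
    return {"labels": labels, "table": table, "geometry": geometry,
            "background": background, "voxel_size": size}


def match_by_centroid(truth_table, measured_table):
    """Index of the measured object nearest each true phantom centroid."""
    tc = truth_table[["centroid_z_um", "centroid_y_um",
                      "centroid_x_um"]].to_numpy(float)
    mc = measured_table[["centroid_z_um", "centroid_y_um",
                         "centroid_x_um"]].to_numpy(float)
    d = np.linalg.norm(tc[:, None, :] - mc[None, :, :], axis=2)
    return d.argmin(axis=1)
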