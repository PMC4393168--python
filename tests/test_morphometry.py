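"""Structural indices: thickness fields, skeleton decomposition, size classes."""

import numpy as np
import pytest
from scipy import ndimage

from kesubct.morphometry import (DiameterBins, inscribed_diameter_field,
                                 local_thickness, mean_skeleton_diameter,
                                 mean_structure_thickness, measure,
                                 segment_density, size_specific, skeletonize,
                                 volume_fraction)
from kesubct.volume import RoiSpec, VolumeGrid, roi_mask

from conftest import add_tube, make_tube


def brute_force_local_thickness(mask: VolumeGrid) -> np.ndarray:
    """Definitional oracle: for every foreground voxel the largest sphere
    (centred at any foreground voxel, radius = that centre's inscribed
    radius) covering it. O(N^2)-ish; only for small masks."""
    fg = mask.data.astype(bool)
    edt = ndimage.distance_transform_edt(fg)
    rins = np.maximum(edt - 0.5, 0.0)
    rins[fg & (rins == 0)] = 0.5
    centers = np.argwhere(fg)
    radii = rins[fg]
    out = np.zeros(mask.shape)
    for c, r in zip(centers, radii):
        lo = np.maximum(np.floor(c - r).astype(int), 0)
        hi = np.minimum(np.ceil(c + r).astype(int) + 1, mask.shape)
        zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                 indexing="ij")
        d = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        sel = (d <= r) & fg[sl]
        reg = out[sl]
        reg[sel] = np.maximum(reg[sel], 2 * r)
        out[sl] = reg
    return out * mask.voxel_um


def ball_mask(shape, center, diameter, voxel_um=1.0):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return VolumeGrid(d2 <= (diameter / 2) ** 2, voxel_um=voxel_um, kind="binary")


def full_roi(grid):
    return grid.with_data(np.ones(grid.shape, bool))


# --------------------------------------------------------- volume fraction


def test_volume_fraction_basics():
    roi = VolumeGrid(np.ones((4, 4, 4), bool), kind="binary")
    assert volume_fraction(roi, roi) == 100.0
    half = roi.with_data(np.arange(64).reshape(4, 4, 4) < 32)
    assert volume_fraction(half, roi) == 50.0
    with pytest.raises(ValueError, match="ROI"):
        volume_fraction(roi, roi.with_data(np.zeros((4, 4, 4), bool)))


# --------------------------------------------------------------- thickness


def test_local_thickness_sphere_and_voxel():
    b = ball_mask((25, 25, 25), (12, 12, 12), 15)
    th = local_thickness(b)
    assert th.max() == pytest.approx(15, abs=1)
    single = VolumeGrid(np.zeros((7, 7, 7), bool), voxel_um=1.0, kind="binary")
    single.data[3, 3, 3] = True
    assert local_thickness(single)[3, 3, 3] == pytest.approx(1.0, abs=0.01)


def test_local_thickness_matches_brute_force_oracle():
    # tube through a small volume plus a ball, against the definitional oracle
    g = make_tube((30, 24, 24), (2, 12, 12), (27, 12, 12), 4.5)
    g = g.with_data(g.data | ball_mask((30, 24, 24), (20, 12, 12), 13).data)
    ours = local_thickness(g)
    oracle = brute_force_local_thickness(g)
    fg = g.data.astype(bool)
    assert np.abs(ours[fg] - oracle[fg]).max() <= 1.0 + 1e-9


def test_cylinder_axis_thickness_is_its_diameter():
    m = np.zeros((40, 31, 31), bool)
    yy, xx = np.ogrid[:31, :31]
    m[:] = (np.hypot(yy - 15, xx - 15) <= 10)[None]
    g = VolumeGrid(m, voxel_um=1.0, kind="binary")
    th = local_thickness(g)
    assert th[5:35, 15, 15].mean() == pytest.approx(20, abs=1)
    insc = inscribed_diameter_field(g)
    assert insc[5:35, 15, 15].mean() == pytest.approx(20, abs=1)


def test_mean_structure_thickness_slab_and_ball():
    slab = VolumeGrid(np.zeros((20, 20, 20), bool), voxel_um=1.0, kind="binary")
    slab.data[:, :, 8:13] = True  # 5 voxels thick
    assert mean_structure_thickness(slab) == pytest.approx(5, abs=1)
    b = ball_mask((25, 25, 25), (12, 12, 12), 15)
    th = local_thickness(b)
    assert mean_structure_thickness(b, th) < 15
    assert th.max() == pytest.approx(15, abs=1)
    empty = VolumeGrid(np.zeros((5, 5, 5), bool), kind="binary")
    assert mean_structure_thickness(empty) is None


# ---------------------------------------------------------------- skeleton


def test_straight_tube_topology():
    g = make_tube((60, 24, 24), (5, 12, 12), (55, 12, 12), 4)
    s = skeletonize(g)
    assert (s.n_segments, s.n_nodes, s.n_free_ends) == (1, 0, 2)


def test_y_junction_topology():
    g = make_tube((80, 80, 40), (10, 40, 20), (40, 40, 20), 4)
    g = add_tube(g, (40, 40, 20), (70, 20, 20), 4)
    g = add_tube(g, (40, 40, 20), (70, 60, 20), 4)
    s = skeletonize(g)
    assert (s.n_segments, s.n_nodes, s.n_free_ends) == (3, 1, 3)


def test_tree_segment_count_equals_edge_count():
    edges = [((5, 50, 50), (30, 50, 50)),
             ((30, 50, 50), (55, 25, 50)), ((30, 50, 50), (55, 75, 50)),
             ((55, 25, 50), (85, 12, 30)), ((55, 25, 50), (85, 38, 30)),
             ((55, 75, 50), (85, 62, 70)), ((55, 75, 50), (85, 88, 70))]
    g = make_tube((100, 100, 100), *edges[0], 3.5)
    for a, b in edges[1:]:
        g = add_tube(g, a, b, 3.5)
    s = skeletonize(g)
    assert s.n_segments == len(edges)
    assert s.n_nodes == 3
    # every skeleton voxel belongs to at least one segment
    assert sum(len(seg) for seg in s.segments) >= s.coords.shape[0]


def test_single_voxel_structure_is_one_segment():
    g = VolumeGrid(np.zeros((9, 9, 9), bool), kind="binary")
    g.data[4, 4, 4] = True
    assert skeletonize(g).n_segments == 1


def test_empty_mask_has_empty_skeleton():
    g = VolumeGrid(np.zeros((6, 6, 6), bool), kind="binary")
    s = skeletonize(g)
    assert s.n_segments == 0 and s.coords.shape == (0, 3)
    assert mean_skeleton_diameter(s, np.zeros((6, 6, 6))) is None


# ------------------------------------------------------------ V.D and bins


def test_mean_skeleton_diameter_single_and_mixed_cylinders():
    g = make_tube((40, 26, 26), (3, 13, 13), (37, 13, 13), 10.0)
    th = inscribed_diameter_field(g)
    s = skeletonize(g)
    assert mean_skeleton_diameter(s, th) == pytest.approx(20, abs=1)
    # two equal-length cylinders of 10 and 30 um -> mean ~ 20 um; tubes are
    # long relative to their radii because thinning erodes free ends inward
    g2 = make_tube((200, 64, 46), (3, 16, 23), (197, 16, 23), 5.0)
    g2 = add_tube(g2, (3, 46, 23), (197, 46, 23), 15.0)
    s2 = skeletonize(g2)
    vd = mean_skeleton_diameter(s2, inscribed_diameter_field(g2))
    assert vd == pytest.approx(20, abs=2.0)


def test_segment_density_arithmetic():
    g = make_tube((40, 26, 26), (3, 13, 13), (37, 13, 13), 5.0)
    s = skeletonize(g)
    assert segment_density(s, 0.122) == pytest.approx(1 / 0.122)
    with pytest.raises(ValueError):
        segment_density(s, 0.0)


def test_diameter_bins_partition():
    bins = DiameterBins()
    assert bins.n == 5
    assert list(bins.index([5, 10, 15, 25, 35, 40, 80])) == [0, 1, 1, 2, 3, 4, 4]


def test_size_specific_single_tube_and_partition():
    # mid-class calibre (24 um): digital diameters quantise ~1 voxel low,
    # so a tube exactly on a class edge would be ambiguous by construction
    g = make_tube((40, 32, 32), (3, 16, 16), (37, 16, 16), 12.0)
    roi = full_roi(g)
    s = skeletonize(g)
    th = inscribed_diameter_field(g)
    vvf, vseg = size_specific(s, g, roi, th)
    assert np.argmax(vvf) == 2  # 20 um tube -> class [20, 30)
    assert vvf.sum() == pytest.approx(volume_fraction(g, roi), abs=1e-9)
    assert vseg.sum() * (roi.voxel_volume_mm3 * roi.data.sum()) == pytest.approx(1.0)


def test_size_specific_volume_split_two_calibres():
    # parallel 12 um and 48 um tubes of equal length: volumes ~ 1:16
    # axes separated by more than the large diameter, otherwise surface
    # voxels of the fat tube sit nearer the thin tube's skeleton line
    g = make_tube((160, 112, 56), (3, 24, 28), (157, 24, 28), 6.0, voxel_um=1.0)
    g = add_tube(g, (3, 78, 28), (157, 78, 28), 24.0)
    roi = full_roi(g)
    s = skeletonize(g)
    vvf, vseg = size_specific(s, g, roi, inscribed_diameter_field(g))
    small, large = vvf[1], vvf[4]
    assert large / small == pytest.approx(16.0, rel=0.25)
    assert vvf.sum() == pytest.approx(volume_fraction(g, roi), abs=1e-9)


def test_measure_partition_is_exact_and_scales_with_voxel_size(clean_phantom):
    spec, pair, truth = clean_phantom
    rm = roi_mask(spec.roi, pair.high)
    res = measure(truth.vessel_mask, truth.bone_mask, rm)
    assert res.v_vf_per_bin_pct.sum() == pytest.approx(res.v_vf_pct, abs=1e-9)
    assert res.v_seg_per_bin_mm3.sum() == pytest.approx(res.v_seg_per_mm3, abs=1e-9)
    assert 0 <= res.v_vf_pct <= 100 and 0 <= res.b_vf_pct <= 100

    # doubling the voxel size doubles every micrometre output
    v2 = VolumeGrid(truth.vessel_mask.data, voxel_um=2 * spec.voxel_um, kind="binary")
    b2 = VolumeGrid(truth.bone_mask.data, voxel_um=2 * spec.voxel_um, kind="binary")
    rm2 = VolumeGrid(rm.data, voxel_um=2 * spec.voxel_um, kind="binary")
    res2 = measure(v2, b2, rm2)
    assert res2.v_d_um == pytest.approx(2 * res.v_d_um, rel=1e-6)
    assert res2.b_th_um == pytest.approx(2 * res.b_th_um, rel=1e-6)
    assert res2.v_vf_pct == pytest.approx(res.v_vf_pct, rel=1e-9)


def test_rotation_robustness_of_tube_metrics():
    g = make_tube((50, 50, 50), (5, 25, 25), (45, 25, 25), 6.0)
    g = add_tube(g, (25, 25, 25), (45, 40, 25), 4.0)
    base = None
    for k in range(3):
        rot = VolumeGrid(np.rot90(g.data, k=1, axes=(0, (k % 2) + 1)).copy(),
                         voxel_um=g.voxel_um, kind="binary") if k else g
        roi = full_roi(rot)
        res = measure(rot, roi.with_data(np.zeros(rot.shape, bool)), roi)
        if base is None:
            base = res
        else:
            assert res.v_vf_pct == pytest.approx(base.v_vf_pct, rel=0.05)
            assert res.v_seg_per_mm3 == pytest.approx(base.v_seg_per_mm3, rel=0.05)
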