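"""K-edge subtraction segmentation: filters, Li threshold, vessel/bone masks."""

import numpy as np
import pytest
from skimage.filters.thresholding import _cross_entropy

from kesubct.calibration import CalibrationLine, dhap_to_mu
from kesubct.phantom import build_phantom
from kesubct.segmentation import (SegmentationParams, li_threshold,
                                  max_filter3d, mean_filter3d, segment_bone,
                                  segment_vessels, subtract_kedge)
from kesubct.volume import DualEnergyPair, VolumeGrid, roi_mask

from conftest import small_spec


def dice(a, b):
    return 2 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))


# ---------------------------------------------------------------- filters


def test_max_filter_expands_single_voxel_to_cube():
    a = np.zeros((9, 9, 9))
    a[4, 4, 4] = 7.0
    out = max_filter3d(VolumeGrid(a, kind="diff"), radius=1).data
    assert (out[3:6, 3:6, 3:6] == 7.0).all()
    assert out.sum() == 27 * 7.0


@pytest.mark.parametrize("op", [max_filter3d, mean_filter3d])
def test_filters_preserve_constants(op):
    a = VolumeGrid(np.full((6, 6, 6), 3.5), kind="diff")
    np.testing.assert_allclose(op(a).data, 3.5)


def test_filters_match_brute_force_neighborhood():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 100, (16, 16, 16))
    mx = max_filter3d(VolumeGrid(a, kind="diff"), 1).data
    mn = mean_filter3d(VolumeGrid(a, kind="diff"), 3).data
    pad = np.pad(a, 1, mode="edge")
    for idx in [(0, 0, 0), (5, 7, 3), (15, 15, 15), (8, 0, 12)]:
        z, y, x = idx
        blk = pad[z : z + 3, y : y + 3, x : x + 3]
        assert mx[idx] == blk.max()
        assert mn[idx] == pytest.approx(blk.mean())
    assert (mx >= a).all()


def test_mean_filter_spreads_impulse():
    a = np.zeros((9, 9, 9))
    a[4, 4, 4] = 27.0
    out = mean_filter3d(VolumeGrid(a, kind="diff")).data
    np.testing.assert_allclose(out[3:6, 3:6, 3:6], 1.0)


def test_subtraction_arithmetic_and_clamp():
    h = VolumeGrid(np.array([[[120.0, 30.0]]]), kind="gray")
    l = VolumeGrid(np.array([[[40.0, 50.0]]]), kind="gray")
    out = subtract_kedge(h, l).data
    np.testing.assert_allclose(out, [[[80.0, 0.0]]])
    with pytest.raises(ValueError):
        subtract_kedge(h, VolumeGrid(np.zeros((1, 1, 3)), kind="gray"))


def test_subtraction_mean_matches_kedge_contrast(clean_phantom):
    # over the core of truth vessels the difference approximates
    # (mu_high - mu_low) / gray factor
    from scipy import ndimage

    spec, pair, truth = clean_phantom
    diff = subtract_kedge(pair.high, max_filter3d(pair.low, 1)).data
    core = ndimage.binary_erosion(truth.vessel_mask.data, iterations=2)
    expected = (spec.mu_vessel_high - spec.mu_vessel_low) / spec.cal.gray_to_mu_factor
    assert diff[core].mean() == pytest.approx(expected, rel=0.05)


# ------------------------------------------------------------- Li threshold


def test_li_separates_two_level_image():
    v = np.array([10.0] * 50 + [200.0] * 50)
    t = li_threshold(v, exclude_zero=False)
    assert 10.0 < t < 200.0


def test_li_is_global_minimiser_of_cross_entropy():
    # exhaustive scan against an independent formulation of the criterion;
    # the criterion is flat over empty histogram gaps, so compare values
    rng = np.random.default_rng(0)
    v = np.concatenate([rng.normal(20, 8, 50000), rng.normal(150, 8, 50000)])
    v = v.clip(0.5)
    t = li_threshold(v, exclude_zero=False)
    ours = _cross_entropy(v, t)
    grid = np.linspace(v.min() + 0.5, v.max() - 0.5, 400)
    best = min(_cross_entropy(v, g) for g in grid)
    assert ours <= best + 1e-9 * abs(best)


def test_li_matches_iterative_reference_classification():
    from skimage.filters import threshold_li

    rng = np.random.default_rng(1)
    v = np.concatenate([rng.normal(20, 8, 50000), rng.normal(150, 8, 50000)]).clip(0.5)
    ours = li_threshold(v, exclude_zero=False)
    ref = threshold_li(v)
    # both must induce the same partition of the sample
    assert np.array_equal(v > ours, v > ref)


def test_li_shift_property():
    rng = np.random.default_rng(2)
    v = np.concatenate([rng.normal(30, 6, 30000), rng.normal(140, 10, 30000)]).clip(1)
    t0 = li_threshold(v, exclude_zero=False)
    t1 = li_threshold(v + 25.0, exclude_zero=False)
    assert t1 - t0 == pytest.approx(25.0, abs=1.0)


def test_li_rejects_degenerate_histogram():
    with pytest.raises(ValueError, match="degenerate"):
        li_threshold(np.full(100, 7.0), exclude_zero=False)
    with pytest.raises(ValueError, match="degenerate"):
        li_threshold(np.zeros(100), exclude_zero=True)


# ------------------------------------------------------- mask segmentation


def test_segment_vessels_recovers_thick_vessel_truth():
    # thick vessels: the sub-voxel boundary shell left by box averaging is
    # small relative to the lumen, so overlap with truth is high
    spec = small_spec(tree_root_diameter_um=44.0, tree_depth=1, n_trees=3,
                      tree_min_diameter_um=30.0)
    pair, truth = build_phantom(spec, compute_expected=False)
    rm = roi_mask(spec.roi, pair.high)
    mask, info = segment_vessels(DualEnergyPair(pair.low, pair.high), roi=rm)
    tv = truth.vessel_mask.data & rm.data
    assert dice(mask.data, tv) >= 0.9
    assert info["threshold"] > 0


def test_segment_vessels_mask_within_one_voxel_shell(clean_phantom):
    from scipy import ndimage

    spec, pair, truth = clean_phantom
    rm = roi_mask(spec.roi, pair.high)
    mask, _ = segment_vessels(DualEnergyPair(pair.low, pair.high), roi=rm)
    tv = truth.vessel_mask.data & rm.data
    shell = np.ones((3, 3, 3), bool)
    assert not (mask.data & ~ndimage.binary_dilation(tv, shell)).any()
    assert not (tv & ~ndimage.binary_dilation(mask.data, shell)).any()


def test_zero_vessel_phantom_yields_empty_mask():
    spec = small_spec(vessel_segments=[], n_woven_islands=4)
    pair, truth = build_phantom(spec, compute_expected=False)
    rm = roi_mask(spec.roi, pair.high)
    mask, _ = segment_vessels(DualEnergyPair(pair.low, pair.high), roi=rm)
    assert mask.data.sum() <= 0.001 * rm.data.sum()


def test_unregistered_shift_degrades_vessel_recovery(clean_phantom):
    from kesubct.registration import RigidTransform, resample

    spec, pair, truth = clean_phantom
    rm = roi_mask(spec.roi, pair.high)
    tv = truth.vessel_mask.data & rm.data
    good, _ = segment_vessels(DualEnergyPair(pair.low, pair.high), roi=rm)
    shifted = resample(pair.low, RigidTransform(translation=(3.0, 3.0, 0.0)))
    bad, _ = segment_vessels(DualEnergyPair(shifted, pair.high), roi=rm)
    assert dice(bad.data, tv) < dice(good.data, tv)


def test_segment_bone_rules():
    cal = CalibrationLine()
    g = np.full((10, 10, 10), dhap_to_mu(800.0, cal) / cal.gray_to_mu_factor)
    low = VolumeGrid(g, kind="gray")
    no_vessels = VolumeGrid(np.zeros((10, 10, 10), bool), kind="binary")
    bone = segment_bone(low, no_vessels, cal)
    assert bone.data.all()  # uniform block at 800 mg/cm^3 is all bone
    all_vessels = VolumeGrid(np.ones((10, 10, 10), bool), kind="binary")
    assert not segment_bone(low, all_vessels, cal).data.any()


def test_vessel_and_bone_masks_disjoint(clean_phantom):
    spec, pair, truth = clean_phantom
    rm = roi_mask(spec.roi, pair.high)
    vessels, _ = segment_vessels(DualEnergyPair(pair.low, pair.high), roi=rm)
    bone = segment_bone(pair.low, vessels, spec.cal, roi=rm)
    assert not (vessels.data & bone.data).any()
    tb = truth.bone_mask.data & rm.data
    assert dice(bone.data, tb) >= 0.9


def test_vessel_detection_monotone_in_contrast():
    # doubling the K-edge jump never loses truth-vessel voxels (the total
    # mask volume is not monotone: the data-driven threshold adapts and the
    # boundary shell narrows as contrast grows)
    base = dict(tree_depth=1, n_trees=3, seed=5)
    recalls = []
    for mu_high in (30.0, 60.0):
        spec = small_spec(mu_vessel_high=mu_high, **base)
        pair, truth = build_phantom(spec, compute_expected=False)
        rm = roi_mask(spec.roi, pair.high)
        mask, _ = segment_vessels(DualEnergyPair(pair.low, pair.high), roi=rm)
        tv = truth.vessel_mask.data & rm.data
        recalls.append(np.count_nonzero(mask.data & tv) / tv.sum())
    assert recalls[1] >= recalls[0]
    assert recalls[1] >= 0.95
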