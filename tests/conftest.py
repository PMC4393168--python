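"""Shared fixtures: geometric masks and small synthetic specimens.

Phantom fixtures use reduced geometry (smaller analysis cylinder, fewer
vessel trees) so the suite stays fast; the generator itself defaults to the
full-size specimen geometry.
"""

import numpy as np
import pytest

from kesubct.phantom import PhantomSpec, build_phantom
from kesubct.volume import VolumeGrid


def make_tube(shape, p0, p1, r, voxel_um=1.0):
    """Rasterise one straight tube into a binary VolumeGrid (test helper)."""
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = np.stack([zz, yy, xx], -1).astype(float)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / d.dot(d), 0, 1)
    dist = np.linalg.norm(pts - (p0 + t[..., None] * d), axis=-1)
    return VolumeGrid(dist <= r, voxel_um=voxel_um, kind="binary")


def add_tube(grid: VolumeGrid, p0, p1, r) -> VolumeGrid:
    other = make_tube(grid.shape, p0, p1, r, grid.voxel_um)
    return grid.with_data(grid.data | other.data)


def small_spec(**kw) -> PhantomSpec:
    """Reduced-geometry phantom spec (~1/10 the voxels of the default)."""
    base = dict(
        roi_diameter_um=300.0, roi_height_um=150.0, hole_diameter_um=360.0,
        n_trees=4, tree_depth=2, tree_root_diameter_um=30.0,
        tree_branch_length_um=(45.0, 80.0), n_woven_islands=8,
        woven_radius_um=(15.0, 35.0),
        blur_sigma_um=0.0, noise_sd_gray=0.0, misalignment=None, seed=11,
    )
    base.update(kw)
    return PhantomSpec(**base)


def mid_spec(**kw) -> PhantomSpec:
    """Mid-size phantom (500 um cylinder): enough lever arm for rotation
    recovery, ~1/3 the voxels of the full-size specimen."""
    base = dict(
        roi_diameter_um=500.0, roi_height_um=220.0, hole_diameter_um=560.0,
        n_trees=8, tree_depth=3, blur_sigma_um=0.0, noise_sd_gray=0.0,
        misalignment=None, seed=13,
    )
    base.update(kw)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def mid_phantom():
    spec = mid_spec()
    pair, truth = build_phantom(spec, compute_expected=False)
    return spec, pair, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-, blur- and misalignment-free reduced phantom with truth."""
    spec = small_spec()
    pair, truth = build_phantom(spec, compute_expected=False)
    return spec, pair, truth
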