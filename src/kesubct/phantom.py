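"""Synthetic dual-energy specimens with known vascular and bone geometry.

The generator emulates a rat tibial cortical drill-hole specimen perfused
with a zirconium-based vascular casting agent and scanned just below
(17.9 keV) and just above (18.1 keV) the zirconium K-edge:

* a cortical wall (intact bone, ~1360 mg/cm^3 hydroxyapatite) pierced by a
  drill-hole, with woven-bone islands (~800 mg/cm^3) regenerating inside,
* a branching tree of contrast-filled vessels whose attenuation jumps from
  mu_low to mu_high between the two energies, while bone and soft tissue
  attenuate identically at both (no edge between 17.9 and 18.1 keV),
* partial-volume blur (isotropic Gaussian), additive Gaussian read-out
  noise with 8-bit quantisation, and a small rigid misalignment of the
  low-energy stack emulating the CT stage's return-to-origin error.

Ground truth (masks, centerlines, per-segment radii, generating-tree edge
count) is kept alongside, untouched by blur and noise, so every downstream
stage can be scored against it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .calibration import CalibrationLine, dhap_to_mu
from .morphometry import (DiameterBins, MorphometryResult,
                          mean_structure_thickness, skeletonize)
from .registration import RigidTransform, resample
from .volume import DualEnergyPair, RoiSpec, VolumeGrid, roi_mask, roi_volume_mm3

#: gray<->mu scaling used for phantom rasterisation: with mu_vessel_high =
#: 60 /cm the supra-edge stack spans the full 8-bit range (gray ~153) and
#: the sub-edge stack stays below ~60 gray, the dynamic ranges seen in real
#: subtraction scans of these specimens.
PHANTOM_CAL = CalibrationLine(gray_to_mu_factor=0.392)


@dataclass
class VesselSegment:
    """One straight centerline edge of the vascular tree (um coordinates)."""

    start_um: np.ndarray
    end_um: np.ndarray
    radius_um: float

    def __post_init__(self):
        self.start_um = np.asarray(self.start_um, dtype=float)
        self.end_um = np.asarray(self.end_um, dtype=float)
        if self.radius_um <= 0:
            raise ValueError("vessel radius must be positive")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(self.end_um - self.start_um))

    def sample_points(self, step_um: float) -> np.ndarray:
        n = max(2, int(np.ceil(self.length_um / step_um)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        return self.start_um + t * (self.end_um - self.start_um)


@dataclass
class BoneRegion:
    """A bone shape primitive carrying a hydroxyapatite density.

    ``shape`` is one of:
      - "ball": params (center_um, radius_um)
      - "cortical_wall": params (axis_center_um (2,), hole_radius_um) — all
        lattice voxels radially beyond the hole, i.e. the drilled cortex.
    """

    shape: str
    params: tuple
    dhap_mg_cm3: float

    def __post_init__(self):
        if self.shape not in ("ball", "cortical_wall"):
            raise ValueError(f"unknown bone primitive {self.shape!r}")
        if self.dhap_mg_cm3 <= 0:
            raise ValueError("bone density must be positive")


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic dual-energy specimen.

    With ``vessel_segments``/``bone_regions`` left as None, a random
    branching vessel tree and the default drilled-cortex-plus-woven-bone
    geometry are generated from ``seed``.
    """

    roi_diameter_um: float = 720.0
    roi_height_um: float = 300.0
    voxel_um: float = 2.74
    hole_diameter_um: float = 780.0
    margin_um: float = 30.0
    vessel_segments: list[VesselSegment] | None = None
    bone_regions: list[BoneRegion] | None = None
    mu_vessel_low: float = 6.0       # /cm at 17.9 keV (below the Zr K-edge)
    mu_vessel_high: float = 60.0     # /cm at 18.1 keV (above it)
    mu_background: float = 0.8       # soft tissue / marrow, both energies
    cortical_dhap: float = 1364.0    # mg/cm^3, intact cortex
    woven_dhap: float = 800.0        # mg/cm^3, regenerating bone islands
    n_woven_islands: int = 60
    woven_radius_um: tuple[float, float] = (15.0, 35.0)
    n_trees: int = 12
    tree_root_diameter_um: float = 36.0
    tree_min_diameter_um: float = 6.0
    tree_depth: int = 4
    tree_branch_length_um: tuple[float, float] = (70.0, 130.0)
    blur_sigma_um: float = 2.74
    noise_sd_gray: float = 2.0
    misalignment: RigidTransform | None = field(
        default_factory=lambda: RigidTransform(
            translation=(2.0, -1.5, 1.0), rotation_deg=(0.2, 0.0, 0.0)
        )
    )
    seed: int = 0
    cal: CalibrationLine = PHANTOM_CAL

    def __post_init__(self):
        if self.mu_vessel_high <= self.mu_vessel_low:
            raise ValueError("mu_vessel_high must exceed mu_vessel_low (K-edge jump)")
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        if self.hole_diameter_um <= self.roi_diameter_um:
            raise ValueError("drill hole must be wider than the ROI cylinder")

    @property
    def lattice_shape(self) -> tuple[int, int, int]:
        vx = self.voxel_um
        nz = int(np.ceil((self.roi_height_um + 2 * self.margin_um) / vx)) + 1
        nxy = int(np.ceil((self.hole_diameter_um + 2 * self.margin_um) / vx)) + 1
        return (nz, nxy, nxy)

    @property
    def roi(self) -> RoiSpec:
        shape = self.lattice_shape
        return RoiSpec(
            center=tuple((s - 1) / 2.0 for s in shape),
            diameter_um=self.roi_diameter_um,
            height_um=self.roi_height_um,
            axis=0,
        )


@dataclass
class PhantomTruth:
    """Exact geometry the phantom was generated from."""

    vessel_mask: VolumeGrid
    bone_mask: VolumeGrid
    segments: list[VesselSegment]
    owner_labels: np.ndarray         # int32: 1-based nearest-segment id on vessel voxels
    applied_misalignment: RigidTransform | None
    spec: PhantomSpec
    expected_indices: MorphometryResult | None = None

    @property
    def per_segment_diameter_um(self) -> np.ndarray:
        return np.array([2.0 * s.radius_um for s in self.segments])


def random_vessel_tree(spec: PhantomSpec, rng: np.random.Generator) -> list[VesselSegment]:
    """A random binary tree of tapering straight vessel edges inside the ROI.

    Child diameter = parent x U(0.7, 0.95), clipped to [tree_min, root]
    which spans all five diameter classes with the default root of 44 um.
    Branch directions fan out by 25-40 degrees so branches stay separated.
    """
    vx = spec.voxel_um
    shape = spec.lattice_shape
    center = np.array([(s - 1) / 2.0 for s in shape]) * vx
    r_roi = spec.roi_diameter_um / 2.0
    z_lo = center[0] - spec.roi_height_um / 2.0
    z_hi = center[0] + spec.roi_height_um / 2.0

    def clamp(p):
        p = p.copy()
        p[0] = np.clip(p[0], z_lo + 6.0, z_hi - 6.0)
        radial = p[1:] - center[1:]
        r = np.linalg.norm(radial)
        rmax = r_roi - spec.tree_root_diameter_um / 2.0 - 4.0
        if r > rmax:
            p[1:] = center[1:] + radial * (rmax / r)
        return p

    def rotate_toward(u, angle_deg, rng):
        # perturb direction u by angle_deg about a random perpendicular axis
        u = u / np.linalg.norm(u)
        a = rng.normal(size=3)
        a -= a.dot(u) * u
        a /= np.linalg.norm(a)
        th = np.deg2rad(angle_deg)
        return np.cos(th) * u + np.sin(th) * a

    segments: list[VesselSegment] = []
    stack = []
    n_trees = max(1, spec.n_trees)
    # roots evenly spaced around the ROI periphery (angiogenic ingrowth from
    # the surrounding tissue); each tree grows axially and inward within its
    # own angular sector so trees do not interpenetrate
    for i in range(n_trees):
        ang = 2 * np.pi * i / n_trees + rng.uniform(-0.3, 0.3) / n_trees
        rad = rng.uniform(0.60, 0.80) * r_roi
        root = np.array([
            rng.uniform(z_lo + 8.0, z_lo + 0.4 * spec.roi_height_um),
            center[1] + rad * np.cos(ang),
            center[2] + rad * np.sin(ang),
        ])
        inward = np.array([0.0, -np.cos(ang), -np.sin(ang)])
        u = 0.8 * np.array([1.0, 0.0, 0.0]) + 0.35 * inward
        u += rng.normal(0, 0.08, 3)
        u /= np.linalg.norm(u)
        stack.append((root, root, u, spec.tree_root_diameter_um, spec.tree_depth))
    # keep each tree within a lateral corridor around its root so that
    # vessels of different trees stay separated (real vessels exclude each
    # other; interpenetrating tubes would also break the truth geometry)
    corridor = 1.2 * np.pi * r_roi / n_trees + spec.tree_root_diameter_um
    while stack:
        root, p, u, d, depth = stack.pop()
        length = rng.uniform(*spec.tree_branch_length_um)
        end = clamp(p + u * length)
        lateral = end - root
        lateral[0] = 0.0
        lat = np.linalg.norm(lateral)
        if lat > corridor:
            end = clamp(root + (end - root) * (0.9 * corridor / max(lat, 1e-9)))
        if np.linalg.norm(end - p) < 2 * vx:
            continue
        segments.append(VesselSegment(p, end, d / 2.0))
        if depth > 0:
            for sign in (1.0, -1.0):
                child_d = np.clip(
                    d * rng.uniform(0.70, 0.95),
                    spec.tree_min_diameter_um, spec.tree_root_diameter_um,
                )
                ang = rng.uniform(18.0, 32.0) * sign
                v = rotate_toward(u, ang, rng)
                # bias back toward the axial direction to keep growth upward
                v = 0.7 * v + 0.3 * np.array([1.0, 0.0, 0.0])
                v /= np.linalg.norm(v)
                stack.append((root, end, v, float(child_d), depth - 1))
    return segments


def default_bone_regions(spec: PhantomSpec, rng: np.random.Generator) -> list[BoneRegion]:
    """Drilled cortical wall plus woven-bone islands inside the ROI."""
    vx = spec.voxel_um
    shape = spec.lattice_shape
    center = np.array([(s - 1) / 2.0 for s in shape]) * vx
    regions = [
        BoneRegion("cortical_wall", (center[1:], spec.hole_diameter_um / 2.0),
                   spec.cortical_dhap)
    ]
    r_roi = spec.roi_diameter_um / 2.0
    for _ in range(spec.n_woven_islands):
        r = rng.uniform(*spec.woven_radius_um)
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.25, 0.8) * (r_roi - r)
        z = rng.uniform(center[0] - spec.roi_height_um / 2.0 + r,
                        center[0] + spec.roi_height_um / 2.0 - r)
        c = np.array([z, center[1] + rad * np.cos(ang), center[2] + rad * np.sin(ang)])
        regions.append(BoneRegion("ball", (c, r), spec.woven_dhap))
    return regions


def _rasterize_vessels(spec: PhantomSpec, segments: list[VesselSegment]):
    """Vessel mask plus nearest-segment owner labels (1-based)."""
    vx = spec.voxel_um
    shape = spec.lattice_shape
    mask = np.zeros(shape, dtype=bool)
    owner = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float32)
    for i, seg in enumerate(segments):
        r = seg.radius_um
        if 2 * r < vx:
            warnings.warn(
                f"vessel diameter {2 * r:.2f} um below the voxel size; "
                "rasterising at one-voxel thickness"
            )
        r_eff = max(r, 0.6 * vx)
        p0 = seg.start_um / vx
        p1 = seg.end_um / vx
        r_vox = r_eff / vx
        lo = np.maximum(np.floor(np.minimum(p0, p1) - r_vox - 1), 0).astype(int)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + r_vox + 1) + 1,
                        np.array(shape)).astype(int)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        pts = np.stack([zz, yy, xx], axis=-1).astype(float)
        d = p1 - p0
        len2 = d.dot(d)
        t = np.clip(((pts - p0) @ d) / len2, 0.0, 1.0) if len2 > 0 else np.zeros(pts.shape[:-1])
        closest = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - closest, axis=-1)
        sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        inside = dist <= r_vox
        mask[sl] |= inside
        closer = inside & (dist < best[sl])
        best[sl][closer] = dist[closer].astype(np.float32)
        owner[sl][closer] = i + 1
    return mask, owner


def _rasterize_bone(spec: PhantomSpec, regions: list[BoneRegion]) -> np.ndarray:
    """Per-voxel d.HAp field (0 outside bone); rejects density conflicts."""
    vx = spec.voxel_um
    shape = spec.lattice_shape
    dhap = np.zeros(shape, dtype=float)
    coords = np.ogrid[: shape[0], : shape[1], : shape[2]]
    for reg in regions:
        if reg.shape == "ball":
            c_um, r_um = reg.params
            c = np.asarray(c_um, dtype=float) / vx
            r = r_um / vx
            d2 = ((coords[0] - c[0]) ** 2 + (coords[1] - c[1]) ** 2
                  + (coords[2] - c[2]) ** 2)
            sel = d2 <= r**2
        else:  # cortical_wall
            c_um, hole_r_um = reg.params
            c = np.asarray(c_um, dtype=float) / vx
            r = hole_r_um / vx
            d2 = (coords[1] - c[0]) ** 2 + (coords[2] - c[1]) ** 2
            sel = d2 > r**2
        sel = np.broadcast_to(sel, shape)
        conflict = sel & (dhap > 0) & (dhap != reg.dhap_mg_cm3)
        if np.any(conflict):
            raise ValueError(
                "overlapping bone primitives carry contradictory densities"
            )
        dhap[sel] = reg.dhap_mg_cm3
    return dhap


def build_phantom(spec: PhantomSpec,
                  compute_expected: bool = True) -> tuple[DualEnergyPair, PhantomTruth]:
    """Generate the dual-energy gray stacks and the exact ground truth.

    The low-energy stack is additionally transformed by ``spec.misalignment``
    (registration has to undo it); blur and noise are applied after
    rasterisation, and the truth masks are untouched by either.
    """
    rng = np.random.default_rng(spec.seed)
    segments = (spec.vessel_segments if spec.vessel_segments is not None
                else random_vessel_tree(spec, rng))
    regions = (spec.bone_regions if spec.bone_regions is not None
               else default_bone_regions(spec, rng))

    vessel_mask, owner = _rasterize_vessels(spec, segments)
    dhap = _rasterize_bone(spec, regions)
    bone_mask = (dhap > 0) & ~vessel_mask  # contrast agent fills the lumen

    cal = spec.cal
    mu_bone = np.where(dhap > 0, dhap_to_mu(dhap, cal), 0.0)
    mu_low = np.full(spec.lattice_shape, spec.mu_background)
    np.copyto(mu_low, mu_bone, where=dhap > 0)
    mu_high = mu_low.copy()
    mu_low[vessel_mask] = spec.mu_vessel_low
    mu_high[vessel_mask] = spec.mu_vessel_high

    def to_gray(mu):
        g = mu / cal.gray_to_mu_factor
        if g.max() > 255:
            warnings.warn("gray values clipped at 255; lower the attenuation "
                          "or raise gray_to_mu_factor")
        return np.clip(g, 0, 255)

    g_low, g_high = to_gray(mu_low), to_gray(mu_high)
    if spec.blur_sigma_um > 0:
        sig = spec.blur_sigma_um / spec.voxel_um
        g_low = ndimage.gaussian_filter(g_low, sig)
        g_high = ndimage.gaussian_filter(g_high, sig)
    if spec.misalignment is not None and not spec.misalignment.is_identity():
        t = replace(
            spec.misalignment,
            center=np.array([(s - 1) / 2.0 for s in spec.lattice_shape]),
        )
        g_low = resample(
            VolumeGrid(g_low, voxel_um=spec.voxel_um, kind="diff"), t
        ).data
        applied = t
    else:
        applied = None
    if spec.noise_sd_gray > 0:
        g_low = g_low + rng.normal(0, spec.noise_sd_gray, g_low.shape)
        g_high = g_high + rng.normal(0, spec.noise_sd_gray, g_high.shape)

    low = VolumeGrid(np.clip(np.round(g_low), 0, 255).astype(np.uint8),
                     voxel_um=spec.voxel_um, kind="gray")
    high = VolumeGrid(np.clip(np.round(g_high), 0, 255).astype(np.uint8),
                      voxel_um=spec.voxel_um, kind="gray")
    pair = DualEnergyPair(low=low, high=high, transform=None)

    truth = PhantomTruth(
        vessel_mask=VolumeGrid(vessel_mask, voxel_um=spec.voxel_um, kind="binary"),
        bone_mask=VolumeGrid(bone_mask, voxel_um=spec.voxel_um, kind="binary"),
        segments=segments, owner_labels=owner, applied_misalignment=applied,
        spec=spec,
    )
    if compute_expected:
        truth.expected_indices = truth_indices(truth, spec.roi)
    return pair, truth


def truth_indices(truth: PhantomTruth, roi: RoiSpec,
                  bins: DiameterBins = DiameterBins()) -> MorphometryResult:
    """Analytic/mask-based indices straight from the truth (no segmentation).

    V.Vf, B.Vf come from the truth masks; V.Seg and the per-class split from
    the generating segments and the nearest-segment ownership of each vessel
    voxel; V.D is the generative diameter averaged along the centerlines at
    voxel-length spacing; B.Th and B.Seg are measured on the truth bone mask.
    """
    spec = truth.spec
    grid = truth.vessel_mask
    rmask = roi_mask(roi, grid)
    n_roi = int(np.count_nonzero(rmask.data))
    if n_roi == 0:
        raise ValueError("empty ROI")
    vol_mm3 = roi_volume_mm3(rmask)
    roi_b = rmask.data.astype(bool)

    v_in = truth.vessel_mask.data.astype(bool) & roi_b
    b_in = truth.bone_mask.data.astype(bool) & roi_b
    v_vf = 100.0 * v_in.sum() / n_roi
    b_vf = 100.0 * b_in.sum() / n_roi

    # segments contributing to the ROI (centerline sampled at voxel spacing)
    vx = spec.voxel_um
    seg_in = []
    vd_samples = []
    c = np.asarray(roi.center, dtype=float)
    r_vox = roi.diameter_um / 2.0 / vx
    h_vox = roi.height_um / vx
    for i, seg in enumerate(truth.segments):
        pts = seg.sample_points(vx) / vx
        ax_ok = np.abs(pts[:, roi.axis] - c[roi.axis]) <= h_vox / 2.0
        rad_axes = [a for a in range(3) if a != roi.axis]
        rr = np.hypot(pts[:, rad_axes[0]] - c[rad_axes[0]],
                      pts[:, rad_axes[1]] - c[rad_axes[1]])
        inside = ax_ok & (rr <= r_vox)
        if inside.any():
            seg_in.append(i)
            vd_samples.append(np.full(int(inside.sum()), 2.0 * seg.radius_um))
    v_seg = len(seg_in) / vol_mm3
    v_d = float(np.concatenate(vd_samples).mean()) if vd_samples else None

    diam = truth.per_segment_diameter_um
    vvf_bins = np.zeros(bins.n)
    vseg_bins = np.zeros(bins.n)
    for i in seg_in:
        vseg_bins[bins.index(diam[i])] += 1.0 / vol_mm3
    own = truth.owner_labels[v_in]
    assigned = own > 0
    own_bin = bins.index(diam[own[assigned] - 1])
    for b in range(bins.n):
        vvf_bins[b] = 100.0 * np.count_nonzero(own_bin == b) / n_roi
    # voxels without an owner (should not happen): largest bin of mask
    n_orphan = int(np.count_nonzero(~assigned))
    if n_orphan:
        warnings.warn(f"{n_orphan} vessel voxels without a generating segment")
        vvf_bins[0] += 100.0 * n_orphan / n_roi

    bone_grid = truth.bone_mask.with_data(b_in)
    if b_in.any():
        b_t = mean_structure_thickness(bone_grid)
        b_seg = skeletonize(bone_grid).n_segments / vol_mm3
    else:
        b_t, b_seg = None, 0.0

    return MorphometryResult(
        v_vf_pct=float(v_vf), b_vf_pct=float(b_vf), v_d_um=v_d, b_th_um=b_t,
        v_seg_per_mm3=float(v_seg), b_seg_per_mm3=float(b_seg),
        roi_volume_mm3=vol_mm3, bins=bins,
        v_vf_per_bin_pct=vvf_bins, v_seg_per_bin_mm3=vseg_bins,
    )


def truth_metadata(truth: PhantomTruth) -> dict:
    """JSON-serialisable summary of the generative truth."""
    spec = truth.spec
    meta = {
        "n_segments": len(truth.segments),
        "per_segment_diameter_um": truth.per_segment_diameter_um.tolist(),
        "seed": spec.seed,
        "voxel_um": spec.voxel_um,
        "mu_vessel_low": spec.mu_vessel_low,
        "mu_vessel_high": spec.mu_vessel_high,
        "gray_to_mu_factor": spec.cal.gray_to_mu_factor,
        "blur_sigma_um": spec.blur_sigma_um,
        "noise_sd_gray": spec.noise_sd_gray,
        "misalignment": json.loads(truth.applied_misalignment.to_json())
        if truth.applied_misalignment is not None else None,
    }
    if truth.expected_indices is not None:
        meta["expected_indices"] = {
            k: (v if not isinstance(v, np.ndarray) else v.tolist())
            for k, v in truth.expected_indices.to_row().items()
        }
    return meta
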