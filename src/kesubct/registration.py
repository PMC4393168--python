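"""Rigid mutual-information registration of the two energy volumes.

The paired 17.9/18.1 keV stacks of one specimen are acquired in separate
rotations of the CT stage and end up misaligned, mainly by the stage's
return-to-origin error: a small rigid offset. The correction here maximises
the mutual information (MI) of the joint gray-level histogram over a
6-parameter rigid transform (3 translations, 3 small rotations), or over
translations only.

The optimiser is deliberately deterministic: an exhaustive integer-shift
grid on a 2x-downsampled pyramid level picks the basin, then a Powell
refinement with trilinear resampling polishes the parameters. Volumes are
lightly Gaussian-smoothed for the metric to suppress the well-known
interpolation artifacts of MI (local maxima at integer shifts).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volume import VolumeGrid


@dataclass
class RigidTransform:
    """Rigid map of voxel coordinates: T(x) = R (x - c) + c + t.

    ``translation`` t and ``center`` c are in voxel units, ``rotation_deg``
    holds small angles about the (z, y, x) axes applied as Rz @ Ry @ Rx.
    :func:`resample` with this transform pulls values from ``vol`` at T(x),
    i.e. content appears moved by -t for a pure translation.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        for v in (self.translation, self.rotation_deg, self.center):
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError("transform parameters must be finite 3-vectors")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def matrix(self) -> np.ndarray:
        az, ay, ax = np.deg2rad(self.rotation_deg)
        cz, sz = np.cos(az), np.sin(az)
        cy, sy = np.cos(ay), np.sin(ay)
        cx, sx = np.cos(ax), np.sin(ax)
        # rotations about axis 0 (z), 1 (y), 2 (x) of the (z, y, x) frame
        rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (pts - self.center) @ self.matrix().T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        """Inverse transform: exact for the translation, small-angle for the
        rotation (negating Euler angles; commutator terms are O(angle^2))."""
        r = self.matrix()
        # T^{-1}(y) = R^T (y - c) + c - R^T t
        tinv = -r.T @ self.translation
        return RigidTransform(tinv, -self.rotation_deg, self.center)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(
            np.all(np.abs(self.translation) <= tol)
            and np.all(np.abs(self.rotation_deg) <= tol)
        )

    def magnitude(self) -> tuple[float, float]:
        """(max |translation| voxels, max |rotation| degrees)."""
        return float(np.abs(self.translation).max()), float(np.abs(self.rotation_deg).max())

    def to_json(self) -> str:
        return json.dumps(
            {
                "translation_voxels": self.translation.tolist(),
                "rotation_deg": self.rotation_deg.tolist(),
                "center_voxels": self.center.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        d = json.loads(s)
        return cls(d["translation_voxels"], d["rotation_deg"], d["center_voxels"])


def resample(moving: VolumeGrid, t: RigidTransform, order: int = 1) -> VolumeGrid:
    """Resample ``moving`` through ``t`` with trilinear interpolation.

    Voxels mapped outside the lattice are filled with 0. The identity
    transform returns the input values bit-exactly.
    """
    if t.is_identity():
        return moving.copy()
    r = t.matrix()
    offset = t.center + t.translation - r @ t.center
    out = ndimage.affine_transform(
        moving.data.astype(float), r, offset=offset, order=order, mode="constant", cval=0.0
    )
    if moving.data.dtype == np.uint8:
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return moving.with_data(out)


def mutual_information(a: VolumeGrid | np.ndarray, b: VolumeGrid | np.ndarray,
                       bins: int = 64) -> float:
    """Mutual information of the joint intensity histogram, in bits.

    Symmetric, non-negative; equals the Shannon entropy for identical
    volumes. A constant image carries no information: MI = 0 (with a
    warning, since registration on it is meaningless).
    """
    av = (a.data if isinstance(a, VolumeGrid) else np.asarray(a)).ravel()
    bv = (b.data if isinstance(b, VolumeGrid) else np.asarray(b)).ravel()
    if av.shape != bv.shape:
        raise ValueError("volumes must share a lattice")
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("constant volume: mutual information is 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / np.outer(pa, pb)[nz])))


def _downsample(data: np.ndarray, ds: int) -> np.ndarray:
    if ds == 1:
        return data.astype(np.float32)
    sm = ndimage.gaussian_filter(data.astype(np.float32), sigma=ds / 2.0)
    return sm[::ds, ::ds, ::ds]


def _central_crop(data: np.ndarray, frac: float) -> np.ndarray:
    # symmetric crop keeps the volume centre (and so the rotation centre)
    if frac >= 1.0:
        return data
    sl = []
    for n in data.shape:
        cut = int(n * (1 - frac) / 2)
        sl.append(slice(cut, n - cut))
    return data[tuple(sl)]


def _shift_mi(a: np.ndarray, b: np.ndarray, shift: np.ndarray, bins: int) -> float:
    """MI of a against b translated by an integer shift, via overlap slicing."""
    sl_a, sl_b = [], []
    for ax, s in enumerate(shift):
        s = int(s)
        n = a.shape[ax]
        if abs(s) >= n:
            return 0.0
        # resample semantics: out(x) = b(x + s) -> compare a[x] with b[x + s]
        if s >= 0:
            sl_a.append(slice(0, n - s))
            sl_b.append(slice(s, n))
        else:
            sl_a.append(slice(-s, n))
            sl_b.append(slice(0, n + s))
    return mutual_information(a[tuple(sl_a)], b[tuple(sl_b)], bins=bins)


def register(
    fixed: VolumeGrid,
    moving: VolumeGrid,
    max_shift_voxels: float = 6.0,
    max_rotation_deg: float = 2.0,
    mode: str = "rigid",
    bins: int = 64,
    metric_smooth_voxels: float = 1.0,
    metric_crop: float = 1.0,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Returns the transform to pass to :func:`resample` on ``moving``.
    ``mode`` is ``"rigid"`` (6 parameters) or ``"translation"`` (3). The
    18.1 keV stack is conventionally the fixed image.

    Deterministic: exhaustive integer-shift scan at a coarse pyramid level,
    then Powell refinement of all parameters at the working level.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving volumes must share a lattice")
    if mode not in ("rigid", "translation"):
        raise ValueError("mode must be 'rigid' or 'translation'")

    # two pyramid levels: integer-shift grid at the coarse one, Powell at
    # the working one (half resolution for large volumes, full otherwise)
    ds = 1
    while min(fixed.shape) // (ds * 2) >= 32 and ds < 2:
        ds *= 2
    a = _central_crop(_downsample(fixed.data, ds), metric_crop)
    b = _central_crop(_downsample(moving.data, ds), metric_crop)
    if metric_smooth_voxels > 0:
        a = ndimage.gaussian_filter(a, metric_smooth_voxels)
        b = ndimage.gaussian_filter(b, metric_smooth_voxels)

    ds_c = 2 if min(a.shape) >= 32 else 1
    ac, bc = _downsample(a, ds_c), _downsample(b, ds_c)
    reach = int(np.ceil(max_shift_voxels / (ds * ds_c)))
    best_mi, best_shift = -np.inf, np.zeros(3)
    rng = range(-reach, reach + 1)
    for sz in rng:
        for sy in rng:
            for sx in rng:
                mi = _shift_mi(ac, bc, np.array([sz, sy, sx]), bins)
                if mi > best_mi:
                    best_mi, best_shift = mi, np.array([sz, sy, sx], dtype=float)
    best_shift = best_shift * ds_c

    center = (np.array(a.shape) - 1) / 2.0
    n_par = 3 if mode == "translation" else 6

    # pre-shift the moving volume by half a voxel so that every candidate
    # transform involves interpolation; the untouched moving volume would
    # otherwise make the identity a spurious local optimum of MI (the one
    # point free of interpolation smoothing)
    half = 0.5
    b_pre = resample(
        VolumeGrid(b, voxel_um=fixed.voxel_um, kind="diff"),
        RigidTransform(translation=np.full(3, half), center=center),
    )

    def unpack(p):
        t = p[:3]
        rot = p[3:6] if n_par == 6 else np.zeros(3)
        return RigidTransform(t, rot, center)

    agrid = VolumeGrid(a, voxel_um=fixed.voxel_um, kind="diff")

    def neg_mi(p):
        warped = resample(b_pre, unpack(p))
        return -mutual_information(agrid, warped, bins=bins)

    p0 = np.concatenate([best_shift - half, np.zeros(3)])[:n_par]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            neg_mi, p0, method="Powell",
            options={"xtol": 5e-3, "ftol": 1e-7, "maxiter": 4, "maxfev": 300},
        )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"registration failed to converge; best so far {p0}")
    p = res.x
    # fold the half-voxel pre-shift back into the reported translation:
    # the net transform is "pre-shift then candidate", a translation offset
    t = (p[:3] + half) * ds
    rot = p[3:6] if n_par == 6 else np.zeros(3)
    # the cropped working array is centred on the full volume, so the
    # rotation centre maps to the full-volume centre; translation scales
    # with the downsampling factor only
    full_center = (np.array(fixed.shape) - 1) / 2.0
    return RigidTransform(t, rot, full_center)
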