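"""Voxel volumes, multi-page TIFF stack I/O and cylindrical regions of interest.

The whole pipeline works on isotropic 3D scalar fields. Axis order is
``(z, y, x)`` with the axial (slice) direction first; voxel centres sit at
integer lattice coordinates, so the physical position of voxel ``(i, j, k)``
is ``(i, j, k) * voxel_um`` micrometres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: Valid intensity semantics for a :class:`VolumeGrid`.
KINDS = ("gray", "mu", "dhap", "binary", "diff")

DEFAULT_VOXEL_UM = 2.74


@dataclass
class VolumeGrid:
    """A 3D scalar field with isotropic voxels and an intensity-semantics tag.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values. ``gray`` volumes are expected to lie in [0, 255].
    voxel_um : float
        Isotropic voxel edge length in micrometres.
    kind : {"gray", "mu", "dhap", "binary", "diff"}
        What the values mean: 8-bit gray levels, linear attenuation (/cm),
        hydroxyapatite-equivalent density (mg/cm^3), a binary mask, or an
        energy-subtraction difference image.
    """

    data: np.ndarray
    voxel_um: float = DEFAULT_VOXEL_UM
    kind: str = "gray"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"unknown intensity kind {self.kind!r}")
        if self.kind == "gray" and self.data.size:
            lo, hi = float(self.data.min()), float(self.data.max())
            # tolerance absorbs float filter roundoff
            if lo < -1e-6 or hi > 255 + 1e-6:
                raise ValueError(f"gray volume out of [0, 255]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_um * 1e-3) ** 3

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "VolumeGrid":
        """A new grid on the same lattice with different values."""
        return VolumeGrid(data, voxel_um=self.voxel_um, kind=kind or self.kind)

    def copy(self) -> "VolumeGrid":
        return replace(self, data=self.data.copy())


@dataclass
class DualEnergyPair:
    """Co-acquired sub-/supra-K-edge volumes of one specimen.

    ``low`` is the 17.9 keV stack (below the zirconium K-edge), ``high`` the
    18.1 keV stack (above it, where the contrast agent attenuates strongly).
    ``transform`` is the rigid inter-energy misalignment correction to apply
    to ``low`` to bring it onto ``high``'s lattice (None = already aligned).
    """

    low: VolumeGrid
    high: VolumeGrid
    transform: object | None = None
    energy_low_kev: float = 17.9
    energy_high_kev: float = 18.1

    def __post_init__(self):
        if self.low.shape != self.high.shape:
            raise ValueError(
                f"energy volumes differ in shape: {self.low.shape} vs {self.high.shape}"
            )
        if self.energy_high_kev <= self.energy_low_kev:
            raise ValueError("high energy must exceed low energy")


def read_stack(path, voxel_um: float = DEFAULT_VOXEL_UM, kind: str = "gray") -> VolumeGrid:
    """Read a multi-page 8-bit grayscale TIFF stack as a volume.

    Page order is taken as axial slice order. Only unsigned 8-bit input is
    accepted; anything else raises ``ValueError``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"stack not found: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {data.shape}")
    if data.dtype != np.uint8:
        raise ValueError(
            f"{path}: unsupported bit depth {data.dtype}; only 8-bit stacks are supported"
        )
    return VolumeGrid(data, voxel_um=voxel_um, kind=kind)


def write_stack(vol: VolumeGrid, path) -> None:
    """Write a volume as a multi-page 8-bit TIFF (binary masks as 0/255)."""
    data = vol.data
    if vol.kind == "binary":
        data = (data.astype(bool) * np.uint8(255))
    elif data.dtype != np.uint8:
        if data.min() < 0 or data.max() > 255:
            raise ValueError("volume values outside [0, 255]; cannot write as 8-bit")
        data = np.round(data).astype(np.uint8)
    tifffile.imwrite(os.fspath(path), data, photometric="minisblack")


@dataclass
class RoiSpec:
    """A cylindrical region of interest aligned with a lattice axis.

    The default geometry (diameter 720 um, height 300 um) is the analysis
    cylinder placed inside a cortical drill-hole defect. ``axis`` is the
    lattice axis the cylinder is aligned with (0 = axial/slice direction,
    the drill-hole direction).
    """

    center: tuple[float, float, float]  # voxel coordinates, (z, y, x)
    diameter_um: float = 720.0
    height_um: float = 300.0
    axis: int = 0

    def __post_init__(self):
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if self.diameter_um < 0 or self.height_um < 0:
            raise ValueError("ROI dimensions must be non-negative")

    @classmethod
    def centered(cls, shape: tuple[int, int, int], **kw) -> "RoiSpec":
        """ROI centred in a lattice of the given shape."""
        return cls(center=tuple((s - 1) / 2.0 for s in shape), **kw)


def roi_mask(roi: RoiSpec, grid: VolumeGrid) -> VolumeGrid:
    """Binary mask of voxels whose centres lie inside the ROI cylinder.

    Raises ``ValueError`` if the cylinder is not fully contained in the
    lattice. A zero-height or zero-diameter cylinder yields an empty mask.
    """
    vx = grid.voxel_um
    r_vox = roi.diameter_um / 2.0 / vx
    h_vox = roi.height_um / vx
    c = np.asarray(roi.center, dtype=float)
    ax = roi.axis
    radial_axes = [a for a in range(3) if a != ax]

    lo_ax = c[ax] - h_vox / 2.0
    hi_ax = c[ax] + h_vox / 2.0
    if lo_ax < -0.5 or hi_ax > grid.shape[ax] - 0.5:
        raise ValueError("ROI cylinder exceeds the lattice along its axis")
    for a in radial_axes:
        if c[a] - r_vox < -0.5 or c[a] + r_vox > grid.shape[a] - 0.5:
            raise ValueError("ROI cylinder exceeds the lattice radially")

    coords = np.ogrid[: grid.shape[0], : grid.shape[1], : grid.shape[2]]
    axial = np.abs(coords[ax] - c[ax]) <= h_vox / 2.0
    r2 = (coords[radial_axes[0]] - c[radial_axes[0]]) ** 2 + (
        coords[radial_axes[1]] - c[radial_axes[1]]
    ) ** 2
    mask = axial & (r2 <= r_vox**2)
    return VolumeGrid(mask, voxel_um=vx, kind="binary")


def roi_volume_mm3(mask: VolumeGrid) -> float:
    """ROI volume in mm^3 (voxel count x voxel volume)."""
    return int(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3
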