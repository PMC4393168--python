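"""3D morphometry of binary vascular and bone structures.

Six indices characterise the two structures inside the analysis cylinder:

* V.Vf, B.Vf (%)     — structure volume as a fraction of the ROI volume,
* V.D (um)           — mean vessel diameter: the diameter of the largest
                       sphere inscribed in the vascular space, averaged over
                       all skeleton voxels,
* B.Th (um)          — mean bone thickness: local thickness averaged over
                       all bone voxels (structure-volume weighted),
* V.Seg, B.Seg (/mm3)— density of node-to-node or node-to-free-end segments
                       of the skeletonised structure.

Vessel-size-specific V.Vf and V.Seg are reported for five diameter classes
(<10, 10-20, 20-30, 30-40, >=40 um); each skeleton segment is classed by its
mean local diameter and each vascular voxel inherits the class of the
segment owning its nearest skeleton voxel, so the per-class quantities
partition the totals exactly.

Local thickness follows the distance-ridge idea of Hildebrand & Rüegsegger:
the thickness at a voxel is the diameter of the largest sphere that lies
fully inside the structure and covers the voxel, computed here by sweeping
candidate radii of the Euclidean distance transform from large to small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .volume import VolumeGrid

_CUBE = np.ones((3, 3, 3), dtype=np.uint8)


@dataclass(frozen=True)
class DiameterBins:
    """Five half-open vessel-diameter classes in micrometres."""

    edges_um: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)

    @property
    def n(self) -> int:
        return len(self.edges_um) + 1

    def labels(self) -> list[str]:
        e = self.edges_um
        labs = [f"<{e[0]:g}"]
        labs += [f"{a:g}-{b:g}" for a, b in zip(e[:-1], e[1:])]
        labs.append(f">={e[-1]:g}")
        return labs

    def index(self, diameter_um) -> np.ndarray:
        """Bin index for each diameter (half-open, upper-exclusive)."""
        return np.searchsorted(np.asarray(self.edges_um), np.asarray(diameter_um),
                               side="right")


@dataclass
class Skeleton:
    """Voxel-chain medial representation of a binary structure.

    ``coords`` are the skeleton voxel coordinates; ``degree`` the number of
    26-connected skeleton neighbours of each. ``segments`` holds, per
    segment, the indices (into ``coords``) of its voxels; node-cluster
    voxels are appended to one incident segment so that every skeleton voxel
    belongs to at least one segment. ``n_nodes`` counts junction clusters
    (degree >= 3 voxels merged by 26-connectivity), ``n_free_ends`` voxels
    of degree <= 1 on retained segments.
    """

    coords: np.ndarray                    # (N, 3) int
    degree: np.ndarray                    # (N,) int
    segments: list[np.ndarray]            # indices into coords
    n_nodes: int
    n_free_ends: int
    shape: tuple[int, int, int]
    voxel_um: float
    n_pruned_spurs: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def label_volume(self) -> np.ndarray:
        """int32 volume: 1-based segment id at skeleton voxels, 0 elsewhere."""
        lab = np.zeros(self.shape, dtype=np.int32)
        for i, seg in enumerate(self.segments):
            c = self.coords[seg]
            lab[c[:, 0], c[:, 1], c[:, 2]] = i + 1
        return lab


@dataclass
class MorphometryResult:
    """The six structural indices plus vessel-size-specific quantities."""

    v_vf_pct: float
    b_vf_pct: float
    v_d_um: float | None
    b_th_um: float | None
    v_seg_per_mm3: float
    b_seg_per_mm3: float
    roi_volume_mm3: float
    bins: DiameterBins = field(default_factory=DiameterBins)
    v_vf_per_bin_pct: np.ndarray = field(default_factory=lambda: np.zeros(5))
    v_seg_per_bin_mm3: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def to_row(self) -> dict:
        row = {
            "V.Vf_pct": self.v_vf_pct,
            "B.Vf_pct": self.b_vf_pct,
            "V.D_um": self.v_d_um,
            "B.Th_um": self.b_th_um,
            "V.Seg_per_mm3": self.v_seg_per_mm3,
            "B.Seg_per_mm3": self.b_seg_per_mm3,
            "ROI_mm3": self.roi_volume_mm3,
        }
        for lab, vv, vs in zip(self.bins.labels(), self.v_vf_per_bin_pct,
                               self.v_seg_per_bin_mm3):
            row[f"V.Vf_{lab}_pct"] = vv
            row[f"V.Seg_{lab}_per_mm3"] = vs
        return row


def volume_fraction(mask: VolumeGrid, roi: VolumeGrid) -> float:
    """100 x |mask in roi| / |roi| (percent)."""
    if mask.shape != roi.shape:
        raise ValueError("mask and ROI must share a lattice")
    n_roi = int(np.count_nonzero(roi.data))
    if n_roi == 0:
        raise ValueError("empty ROI")
    n = int(np.count_nonzero(mask.data.astype(bool) & roi.data.astype(bool)))
    return 100.0 * n / n_roi


def local_thickness(mask: VolumeGrid, radius_step_voxels: float = 0.25) -> np.ndarray:
    """Local thickness field in micrometres (0 outside the structure).

    The thickness at a foreground voxel is the diameter of the largest
    sphere contained in the foreground that covers it. The inscribed-sphere
    radius at a candidate centre is its Euclidean distance transform minus
    half a voxel (the structure surface runs along voxel boundaries, so a
    single isolated voxel measures one voxel thick). Radii are swept from
    the largest down; a voxel within r of a centre with inscribed radius
    >= r has thickness at least 2r. Candidate radii are quantised to
    ``radius_step_voxels`` (diameter error at most one step).
    """
    fg = mask.data.astype(bool)
    th = np.zeros(mask.shape, dtype=float)
    if not fg.any():
        return th

    # work inside the bounding box (padded by the largest radius)
    edt_full = ndimage.distance_transform_edt(fg)
    rmax = float(edt_full.max())
    obj = ndimage.find_objects(fg.astype(np.int8))[0]
    pad = int(np.ceil(rmax)) + 1
    sl = tuple(
        slice(max(0, s.start - pad), min(n, s.stop + pad))
        for s, n in zip(obj, mask.shape)
    )
    fgb = fg[sl]
    rins = np.maximum(edt_full[sl] - 0.5, 0.0)
    rins[fgb & (rins == 0)] = 0.5  # every foreground voxel is >= 1 voxel thick

    radii = np.unique(rins[fgb])
    radii = radii[radii > 0]
    if radii.size > 2.0 * rmax / radius_step_voxels:
        radii = np.unique(np.floor(radii / radius_step_voxels) * radius_step_voxels)
        radii = radii[radii > 0]
    thb = np.zeros(fgb.shape, dtype=float)
    for r in radii[::-1]:
        centers = rins >= r
        dist_to_center = ndimage.distance_transform_edt(~centers)
        covered = fgb & (dist_to_center <= r) & (thb == 0)
        thb[covered] = 2.0 * r
    th[sl] = thb
    return th * mask.voxel_um


def inscribed_diameter_field(mask: VolumeGrid) -> np.ndarray:
    """Diameter (um) of the largest sphere centred at each voxel that stays
    inside the structure; 0 outside.

    This is the vessel-diameter definition: the largest sphere falling
    inside the vascular space *with its centre on the skeleton line*. It is
    evaluated at every voxel so it can simply be sampled on the skeleton.
    Unlike the covering-sphere local thickness it does not inflate at
    junctions covered by a neighbouring branch's larger sphere.
    """
    fg = mask.data.astype(bool)
    edt = ndimage.distance_transform_edt(fg)
    r = np.maximum(edt - 0.5, 0.0)
    r[fg & (r == 0)] = 0.5
    return 2.0 * r * mask.voxel_um


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    """Number of 26-connected skeleton neighbours at each voxel."""
    cnt = ndimage.convolve(skel.astype(np.uint8), _CUBE, mode="constant", cval=0)
    return (cnt - 1) * skel


def skeletonize(mask: VolumeGrid, prune_spur_voxels: int = 2) -> Skeleton:
    """Medial-line skeleton with node / free-end / segment decomposition.

    Thinning is homotopy-preserving 3D thinning; the resulting voxel set is
    decomposed under 26-connectivity: voxels with >= 3 skeleton neighbours
    form junction clusters (nodes), the remaining chains are branches, and a
    segment is a maximal node-to-node or node-to-free-end branch. Junction
    clusters joining exactly two branches (thinning corner artifacts, not
    true bifurcations) are spliced away. Spurs (free-ended branches) shorter
    than ``prune_spur_voxels`` are dropped as thinning artifacts.
    """
    fg = mask.data.astype(bool)
    if not fg.any():
        return Skeleton(
            coords=np.empty((0, 3), dtype=int), degree=np.empty(0, dtype=int),
            segments=[], n_nodes=0, n_free_ends=0, shape=mask.shape,
            voxel_um=mask.voxel_um,
        )
    skel = _sk_skeletonize(fg)
    if not skel.any():
        # a structure so small that thinning removed it: keep its centroid
        c = np.round(np.array(np.nonzero(fg)).mean(axis=1)).astype(int)
        skel = np.zeros_like(fg)
        skel[tuple(c)] = True

    ncount = _neighbor_count(skel)
    junction = skel & (ncount >= 3)
    branch = skel & ~junction

    branch_lab, n_branch = ndimage.label(branch, structure=_CUBE)
    node_lab, n_node = ndimage.label(junction, structure=_CUBE)

    # adjacency between branches and node clusters via a dilated node-label map
    incident: dict[int, set[int]] = {b + 1: set() for b in range(n_branch)}
    if n_node:
        node_dil = ndimage.grey_dilation(node_lab, footprint=_CUBE)
        touching = branch & (node_dil > 0)
        for b, nd in zip(branch_lab[touching], node_dil[touching]):
            incident[int(b)].add(int(nd))
    # branches per node cluster
    node_branches: dict[int, set[int]] = {n + 1: set() for n in range(n_node)}
    for b, nds in incident.items():
        for nd in nds:
            node_branches[nd].add(b)

    # splice pass-through "nodes" joining exactly two branches (corner artifacts)
    parent = {b + 1: b + 1 for b in range(n_branch)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    spliced_nodes = set()
    for nd, bs in node_branches.items():
        if len(bs) == 2:
            a, b = sorted(bs)
            parent[find(b)] = find(a)
            spliced_nodes.add(nd)
    true_nodes = [nd for nd in node_branches if nd not in spliced_nodes]

    # collect voxels per merged segment
    groups: dict[int, list[np.ndarray]] = {}
    for b in range(1, n_branch + 1):
        root = find(b)
        groups.setdefault(root, []).append(np.argwhere(branch_lab == b))
    # node-cluster voxels: spliced nodes join their (now single) segment;
    # true-node voxels are appended to their lowest-id incident segment
    node_assign: dict[int, int] = {}
    for nd, bs in node_branches.items():
        if bs:
            node_assign[nd] = min(find(b) for b in bs)
    for nd, root in node_assign.items():
        if root in groups:
            groups[root].append(np.argwhere(node_lab == nd))
    # node clusters with no incident branch (blob skeletons): own segment
    for nd in range(1, n_node + 1):
        if nd not in node_assign:
            groups[-nd] = [np.argwhere(node_lab == nd)]
            if nd in spliced_nodes:
                spliced_nodes.discard(nd)
            if nd not in true_nodes:
                true_nodes.append(nd)

    # prune short free-ended spurs attached to a true node
    seg_voxel_lists = []
    n_pruned = 0
    for root, parts in sorted(groups.items()):
        vox = np.vstack(parts)
        branch_ids = [b for b in range(1, n_branch + 1) if find(b) == root] if root > 0 else []
        inc_nodes = set().union(*(incident[b] for b in branch_ids)) if branch_ids else set()
        inc_true = {nd for nd in inc_nodes if nd not in spliced_nodes}
        n_branch_vox = sum(p.shape[0] for p in parts[: len(branch_ids)] or parts)
        is_spur = len(inc_true) == 1 and n_branch_vox < prune_spur_voxels
        if is_spur:
            n_pruned += 1
            continue
        seg_voxel_lists.append(vox)

    if not seg_voxel_lists:  # everything pruned: keep the largest group
        vox = max((np.vstack(p) for p in groups.values()), key=len)
        seg_voxel_lists = [vox]

    coords = np.vstack(seg_voxel_lists)
    offsets = np.cumsum([0] + [v.shape[0] for v in seg_voxel_lists])
    segments = [np.arange(offsets[i], offsets[i + 1]) for i in range(len(seg_voxel_lists))]
    deg = ncount[coords[:, 0], coords[:, 1], coords[:, 2]]
    n_free_ends = int(np.count_nonzero(deg <= 1))
    return Skeleton(
        coords=coords, degree=deg, segments=segments, n_nodes=len(true_nodes),
        n_free_ends=n_free_ends, shape=mask.shape, voxel_um=mask.voxel_um,
        n_pruned_spurs=n_pruned,
    )


def sample_field(field_vol: np.ndarray, skel: Skeleton) -> np.ndarray:
    """Values of a voxel field at the skeleton voxels."""
    c = skel.coords
    return field_vol[c[:, 0], c[:, 1], c[:, 2]]


def mean_skeleton_diameter(skel: Skeleton, thickness_um: np.ndarray) -> float | None:
    """Unweighted mean of the local diameter over all skeleton voxels (um).

    Returns None for an empty skeleton (the index is undefined, not zero).
    """
    if skel.coords.shape[0] == 0:
        return None
    return float(sample_field(thickness_um, skel).mean())


def mean_structure_thickness(mask: VolumeGrid,
                             thickness_um: np.ndarray | None = None) -> float | None:
    """Structure-volume-weighted mean local thickness (um); None if empty."""
    fg = mask.data.astype(bool)
    if not fg.any():
        return None
    if thickness_um is None:
        thickness_um = local_thickness(mask)
    return float(thickness_um[fg].mean())


def segment_density(skel: Skeleton, roi_volume_mm3: float) -> float:
    """Number of skeleton segments per mm^3 of ROI."""
    if roi_volume_mm3 <= 0:
        raise ValueError("ROI volume must be positive")
    return skel.n_segments / roi_volume_mm3


def size_specific(
    skel: Skeleton,
    mask: VolumeGrid,
    roi: VolumeGrid,
    thickness_um: np.ndarray,
    bins: DiameterBins = DiameterBins(),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-diameter-class (V.Vf %, V.Seg /mm^3); partitions the totals exactly.

    Each segment is classed by the mean local diameter over its skeleton
    voxels; each foreground voxel inherits the class of the segment owning
    its nearest skeleton voxel.
    """
    from .volume import roi_volume_mm3 as _roi_vol

    n_roi = int(np.count_nonzero(roi.data))
    if n_roi == 0:
        raise ValueError("empty ROI")
    vvf = np.zeros(bins.n)
    vseg = np.zeros(bins.n)
    fg = mask.data.astype(bool) & roi.data.astype(bool)
    if skel.n_segments == 0:
        if fg.any():
            warnings.warn("mask voxels present but skeleton empty; left unbinned")
        return vvf, vseg

    seg_diam = np.array(
        [sample_field(thickness_um, skel)[seg].mean() for seg in skel.segments]
    )
    seg_bin = bins.index(seg_diam)
    vol_mm3 = _roi_vol(roi)
    for b in seg_bin:
        vseg[b] += 1.0 / vol_mm3

    # nearest skeleton voxel for every foreground voxel
    lab = skel.label_volume()
    _, (iz, iy, ix) = ndimage.distance_transform_edt(lab == 0, return_indices=True)
    owner_seg = lab[iz[fg], iy[fg], ix[fg]] - 1  # 0-based segment id
    owner_bin = seg_bin[owner_seg]
    for b in range(bins.n):
        vvf[b] = 100.0 * np.count_nonzero(owner_bin == b) / n_roi
    return vvf, vseg


def measure(
    vessel_mask: VolumeGrid,
    bone_mask: VolumeGrid,
    roi: VolumeGrid,
    bins: DiameterBins = DiameterBins(),
    prune_spur_voxels: int = 2,
) -> MorphometryResult:
    """All six indices plus vessel-size-specific quantities for one specimen.

    Masks are intersected with the ROI before measurement; skeletons and
    thickness fields are computed on the ROI-restricted masks.
    """
    from .volume import roi_volume_mm3 as _roi_vol

    roi_b = roi.data.astype(bool)
    v = vessel_mask.with_data(vessel_mask.data.astype(bool) & roi_b)
    b = bone_mask.with_data(bone_mask.data.astype(bool) & roi_b)
    vol_mm3 = _roi_vol(roi)

    v_vf = volume_fraction(v, roi)
    b_vf = volume_fraction(b, roi)

    # vessel diameters: sphere centred on the skeleton line; bone thickness:
    # covering-sphere local thickness — the two indices are defined on
    # different supports and with different sphere conventions
    v_th = inscribed_diameter_field(v)
    b_th_field = local_thickness(b)
    v_skel = skeletonize(v, prune_spur_voxels)
    b_skel = skeletonize(b, prune_spur_voxels)

    v_d = mean_skeleton_diameter(v_skel, v_th)
    b_t = mean_structure_thickness(b, b_th_field)
    v_seg = segment_density(v_skel, vol_mm3)
    b_seg = segment_density(b_skel, vol_mm3)
    if v.data.any():
        vvf_bins, vseg_bins = size_specific(v_skel, v, roi, v_th, bins)
    else:
        vvf_bins, vseg_bins = np.zeros(bins.n), np.zeros(bins.n)

    return MorphometryResult(
        v_vf_pct=v_vf, b_vf_pct=b_vf, v_d_um=v_d, b_th_um=b_t,
        v_seg_per_mm3=v_seg, b_seg_per_mm3=b_seg, roi_volume_mm3=vol_mm3,
        bins=bins, v_vf_per_bin_pct=vvf_bins, v_seg_per_bin_mm3=vseg_bins,
    )
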