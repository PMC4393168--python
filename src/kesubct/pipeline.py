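"""End-to-end orchestration: register -> segment -> measure -> density -> stats.

`run_specimen` executes the stages in acquisition order on one dual-energy
pair and writes masks, a per-specimen CSV row and a provenance JSON.
`run_study` aggregates per-specimen rows into group summaries, runs the
nonparametric group tests and produces the reporting arithmetic (percent
contrasts, partition checks).
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationLine
from .density import DensityHistogram, dhap_distribution
from .morphometry import DiameterBins, MorphometryResult, measure
from .registration import RigidTransform, register, resample
from .segmentation import SegmentationParams, segment_bone, segment_vessels
from .stats import (dunn_posthoc, group_summary, group_table, kruskal_wallis,
                    partition_check, percent_contrast)
from .volume import (DualEnergyPair, RoiSpec, read_stack, roi_mask,
                     write_stack)


@dataclass
class RunConfig:
    """Fully resolved configuration of one specimen run."""

    low_path: str | None = None
    high_path: str | None = None
    out_dir: str | None = None
    voxel_um: float = 2.74
    cal: CalibrationLine = field(default_factory=CalibrationLine)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    roi: RoiSpec | None = None            # None: centred default cylinder
    bins: DiameterBins = field(default_factory=DiameterBins)
    register_mode: str = "rigid"          # "rigid" | "translation" | "none"
    max_shift_voxels: float = 6.0
    seed: int = 0
    save_masks: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "cal" in kw:
            kw["cal"] = CalibrationLine(**kw["cal"])
        if "seg" in kw:
            kw["seg"] = SegmentationParams(**kw["seg"])
        if "roi" in kw and kw["roi"] is not None:
            kw["roi"] = RoiSpec(**kw["roi"])
        if "bins" in kw:
            kw["bins"] = DiameterBins(tuple(kw["bins"]))
        return cls(**kw)


def default_roi(shape, voxel_um: float) -> RoiSpec:
    """Centred analysis cylinder: the standard 720 x 300 um geometry, shrunk
    if the lattice is smaller than that."""
    d = min(720.0, (min(shape[1], shape[2]) - 3) * voxel_um)
    h = min(300.0, (shape[0] - 3) * voxel_um)
    return RoiSpec.centered(shape, diameter_um=d, height_um=h)


@dataclass
class SpecimenResult:
    indices: MorphometryResult
    density: DensityHistogram | None
    transform: RigidTransform | None
    vessel_threshold: float | None
    provenance: dict


def run_specimen(
    config: RunConfig,
    pair: DualEnergyPair | None = None,
) -> SpecimenResult:
    """Run the full per-specimen chain.

    ``pair`` may be passed directly (e.g. a freshly built phantom);
    otherwise the two stacks are read from ``config.low_path`` /
    ``config.high_path``. Stage order: registration of the low-energy stack
    onto the high-energy one, K-edge subtraction segmentation, bone rule,
    ROI cropping, morphometry, then the mineral-density distribution.
    """
    if pair is None:
        for name, p in [("17.9 keV", config.low_path), ("18.1 keV", config.high_path)]:
            if p is None or not os.path.exists(str(p)):
                raise FileNotFoundError(f"{name} stack missing: {p}")
        pair = DualEnergyPair(
            low=read_stack(config.low_path, voxel_um=config.voxel_um),
            high=read_stack(config.high_path, voxel_um=config.voxel_um),
        )

    roi = config.roi or default_roi(pair.high.shape, config.voxel_um)
    rmask = roi_mask(roi, pair.high)

    transform = None
    low_aligned = pair.low
    if config.register_mode != "none":
        transform = register(
            pair.high, pair.low,
            max_shift_voxels=config.max_shift_voxels,
            mode=config.register_mode,
        )
        low_aligned = resample(pair.low, transform)
    aligned = DualEnergyPair(low=low_aligned, high=pair.high, transform=None)

    vessels, seg_info = segment_vessels(aligned, config.seg, roi=rmask)
    bone = segment_bone(low_aligned, vessels, config.cal, config.seg, roi=rmask)
    indices = measure(vessels, bone, rmask, bins=config.bins)
    hist = dhap_distribution(bone, low_aligned, config.cal, roi=rmask,
                             params=config.seg)

    prov = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "vessel_threshold": seg_info.get("threshold"),
        "segmentation": {k: v for k, v in seg_info.items() if k != "threshold"},
        "transform": json.loads(transform.to_json()) if transform is not None else None,
        "roi_volume_mm3": indices.roi_volume_mm3,
    }

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        if config.save_masks:
            write_stack(vessels, os.path.join(config.out_dir, "vessel_mask.tif"))
            write_stack(bone, os.path.join(config.out_dir, "bone_mask.tif"))
        row = indices.to_row()
        pd.DataFrame([row]).to_csv(os.path.join(config.out_dir, "indices.csv"),
                                   index=False)
        if hist is not None:
            hist.to_frame().to_csv(os.path.join(config.out_dir, "dhap_histogram.csv"),
                                   index=False)
        with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
            json.dump(prov, fh, indent=2, default=str)

    return SpecimenResult(indices=indices, density=hist, transform=transform,
                          vessel_threshold=seg_info.get("threshold"), provenance=prov)


#: indices reported per specimen, in table order
INDEX_COLUMNS = ["B.Vf_pct", "V.Vf_pct", "B.Th_um", "V.D_um",
                 "B.Seg_per_mm3", "V.Seg_per_mm3"]


def run_study(
    rows: pd.DataFrame,
    group_col: str = "group",
    reference_group: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Group-level analysis of a per-specimen index table.

    ``rows`` needs one row per specimen with a ``group`` column and the
    index columns produced by :meth:`MorphometryResult.to_row`. Returns a
    dict with the group summary (mean, SEM), Kruskal-Wallis + Dunn results
    per index, percent contrasts of each group mean against the reference
    group, and per-group partition checks of the size-specific columns.
    """
    groups = [g for g, sub in rows.groupby(group_col) if len(sub)]
    if len(groups) < 2:
        warnings.warn("fewer than 2 groups: summaries only, tests skipped")
    summary = group_summary(rows, group=group_col)

    tests = {}
    index_cols = [c for c in INDEX_COLUMNS if c in rows.columns]
    if len(groups) >= 2:
        for col in index_cols:
            gt = {g: v for g, v in group_table(rows, col, group_col).items()
                  if len(v) >= 1}
            h, p = kruskal_wallis(gt)
            entry = {"H": h, "p": p}
            if all(len(v) >= 2 for v in gt.values()):
                entry["dunn"] = dunn_posthoc(gt)
            tests[col] = entry

    contrasts = {}
    if reference_group is not None and reference_group in groups:
        ref_means = rows[rows[group_col] == reference_group][index_cols].mean()
        for g in groups:
            if g == reference_group:
                continue
            gm = rows[rows[group_col] == g][index_cols].mean()
            contrasts[g] = {
                col: percent_contrast(ref_means[col], gm[col])
                for col in index_cols if ref_means[col] not in (0.0,)
            }

    partitions = {}
    bins = DiameterBins()
    vvf_cols = [f"V.Vf_{l}_pct" for l in bins.labels()]
    vseg_cols = [f"V.Seg_{l}_per_mm3" for l in bins.labels()]
    if all(c in rows.columns for c in vvf_cols):
        for g in groups:
            sub = rows[rows[group_col] == g]
            partitions[g] = {
                "V.Vf": partition_check(sub[vvf_cols].mean().to_numpy(),
                                        sub["V.Vf_pct"].mean(), tol=0.02),
                "V.Seg": partition_check(sub[vseg_cols].mean().to_numpy(),
                                         sub["V.Seg_per_mm3"].mean(), tol=1.0),
            }

    return {"summary": summary, "tests": tests, "contrasts": contrasts,
            "partitions": partitions, "alpha": alpha}
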