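"""Hydroxyapatite-density distribution of segmented bone.

The mineral density of each bone voxel is read off the box-averaged
17.9 keV stack through the attenuation calibration, and the relative bone
volume is histogrammed in 8 mg/cm^3 bins anchored at the 500 mg/cm^3
segmentation floor. Percentages are relative to all bone voxels with
d.HAp above the floor, so a histogram always sums to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationLine, gray_to_mu, mu_to_dhap
from .segmentation import SegmentationParams, mean_filter3d
from .volume import VolumeGrid


@dataclass
class DensityHistogram:
    """Relative bone-volume distribution over mineral density."""

    bin_edges: np.ndarray        # mg/cm^3, len = n_bins + 1
    percent: np.ndarray          # % of total bone volume per bin
    mean: float                  # mg/cm^3
    median: float                # mg/cm^3
    n_voxels: int
    bin_width: float = 8.0

    def summary(self) -> dict:
        return {
            "mean_mg_cm3": self.mean,
            "median_mg_cm3": self.median,
            "n_voxels": self.n_voxels,
            "bin_width_mg_cm3": self.bin_width,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_left_mg_cm3": self.bin_edges[:-1],
                "bin_right_mg_cm3": self.bin_edges[1:],
                "percent": self.percent,
            }
        )


def dhap_distribution(
    bone_mask: VolumeGrid,
    low: VolumeGrid,
    cal: CalibrationLine = CalibrationLine(),
    roi: VolumeGrid | None = None,
    bin_width: float = 8.0,
    floor: float = 500.0,
    params: SegmentationParams = SegmentationParams(),
    presmoothed: bool = False,
) -> DensityHistogram | None:
    """Per-voxel d.HAp histogram over the bone mask (None if no bone).

    ``low`` is the 17.9 keV gray stack; it is box-averaged with the same
    filter as the bone segmentation unless ``presmoothed`` is set. Only
    voxels with d.HAp > ``floor`` contribute (the distribution is defined
    over the mineralised fraction).
    """
    fg = bone_mask.data.astype(bool)
    if roi is not None:
        fg = fg & roi.data.astype(bool)
    if not fg.any():
        return None
    smooth = low if presmoothed else mean_filter3d(low, params.mean_filter_size)
    dhap = mu_to_dhap(gray_to_mu(smooth.data[fg], cal), cal)
    dhap = np.asarray(dhap)[np.asarray(dhap) > floor]
    if dhap.size == 0:
        return None
    n_bins = int(np.ceil((dhap.max() - floor) / bin_width)) or 1
    edges = floor + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(dhap, bins=edges)
    pct = 100.0 * counts / counts.sum()
    return DensityHistogram(
        bin_edges=edges, percent=pct, mean=float(dhap.mean()),
        median=float(np.median(dhap)), n_voxels=int(dhap.size), bin_width=bin_width,
    )


def average_histograms(hists: list[DensityHistogram]) -> DensityHistogram:
    """Average per-specimen histograms within a group (equal specimen weight).

    Pads all histograms to a common support before averaging; the mean and
    median reported are the averages of the per-specimen values.
    """
    hists = [h for h in hists if h is not None]
    if not hists:
        raise ValueError("no histograms to average")
    bw = hists[0].bin_width
    floor = hists[0].bin_edges[0]
    n = max(len(h.percent) for h in hists)
    edges = floor + bw * np.arange(n + 1)
    acc = np.zeros(n)
    for h in hists:
        acc[: len(h.percent)] += h.percent
    acc /= len(hists)
    return DensityHistogram(
        bin_edges=edges, percent=acc,
        mean=float(np.mean([h.mean for h in hists])),
        median=float(np.mean([h.median for h in hists])),
        n_voxels=int(sum(h.n_voxels for h in hists)), bin_width=bw,
    )
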