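# kesubct — K-edge subtraction micro-CT analysis

`kesubct` quantifies angiogenic vasculature and regenerating bone in
synchrotron micro-CT scans of cortical drill-hole defects, using K-edge
subtraction: the specimen, perfused with a zirconium dioxide vascular
casting agent, is imaged just below (17.9 keV) and just above (18.1 keV)
the zirconium K-absorption edge. Contrast-filled vessels attenuate several
times more strongly above the edge while bone and soft tissue are
unchanged, so the registered difference image isolates the vasculature and
the sub-edge image quantifies mineralised bone. The package is aimed at
bone/vascular imaging groups who want the full chain — from paired 8-bit
voxel stacks to structural indices and group statistics — as tested,
scriptable Python, together with a synthetic dual-energy phantom generator
that provides exact ground truth for validation.

## The analysis chain

For each specimen (isotropic 2.74 µm voxels, cylindrical analysis region of
720 µm × 300 µm inside the defect):

1. **Registration** — the 17.9 keV stack is aligned to the 18.1 keV stack
   with a rigid transform maximising the mutual information of the joint
   gray-level histogram (the misalignment stems mainly from the CT stage's
   return-to-origin error).
2. **Vessel segmentation** — the low-energy stack is expanded by a 3×3×3
   maximum filter (to keep partial-volume bone residues out of the
   difference), subtracted from the high-energy stack (clamped at 0),
   box-averaged 3×3×3, and thresholded by minimum cross-entropy (Li).
3. **Bone segmentation** — the box-averaged low-energy stack is converted
   to linear attenuation µ and voxels with µ ≥ 4.74 cm⁻¹, excluding the
   vascular mask, are classified as bone. Mineral density follows the
   calibration d.HAp (mg/cm³) = 136·µ (cm⁻¹) − 142, so the bone
   threshold corresponds to 500 mg/cm³ hydroxyapatite.
4. **Morphometry** — vascular and bone volume fractions (V.Vf, B.Vf, % of
   the ROI); mean vessel diameter V.D (largest sphere inscribed in the
   vascular space centred on the skeleton line, averaged over skeleton
   voxels); bone thickness B.Th (covering-sphere local thickness averaged
   over bone voxels); segment densities V.Seg, B.Seg (node-to-node or
   node-to-free-end skeleton segments per mm³); and vessel-size-specific
   V.Vf/V.Seg over five diameter classes (<10, 10–20, 20–30, 30–40,
   ≥40 µm) that partition the totals exactly.
5. **Density distribution** — relative bone volume histogrammed over d.HAp
   in 8 mg/cm³ bins above the 500 mg/cm³ floor, with mean and median.
6. **Statistics** — Kruskal–Wallis tests with Dunn's post-hoc comparisons
   across treatment groups (hindlimb unloading, deferoxamine-treated
   unloading, weight bearing), paired t-tests for within-group changes,
   and reporting arithmetic (percent contrasts of group means, partition
   checks of the size-specific tables).

The phantom generator builds dual-energy specimens with a drilled cortical
wall, woven-bone islands, and branching vessel trees of known centerlines
and radii, then applies partial-volume blur, 8-bit quantisation noise and a
rigid inter-energy misalignment — every downstream stage can be scored
against exact truth.

## Worked example

Build a mid-size synthetic specimen (500 µm analysis cylinder), run the
full chain, and compare with the generative truth:

```python
import numpy as np
from kesubct import (PhantomSpec, RunConfig, build_phantom, run_specimen,
                     truth_indices)

spec = PhantomSpec(roi_diameter_um=500, roi_height_um=220,
                   hole_diameter_um=560, n_trees=8, tree_depth=3,
                   blur_sigma_um=0, noise_sd_gray=0, seed=23)
pair, truth = build_phantom(spec, compute_expected=False)
expected = truth_indices(truth, spec.roi)

cfg = RunConfig(cal=spec.cal, register_mode="rigid", roi=spec.roi,
                save_masks=False)
result = run_specimen(cfg, pair=pair)

print(f"registration:   {np.round(result.transform.translation, 2)} voxels")
print(f"Li threshold:   {result.vessel_threshold:.1f} gray")
for name, t, r in [("V.Vf (%)", expected.v_vf_pct, result.indices.v_vf_pct),
                   ("V.D (um)", expected.v_d_um, result.indices.v_d_um),
                   ("B.Th (um)", expected.b_th_um, result.indices.b_th_um)]:
    print(f"{name:10s} truth {t:8.2f}   recovered {r:8.2f}")
```

prints

```
registration:   [-2.09  1.49 -1.  ] voxels
Li threshold:   18.1 gray
V.Vf (%)   truth     5.67   recovered     7.53
V.D (um)   truth    25.57   recovered    24.59
B.Th (um)  truth    40.43   recovered    38.27
```

The registration has undone the generator's (2, −1.5, 1)-voxel misalignment
to better than a tenth of a voxel, and the mean vessel diameter and bone
thickness are recovered to within a voxel. The vascular volume fraction
overshoots the truth: the minimum cross-entropy threshold is deliberately
inclusive, so the mask carries a sub-voxel partial-volume shell around each
vessel — see `docs/methods.md` for the quantitative analysis of this bias.

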