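# Methods

This note documents the models, conventions and numerical choices behind
`kesubct`, what the synthetic phantoms do and do not emulate, and the known
limitations of the analysis chain.

## Physical model

Two monochromatic scans bracket the zirconium K-absorption edge
(17.998 keV): at 17.9 keV the contrast agent in the vessels attenuates
modestly; at 18.1 keV its attenuation jumps several-fold, while bone and
soft tissue attenuate essentially identically at both energies (neither has
an edge in this window). Subtracting the registered low-energy stack from
the high-energy stack therefore cancels bone and tissue and leaves the
vasculature. Volumes are 8-bit gray stacks with isotropic 2.74 µm voxels;
gray levels are proportional to linear attenuation µ (cm⁻¹).

### Calibration

Two affine maps connect the intensity domains:

* µ = `gray_to_mu_factor` × gray. The factor is scanner scaling, not
  physics, and is a configuration parameter. Its default, 7.97/136 ≈
  0.0586 cm⁻¹ per gray level, is chosen so that the composition of the two
  maps reproduces the hydroxyapatite-phantom gray-domain line
  d.HAp = 7.97 × gray − 142 exactly. (A µ = 0.392 × gray convention also
  circulates for these scans; 136 × 0.392 ≠ 7.97, so the two cannot hold
  simultaneously — we treat the µ-domain relation as canonical and leave
  the gray factor configurable rather than guess which figure is right.)
* d.HAp (mg/cm³) = 136 × µ (cm⁻¹) − 142, from a K₂HPO₄-phantom
  calibration of 17.9 keV scans. The bone-classification threshold
  µ ≥ 4.74 cm⁻¹ maps to 502.6 ≈ 500 mg/cm³; the constructor rejects
  constant sets that disagree by more than 5 mg/cm³.

The synthetic phantom uses a gray factor of 0.392 by default so that its
default vessel attenuation (60 cm⁻¹ above the edge) maps to gray ≈ 153
within the 8-bit range and its sub-edge stack stays below ~60 gray, the
dynamic ranges observed in real scans of these specimens; with the 0.0586
default the same attenuation would clip at 255. Pipelines run on phantom
data must use the phantom's calibration (recorded in its metadata).

## Registration

A 6-parameter rigid transform (3 translations in voxels, 3 small Euler
angles about the z/y/x axes, centre at the volume centre) maximises the
mutual information of the joint 64-bin histogram. The optimiser is
deterministic: an exhaustive integer-shift grid on a coarse pyramid level
(4× downsampled) selects the basin, then Powell refinement with trilinear
resampling polishes all parameters at the working level (2× downsampled
for large volumes). Two numerical details matter:

* Volumes are Gaussian-smoothed (σ = 1 working voxel) for the metric to
  damp the well-known interpolation artifacts of MI.
* The moving volume is pre-shifted by half a voxel before optimisation and
  the half voxel folded back into the reported translation. Without this,
  the identity is the only candidate evaluated without interpolation
  smoothing and becomes a spurious local optimum; a pure 1° rotation would
  go uncorrected.

Measured recovery on mid/full-size phantoms: translations within 0.1 voxel
over ±5 voxels, rotations within 0.25° over ±2°. Rotation recovery
requires a lever arm: on a small test volume a 1° rotation displaces
content by less than half a voxel and is genuinely below the metric's
sensitivity, so rotation tests use the 500 µm phantom. A translation-only
mode exists since stage return error is mostly translational. The
18.1 keV stack is the fixed image; registration is estimated on whole
stacks and applied before ROI cropping.

## Segmentation

Vessels: `max_filter3d(E_low, 3×3×3)` → `E_high − E_low_expanded`, clamped
at 0 → 3×3×3 box average → minimum cross-entropy (Li) threshold →
foreground above threshold, restricted to the ROI. The maximum filter
expands bright structures in the sub-edge stack by one voxel so that
partial-volume bone boundaries cannot survive the subtraction. The Li
threshold is computed by exhaustive scan over the distinct intensities of
the histogram (deterministic and exactly the criterion minimum; the
classical iterative update reaches the same partition, which a test
verifies against scikit-image). Exact zeros are excluded from the
histogram by default: in a clamped difference image they encode "no
signal" and their mass would dominate the criterion. Thresholding is
global over the ROI, not per slice.

Bone: 3×3×3 box average of the sub-edge stack → gray→µ → µ ≥ 4.74 cm⁻¹,
minus the vascular mask. Vessel and bone masks are disjoint by
construction.

## Morphometry

Connectivity is 26 for foreground, 6 for background. The skeleton is
obtained by homotopy-preserving 3D thinning (scikit-image), then decomposed
into junction clusters (voxels with ≥3 skeleton neighbours, merged under
26-connectivity), branches, and free ends. Two cleanups make the segment
count robust: junction clusters joined by exactly two branches (thinning
corner artifacts, not true bifurcations) are spliced away, and free-ended
spurs shorter than 2 voxels (configurable, logged) are pruned. An isolated
chain counts as one segment; a loop counts once. On tube networks built
from trees with well-separated branches the segment count equals the
generating edge count exactly.

Two sphere conventions, deliberately distinct:

* **V.D** uses the largest sphere *centred on the skeleton line* that stays
  inside the vascular space — diameter 2·(EDT − ½ voxel) sampled at
  skeleton voxels, averaged voxel-weighted (an open choice; a
  segment-weighted variant is easy to compute from the per-segment
  diameters). The covering-sphere alternative inflates junction voxels
  covered by a neighbouring branch's larger sphere and was measured to
  bias V.D by several µm on dense networks.
* **B.Th** uses covering-sphere local thickness (Hildebrand–Rüegsegger):
  the diameter of the largest sphere contained in the structure that
  covers each voxel, averaged over all structure voxels
  (structure-volume-weighted). Implementation: sweep candidate radii of
  the distance transform from large to small, marking coverage via one
  EDT per radius; radii are quantised to ¼ voxel, so the diameter error is
  at most half a voxel on top of digitisation. The surface convention
  (inscribed radius = EDT − ½) makes a single isolated voxel measure one
  voxel thick and a digital 20-voxel cylinder 19–20 voxels.

Size-specific quantities: each segment is classed by its mean centred-sphere
diameter into half-open bins (<10, [10,20), [20,30), [30,40), ≥40 µm); each
vascular voxel inherits the class of the segment owning its nearest
skeleton voxel. The per-class V.Vf and V.Seg therefore partition the totals
exactly, on every input. Note that digital diameters quantise roughly one
voxel low, so a tube generated exactly on a class edge (e.g. 20 µm) may
fall in the class below; validation fixtures use mid-class calibres.

## Density distribution

Per-voxel d.HAp is read off the box-averaged 17.9 keV stack through the
calibration and histogrammed over the bone mask in 8 mg/cm³ bins anchored
at the 500 mg/cm³ segmentation floor ([500,508), [508,516), …), as
percentages of the bone volume above the floor. Group curves average
per-specimen histograms with equal specimen weight (pooling voxels is
available via `average_histograms` inputs).

## Statistics

Kruskal–Wallis (tie-corrected, χ² reference with k−1 df; identical data
returns H = 0, p = 1) across groups, followed by Dunn's pairwise z-tests on
the pooled ranks with tie correction, Bonferroni-adjusted over all
k(k−1)/2 pairs (Holm via flag); groups with n < 2 are excluded with a
warning. Paired t-tests are two-sided and error on zero-variance
differences. Significance is α = 0.05 two-sided; summaries report
mean ± SEM. Percent contrasts are 100·(ref−comp)/ref ("smaller") or
100·(comp−ref)/ref ("larger"), rounded to integers for reporting.
Partition checks pass at |Σ bins − total| ≤ 0.02 percentage points for
V.Vf and ≤ 1 /mm³ for V.Seg (the rounding tolerance of printed tables).

## The synthetic phantom

The generator emulates a rat tibial drill-hole specimen: a cortical wall
(1364 mg/cm³) pierced by a 780 µm hole, woven-bone islands (800 mg/cm³,
60 balls of 15–35 µm radius) regenerating inside, and branching vessel
trees. Twelve trees enter evenly around the ROI periphery (angiogenic
ingrowth), grow axially and inward within separate angular corridors so
that trees do not interpenetrate, and branch as binary trees (root
diameter 36 µm, child = parent × U(0.7, 0.95) clipped to ≥6 µm, fan angles
18–32°, branch lengths 70–130 µm, depth 4). The defaults produce V.Vf
≈ 4–4.5 %, V.Seg ≈ 2000–3000 /mm³ and vessel diameters spanning all five
classes — the magnitudes reported for these specimens at postoperative
days 5–10. Vessel attenuation defaults to 6 cm⁻¹ below and 60 cm⁻¹ above
the edge (the agent's attenuation is not published; both are
configurable); soft tissue is 0.8 cm⁻¹ at both energies.

Degradations, applied after rasterisation and never to the truth masks:
isotropic Gaussian blur (default σ = 2.74 µm, one voxel, a surrogate
point-spread function), additive Gaussian gray noise (default SD 2) with
clipping and 8-bit quantisation, and a rigid misalignment of the
low-energy stack (default (2, −1.5, 1) voxels and 0.2° axial — a
plausible stage return error). Segments rasterise as capsules
(hemispherical caps); radii below the voxel size warn and rasterise at
one-voxel thickness. Bone primitives with contradictory densities are
rejected; vessels take precedence over bone (the agent fills the lumen).

What the phantom does not emulate: projection physics (beam hardening,
phase contrast, reconstruction artifacts), incomplete or uneven vascular
filling, anastomoses and non-tree topology, marrow heterogeneity, and
spatially varying mineralisation. Passing recovery tests therefore shows
the chain is correct on geometrically clean, well-contrasted data — not
that real-scan accuracy matches.

Ground truth carries the masks, centerlines, per-segment radii and a
nearest-segment ownership label per vessel voxel; `truth_indices` computes
the reference indices directly from this geometry (B.Th/B.Seg are measured
on the truth bone mask, since no analytic form exists for unions of balls).

## Problem sizes used in validation

The test suite uses reduced phantoms — a 300 µm cylinder for segmentation
and pipeline tests, a 500 µm cylinder for registration-rotation and
full-chain recovery — chosen as the smallest geometries where each effect
under test is physically expressed. The acceptance script runs the full
study geometry (720 × 300 µm, ~12.6 M voxels).

## Known limitations

* **Volume-fraction bias of the subtraction segmentation.** Minimum
  cross-entropy thresholding of the smoothed difference image is
  deliberately inclusive: on noise-free phantoms the threshold lands at
  ~15–25 % of the vessel-core contrast, so the 3×3×3 box average leaves a
  sub-voxel partial-volume shell around every vessel inside the mask. For
  vessels of 4–15 voxel diameter this inflates V.Vf by ~30 % relative
  (measured: truth 4.07 % → recovered 5.53 % at full scale). A threshold
  near 50 % of core contrast would remove the bias (mask/truth volume
  ratio 0.98 when forced), but no reading of the cross-entropy criterion
  produces it on these histograms — the bias is a property of the
  published method, not of this implementation, and comparisons between
  groups analysed identically are unaffected. V.D is insensitive to it
  (the shell moves diameters by ~½ voxel, partially cancelled by digital
  quantisation); B.Vf is slightly eroded instead (threshold-side boundary
  loss at the bone edge).
* Segment densities on dense networks under-count relative to the
  generating tree when the dilated masks fuse nearby branches; the
  edge-count identity holds for well-separated branches only.
* The skeleton spur-pruning and junction-splicing heuristics are logged
  but not re-iterated to a fixed point; pathological thinning outputs
  could leave an off-by-one segment count.
* MI registration assumes overlapping content and fails on constant
  images (warned); accuracy was validated to ±5 voxels / ±2°, not beyond.
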