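# Methods

## The segmentation model

`mvseg` treats lumen segmentation as per-pixel binary classification,
performed coarse-to-fine by four independent 2D U-Nets:

1. a **coarse localizer** applied to axial slices downsampled ×4 in-plane,
   whose thresholded output only has to place a bounding box around the
   vessel;
2. three **single-view segmenters** applied to the axial, sagittal, and
   coronal slices of a fixed-size cuboid cropped around that box at ×2
   resolution.

The cuboid centre is the centre of the coarse mask's bounding box (not the
centroid — the box is what the localization stage produces, and its centre
is robust to asymmetric over-segmentation along the vessel). In-plane
coordinates scale by coarse_factor / working_factor = 2 between the two
grids; the slice axis is unscaled because downsampling is in-plane only.

Each 2D network is a classic U-Net: two 3×3 conv + ReLU layers per level,
2×2 max pooling, channel doubling per level, 2×2 transposed-conv
upsampling with skip concatenation, and a 1×1 sigmoid head. Depth and
width are configurable; input height/width must be divisible by 2^depth.
The head bias starts at logit(0.01), the standard imbalance-aware
initialization for a thin foreground class. The implementation is plain
NumPy with exact analytic gradients (verified against float64 finite
differences in the development suite) — at the problem sizes used here a
few GEMMs per convolution are fast enough on one CPU, and the absence of
framework nondeterminism makes every training run bit-reproducible from
its seed.

Assumptions inherited from the design: one bright, roughly tubular,
connected target per scan; axis-aligned acquisition; contrast filling that
keeps the lumen inside the display window.

## Preprocessing

* **Resampling** to a common voxel size with linear interpolation for
  intensities and nearest-neighbour for labels (labels must stay binary).
  Output grid size is `round(n·old/new)` per axis, preserving physical
  extent to within one voxel. The full-scale default, 0.62 mm slices and
  0.73 mm pixels, matches the median geometry of clinical CTA.
* **Windowing**: the interval [level − width/2, level + width/2] maps
  linearly onto [0, 255] and clamps outside — standard radiological window
  semantics; defaults level 200 HU, width 800 HU, i.e. [−200, 600] HU.
  Networks consume these grey values divided by 255.
* **Downsampling** in-plane by integer factor: block averaging for
  intensities/probabilities, block-centre subsampling for labels.
* **Augmentation**: one rotation/shift/zoom triple drawn uniformly per
  slice per mini-batch, applied identically to image (linear) and mask
  (nearest), out-of-bounds filled with 0 (the post-window background).
  Full-scale default ranges: coarse ±10°, ±20/±22 px, zoom [0.85, 1.15];
  single-view ±7°, ±22 px (x), ±22 px axial / ±72 px sagittal-coronal (y),
  same zoom.

## Training

Binary cross-entropy on logits (log-sum-exp form), Adam (defaults:
lr 1e-4; batch 20 for the coarse stage, 10 for the single-view stages),
mini-batches sampled randomly from *all* training slices — slices with
empty masks included, since the networks must also learn to stay silent
above and below the vessel. Early stopping monitors un-augmented
validation loss with patience 15 and restores the best-epoch weights.

Single-view training data is cropped with cuboids derived from the trained
coarse model's own predictions, so the view networks see the same ROI
statistics at training and inference time; if localization fails on a
training case the ground-truth bounding box is used instead (logged).

## Binarization and fusion

Every probability map is binarized with a single global threshold chosen
to maximize mean per-case 3D Dice over the validation split, searched on a
0.05-step grid over (0, 1); ties go to the smallest threshold. Thresholds
are selected separately for the coarse stage, each view (after smoothing),
and each fusion rule that needs a final binarization.

Per-view probability stacks are smoothed with a 1D Gaussian (σ = 1 slice
by default) along the stacking axis of the view that produced them — the
direction in which the 2D predictions are independent, hence the one that
needs regularizing. Smoothing along each view's own axis (rather than
anatomical z for all three) is the package's reading; both make sense, and
σ = 0 disables it.

Fusion rules, per voxel: majority voting over the three binarized views;
plain averaging p = (p_ax + p_sag + p_cor)/3; and the combined rule —
exactly 1/0 where the binarized views are unanimous, the average
otherwise. Majority voting is already binary (its implied threshold is
0.5); the other two are thresholded with their validated final threshold.

**Paste-back** places the fused *probabilities* (not a quantized mask)
into the working grid, zero outside the cuboid, then resamples linearly to
the original scan grid before the final threshold. Thresholding after
interpolation recovers sub-voxel boundary placement that
nearest-neighbour upsampling of a binary mask would destroy; on desk-scale
tubes this is worth several Dice points and is a deliberate design choice.

## Synthetic phantoms

The generator emulates the geometry and contrast regime of
contrast-enhanced CTA of an aneurysmal aorta: a lumen tube swept as
spheres along a cubic-spline centerline (sampled every ≤ 0.5 voxel),
per-case random curvature and radius profile (5–7 mm), an optional
fusiform aneurysm bulge (radius ×1.3–1.8), an optional side branch, lumen
intensity uniform in [250, 450] HU over a [−50, 80] HU background, a
0.6-voxel Gaussian point-spread blur (partial-volume), additive Gaussian
noise (desk default 20 HU), and bright ellipsoidal **distractor blobs**
whose intensity lies in the lumen range but which are kept ≥ 2 voxels away
from the lumen — so any false positive on them is unambiguously a model
error, mimicking the prosthesis/adjacent-vessel failure modes seen in
clinical scans. Axial cross-sections of a distractor are nearly
indistinguishable from the lumen; the long-axis views are not, which is
precisely what multi-view fusion exploits.

What the phantoms do **not** model: organs and bone, beam hardening and
streak artifacts, thrombus, intensity inhomogeneity along the vessel, and
anatomical variability beyond smooth tubes. Passing the end-to-end test
therefore shows the pipeline's machinery is sound and that fusion behaves
as designed — not clinical-grade performance on real CTA.

## Evaluation metrics

Dice and Jaccard by exact voxel counting (both-empty pairs score 1.0 by
convention; one-empty pairs 0.0). Surface distances: a boundary voxel is a
foreground voxel with ≥ 1 face-adjacent (6-connected) background
neighbour, with out-of-volume treated as background; each boundary's exact
Euclidean distance map (scipy's EDT, the Maurer-type algorithm) is sampled
at the other mask's boundary voxels, voxel centre to voxel centre in
physical mm; mean, population std, and maximum are reported over the
symmetric (bidirectional) distance set. Distances are undefined (raised,
reported as NaN in batch reports) when either mask is empty.

## Desk-scale configuration

`desk_config()` is the package's own scaled-down study condition, chosen
once: phantoms 128×96×96 at 1 mm; 16/2/4 train/val/test; depth-2,
8-filter U-Nets; ROI 128×40×40 (full z — the in-plane grid is only 48
at working resolution, so a 40-voxel cuboid already excludes most
background); learning rate 1e-3 with 50 optimizer steps per epoch and 8
epochs (small networks on an easy contrast task converge in a few hundred
steps; 1e-4 would simply need proportionally more); augmentation scaled to
the small grids (±7°, ±2 px, zoom [0.9, 1.1]). A full train-and-evaluate
cycle takes about 5 minutes on one CPU.

## Numerical and degenerate-input choices

* Threshold grid 0.05-granular; tie-break to the smallest value.
* Validation-loss improvement tolerance 1e-9 for early stopping.
* Probability volumes are clipped to [0, 1] after smoothing, averaging,
  and resampling (interpolation can overshoot).
* Coarse localization with no voxel above threshold raises a
  `LocalizationError` carrying the maximum probability seen.
* Oblique direction cosines in input files are not reoriented, only
  warned about; phantoms are axis-aligned.
* File round-trips preserve label values exactly (uint8 on disk) and
  spacing to float32 precision (~1e-7 relative), the NIfTI header's own
  limit.

## Known limitations

* The NumPy networks are CPU-only and desk-scale; full-resolution clinical
  grids (512×512×~700) would need hours per epoch and are out of scope.
* The phantom realism gap above: results on phantoms bound nothing about
  clinical accuracy.
* Single-component assumption: the pipeline keeps everything inside one
  cuboid; pathology outside it (or a failed localization) is unrecoverable
  by design, matching the cascade's intent.
* Only binary lumen segmentation; no thrombus or multi-class output.
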