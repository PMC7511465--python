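"""Coarse-to-fine orchestration: localization, cuboid ROI, per-view
segmentation, stack smoothing, and multi-view fusion.

The inference path is: preprocess the scan (resample, HU window), coarsely
segment the lumen on the x4 in-plane downsampled axial slices, take the
bounding-box centre of that coarse mask, crop a fixed-size cuboid around it at
working (x2) resolution, segment the cuboid from the axial, sagittal, and
coronal views, smooth each view's probability stack along its stacking axis,
fuse the three maps, and threshold.  The fused probabilities are pasted back
into the working grid and resampled to the original scan grid before the final
threshold, so the output mask lives on the input grid; everything outside the
cuboid is background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import apply_window, downsample_inplane, resample_volume
from .segnet import TrainedModel, predict_stack
from .views import STACK_AXIS, ViewStack, slice_views  # noqa: F401  (re-export)
from .volume import Volume

logger = logging.getLogger(__name__)

FUSION_MODES = ("majority", "average", "combined")

DEFAULT_ROI_SIZE = (480, 144, 144)


class LocalizationError(RuntimeError):
    """Coarse localization produced no foreground at the given threshold."""


@dataclass(frozen=True)
class CuboidROI:
    """A fixed-size axis-aligned crop at working resolution.

    ``center`` and ``start`` are voxel coordinates on the working grid
    (``start`` may be negative when the cuboid was zero-padded at an edge);
    ``source_factor`` is the in-plane scale between the coarse grid the centre
    was found on and the working grid.
    """

    center: tuple[int, int, int]
    size: tuple[int, int, int]
    start: tuple[int, int, int]
    source_shape: tuple[int, int, int]
    source_factor: int = 2

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError(f"ROI size must be positive, got {self.size}")
        if not all(0 <= c < n for c, n in zip(self.center, self.source_shape)):
            raise ValueError(
                f"ROI centre {self.center} outside working grid {self.source_shape}"
            )


def coarse_localize(
    scan: Volume, coarse_model: TrainedModel, threshold: float
) -> Volume:
    """Binary coarse lumen mask from per-axial-slice prediction.

    ``scan`` must already be preprocessed (windowed) and downsampled to the
    coarse grid the model was trained on.
    """
    axial, _, _ = slice_views(scan)
    prob = predict_stack(coarse_model, axial)
    mask = (prob.data >= threshold).astype(np.uint8)
    if not mask.any():
        raise LocalizationError(
            f"no foreground at threshold {threshold} "
            f"(max probability {float(prob.data.max()):.4f})"
        )
    return prob.with_data(mask, role="label")


def bounding_box(
    mask: Volume,
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Tight inclusive (min, max) voxel bounds of the nonzero region."""
    nz = np.nonzero(mask.data)
    if len(nz[0]) == 0:
        raise ValueError("bounding_box of an empty mask is undefined")
    lo = tuple(int(a.min()) for a in nz)
    hi = tuple(int(a.max()) for a in nz)
    return lo, hi


def extract_roi(
    scan_fine: Volume,
    coarse_mask: Volume,
    roi_size: tuple[int, int, int] = DEFAULT_ROI_SIZE,
    inplane_scale: int = 2,
) -> tuple[Volume, CuboidROI]:
    """Crop a fixed-size cuboid of the working-resolution scan around the
    coarse mask.

    The cuboid centre is the bounding-box centre of the coarse mask, with
    in-plane (y, x) coordinates scaled by ``inplane_scale`` (the coarse /
    working downsample ratio; the slice axis is unscaled because downsampling
    is in-plane only).  Regions outside the scan are zero-padded so the crop
    is exactly ``roi_size``.
    """
    lo, hi = bounding_box(coarse_mask)
    center = [(a + b) // 2 for a, b in zip(lo, hi)]
    center[1] *= inplane_scale
    center[2] *= inplane_scale
    center = tuple(
        int(np.clip(c, 0, n - 1)) for c, n in zip(center, scan_fine.shape)
    )
    start = tuple(c - s // 2 for c, s in zip(center, roi_size))
    roi = CuboidROI(
        center=center,
        size=tuple(int(s) for s in roi_size),
        start=start,
        source_shape=scan_fine.shape,
        source_factor=inplane_scale,
    )
    out = np.zeros(roi.size, dtype=scan_fine.data.dtype)
    src, dst = [], []
    for a in range(3):
        s0 = max(start[a], 0)
        s1 = min(start[a] + roi.size[a], scan_fine.shape[a])
        if s1 <= s0:
            raise ValueError("ROI lies entirely outside the scan")
        src.append(slice(s0, s1))
        dst.append(slice(s0 - start[a], s1 - start[a]))
    out[tuple(dst)] = scan_fine.data[tuple(src)]
    return (
        Volume(out, scan_fine.spacing, scan_fine.origin, scan_fine.role),
        roi,
    )


def paste_back(data: np.ndarray, roi: CuboidROI) -> np.ndarray:
    """Place cuboid-grid data back into a zero background on the working grid."""
    if tuple(data.shape) != roi.size:
        raise ValueError(f"data shape {data.shape} does not match ROI {roi.size}")
    out = np.zeros(roi.source_shape, dtype=data.dtype)
    for_src, for_dst = [], []
    for a in range(3):
        s0 = max(roi.start[a], 0)
        s1 = min(roi.start[a] + roi.size[a], roi.source_shape[a])
        for_dst.append(slice(s0, s1))
        for_src.append(slice(s0 - roi.start[a], s1 - roi.start[a]))
    out[tuple(for_dst)] = data[tuple(for_src)]
    return out


def smooth_stack(prob: Volume, axis: str, sigma: float) -> Volume:
    """1D Gaussian smoothing along the stacking axis of the producing view.

    Regularizes the slice-to-slice independence of 2D predictions; sigma is in
    slices, sigma 0 is the identity.  Output is clipped to [0, 1].
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if prob.role != "probability":
        raise ValueError("smooth_stack expects a probability volume")
    if sigma == 0:
        return prob.with_data(prob.data.copy())
    out = ndimage.gaussian_filter1d(
        prob.data.astype(np.float32), sigma, axis=STACK_AXIS[axis], mode="nearest"
    )
    return prob.with_data(np.clip(out, 0.0, 1.0))


# -- fusion rules -------------------------------------------------------------


def _check_three(volumes, role) -> None:
    if len(volumes) != 3:
        raise ValueError(f"expected exactly 3 volumes, got {len(volumes)}")
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among fused volumes: {shapes}")
    for v in volumes:
        if v.role != role:
            raise ValueError(f"expected {role} volumes, got {v.role}")


def majority_vote(masks: list[Volume]) -> Volume:
    """Per voxel, the label held by at least 2 of the 3 binary masks."""
    _check_three(masks, "label")
    votes = sum(m.data.astype(np.uint8) for m in masks)
    return masks[0].with_data((votes >= 2).astype(np.uint8), role="label")


def average_probs(probs: list[Volume]) -> Volume:
    """Equal-weight mean of the three per-view probability maps."""
    _check_three(probs, "probability")
    mean = sum(p.data.astype(np.float32) for p in probs) / 3.0
    return probs[0].with_data(np.clip(mean, 0.0, 1.0), role="probability")


def combined_fusion(probs: list[Volume], view_thresholds: list[float]) -> Volume:
    """Majority voting integrated with averaging.

    Each view's map is binarized with its own validated threshold; where all
    three labels agree the fused probability is exactly 1 (lumen) or 0
    (background), otherwise it is the plain three-view average.
    """
    _check_three(probs, "probability")
    if len(view_thresholds) != 3:
        raise ValueError("need one threshold per view")
    if any(not 0 < t < 1 for t in view_thresholds):
        raise ValueError("view thresholds must lie in (0, 1)")
    labels = [p.data >= t for p, t in zip(probs, view_thresholds)]
    votes = sum(lab.astype(np.uint8) for lab in labels)
    fused = average_probs(probs).data
    fused = np.where(votes == 3, 1.0, fused)
    fused = np.where(votes == 0, 0.0, fused)
    return probs[0].with_data(fused.astype(np.float32), role="probability")


# -- end-to-end inference ------------------------------------------------------


def _zoom_to_shape(data: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    if tuple(data.shape) == tuple(shape):
        return data
    zoom = [t / s for t, s in zip(shape, data.shape)]
    return ndimage.zoom(
        data.astype(np.float32),
        zoom,
        order=1,
        mode="grid-constant",
        grid_mode=True,
        cval=0.0,
    )


def predict_views(
    scan: Volume,
    models: dict[str, TrainedModel],
    coarse_threshold: float,
    sigma: float = 1.0,
    target_spacing: tuple[float, float, float] | None = None,
    window_level: float = 200.0,
    window_width: float = 800.0,
    coarse_factor: int = 4,
    working_factor: int = 2,
    roi_size: tuple[int, int, int] = DEFAULT_ROI_SIZE,
) -> tuple[dict[str, Volume], CuboidROI, tuple[int, int, int]]:
    """Stages 1-3 of inference: preprocess, localize, crop, per-view predict.

    Returns the smoothed per-view probability volumes on the ROI grid, the
    cuboid record, and the preprocessed-grid shape needed for paste-back.
    """
    for key in ("coarse", "axial", "sagittal", "coronal"):
        if key not in models:
            raise ValueError(f"missing model {key!r}")
    logger.info("preprocess: resample + window %s/%s HU", window_level, window_width)
    pre = scan
    if target_spacing is not None:
        pre = resample_volume(pre, target_spacing, interp="linear")
    pre = apply_window(pre, window_level, window_width)
    coarse_scan = downsample_inplane(pre, coarse_factor)
    working_scan = downsample_inplane(pre, working_factor)

    logger.info("coarse localization on grid %s", coarse_scan.shape)
    coarse_mask = coarse_localize(coarse_scan, models["coarse"], coarse_threshold)

    roi_scan, roi = extract_roi(
        working_scan,
        coarse_mask,
        roi_size=roi_size,
        inplane_scale=coarse_factor // working_factor,
    )
    logger.info("ROI %s at centre %s", roi.size, roi.center)

    axial, sagittal, coronal = slice_views(roi_scan)
    probs = {}
    for stack in (axial, sagittal, coronal):
        raw = predict_stack(models[stack.axis], stack)
        probs[stack.axis] = smooth_stack(raw, stack.axis, sigma)
    return probs, roi, pre.shape


def prob_to_scan_grid(
    prob_roi: Volume, roi: CuboidROI, pre_shape: tuple[int, int, int], scan: Volume
) -> Volume:
    """Paste an ROI-grid probability map back and resample to the scan grid.

    The probabilities (not a quantized mask) are interpolated, so the final
    threshold acts at the input resolution; outside the cuboid everything is
    background.
    """
    working = paste_back(prob_roi.data.astype(np.float32), roi)
    full = _zoom_to_shape(_zoom_to_shape(working, pre_shape), scan.shape)
    return Volume(
        np.clip(full, 0.0, 1.0), scan.spacing, scan.origin, role="probability"
    )


def fuse_views(
    probs: dict[str, Volume],
    fusion: str,
    view_thresholds: dict[str, float],
) -> tuple[Volume, float | None]:
    """Apply one fusion rule to the smoothed per-view maps.

    Returns a probability volume plus the binarization threshold implied by
    the rule (0.5 for majority voting, whose output is already {0, 1}; None
    for the others, where the caller supplies a validated final threshold).
    """
    if fusion not in FUSION_MODES:
        raise ValueError(f"fusion must be one of {FUSION_MODES}, got {fusion!r}")
    ordered = [probs["axial"], probs["sagittal"], probs["coronal"]]
    thr = [view_thresholds[k] for k in ("axial", "sagittal", "coronal")]
    if fusion == "majority":
        labels = [
            p.with_data((p.data >= t).astype(np.uint8), role="label")
            for p, t in zip(ordered, thr)
        ]
        voted = majority_vote(labels)
        return voted.with_data(voted.data.astype(np.float32), role="probability"), 0.5
    if fusion == "average":
        return average_probs(ordered), None
    return combined_fusion(ordered, thr), None


def run_pipeline(
    scan: Volume,
    models: dict[str, TrainedModel],
    thresholds: dict[str, float],
    fusion: str = "combined",
    sigma: float = 1.0,
    target_spacing: tuple[float, float, float] | None = None,
    window_level: float = 200.0,
    window_width: float = 800.0,
    coarse_factor: int = 4,
    working_factor: int = 2,
    roi_size: tuple[int, int, int] = DEFAULT_ROI_SIZE,
) -> Volume:
    """Full-scan segmentation; returns a binary mask on the input scan grid.

    ``models`` maps ``coarse``/``axial``/``sagittal``/``coronal`` to trained
    networks; ``thresholds`` holds the validated binarization threshold for
    each of those stages plus ``final`` for the fused map (ignored by the
    majority rule, which is already binary).
    """
    if fusion not in FUSION_MODES:
        raise ValueError(f"fusion must be one of {FUSION_MODES}, got {fusion!r}")
    probs, roi, pre_shape = predict_views(
        scan,
        models,
        thresholds["coarse"],
        sigma=sigma,
        target_spacing=target_spacing,
        window_level=window_level,
        window_width=window_width,
        coarse_factor=coarse_factor,
        working_factor=working_factor,
        roi_size=roi_size,
    )
    logger.info("fusing views with %r rule", fusion)
    fused, implied_threshold = fuse_views(
        probs,
        fusion,
        {k: thresholds[k] for k in ("axial", "sagittal", "coronal")},
    )
    final_threshold = (
        implied_threshold if implied_threshold is not None else thresholds["final"]
    )
    full_prob = prob_to_scan_grid(fused, roi, pre_shape, scan)
    mask = (full_prob.data >= final_threshold).astype(np.uint8)
    return Volume(mask, scan.spacing, scan.origin, role="label")
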