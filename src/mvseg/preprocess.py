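"""Voxel-size normalization, HU windowing, downsampling and 2D augmentation.

A CTA scan is prepared for the networks in this order: resample to a common
voxel size, map a Hounsfield window linearly onto [0, 255], then produce the
coarse (x4 in-plane) and working (x2 in-plane) grids.  Slice-level
augmentation (rotation, shift, zoom) is applied on the fly during training,
identically to the image and its mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume


@dataclass(frozen=True)
class AugmentParams:
    """Uniform sampling intervals for slice augmentation.

    Angles in degrees, shifts in pixels (x = in-slice columns, y = rows),
    zoom as a scale factor applied about the slice centre.
    """

    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    shift_x_px: tuple[float, float] = (-20.0, 20.0)
    shift_y_px: tuple[float, float] = (-22.0, 22.0)
    zoom: tuple[float, float] = (0.85, 1.15)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "shift_x_px", "shift_y_px", "zoom"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval has lo > hi: ({lo}, {hi})")
        if self.zoom[0] <= 0:
            raise ValueError("zoom interval must be strictly positive")


def resample_volume(
    v: Volume,
    target_spacing: tuple[float, float, float],
    interp: str = "linear",
) -> Volume:
    """Resample onto a new voxel size, preserving the physical extent.

    The output grid has ``new_n = round(old_n * old_spacing / new_spacing)``
    voxels per axis, so the extent is preserved to within one output voxel.
    Label volumes must use nearest interpolation and stay binary.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    if v.role == "label" and interp != "nearest":
        raise ValueError("label volumes must be resampled with nearest interpolation")
    target_spacing = tuple(float(s) for s in target_spacing)
    if target_spacing == v.spacing:
        return Volume(v.data.copy(), target_spacing, v.origin, v.role)
    new_shape = tuple(
        max(1, round(n * sp / tsp))
        for n, sp, tsp in zip(v.shape, v.spacing, target_spacing)
    )
    zoom = [ns / n for ns, n in zip(new_shape, v.shape)]
    order = 1 if interp == "linear" else 0
    out = ndimage.zoom(
        v.data.astype(np.float32, copy=False),
        zoom,
        order=order,
        mode="grid-constant",
        grid_mode=True,
        cval=0.0,
    )
    if v.role == "label":
        out = (out > 0.5).astype(np.uint8)
    return Volume(out, target_spacing, v.origin, v.role)


def apply_window(v: Volume, level: float = 200.0, width: float = 800.0) -> Volume:
    """Map the HU window [level - width/2, level + width/2] onto [0, 255].

    Values outside the window clamp to 0 or 255.  The default 200/800 window
    brightens contrast-enhanced lumen while keeping soft tissue visible.
    """
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    if v.role != "intensity":
        raise ValueError(f"apply_window expects an intensity volume, got {v.role}")
    lo = level - width / 2.0
    out = (v.data.astype(np.float32) - lo) * (255.0 / width)
    np.clip(out, 0.0, 255.0, out=out)
    return v.with_data(out)


def downsample_inplane(v: Volume, factor: int) -> Volume:
    """Reduce the in-plane (y, x) resolution by an integer factor.

    Intensities and probabilities are block-averaged; labels are subsampled at
    block centres so they remain binary.  Axes not divisible by the factor are
    zero-padded symmetrically to the next multiple first.  In-plane spacing is
    multiplied by the factor; the slice axis is untouched.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return Volume(v.data.copy(), v.spacing, v.origin, v.role)
    data = v.data
    nz, ny, nx = data.shape
    pad_y = (-ny) % factor
    pad_x = (-nx) % factor
    if pad_y or pad_x:
        data = np.pad(
            data,
            (
                (0, 0),
                (pad_y // 2, pad_y - pad_y // 2),
                (pad_x // 2, pad_x - pad_x // 2),
            ),
        )
        ny, nx = data.shape[1:]
    if v.role == "label":
        off = factor // 2
        out = data[:, off::factor, off::factor].astype(np.uint8)
    else:
        out = (
            data.astype(np.float32)
            .reshape(nz, ny // factor, factor, nx // factor, factor)
            .mean(axis=(2, 4))
        )
        if v.role == "probability":
            out = np.clip(out, 0.0, 1.0)
    sz, sy, sx = v.spacing
    return Volume(out, (sz, sy * factor, sx * factor), v.origin, v.role)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    params: AugmentParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random rotation / shift / zoom to a slice and its mask.

    A single transform is drawn uniformly from the parameter intervals and
    applied to both inputs: linear interpolation for the image, nearest for
    the mask (so it stays binary).  Out-of-bounds regions fill with 0.
    Deterministic for a given ``params.seed`` when ``rng`` is not supplied.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    angle = np.deg2rad(rng.uniform(*params.rotation_deg))
    shift_x = rng.uniform(*params.shift_x_px)
    shift_y = rng.uniform(*params.shift_y_px)
    zoom = rng.uniform(*params.zoom)

    if angle == 0.0 and shift_x == 0.0 and shift_y == 0.0 and zoom == 1.0:
        return image.copy(), mask.copy()

    # Output (row, col) -> input coords: rotate and zoom about the slice
    # centre, then translate.  scipy's affine_transform maps output to input
    # as i = M @ o + offset.
    c, s = np.cos(angle), np.sin(angle)
    m = np.array([[c, -s], [s, c]]) / zoom
    centre = (np.asarray(image.shape) - 1) / 2.0
    shift = np.array([shift_y, shift_x])
    offset = centre - m @ (centre + shift)
    img_out = ndimage.affine_transform(
        image.astype(np.float32), m, offset=offset, order=1, mode="constant", cval=0.0
    )
    mask_out = ndimage.affine_transform(
        mask, m, offset=offset, order=0, mode="constant", cval=0
    )
    return img_out, mask_out
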