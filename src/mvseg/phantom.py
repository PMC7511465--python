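"""Synthetic contrast-enhanced vascular phantoms with ground-truth masks.

Each phantom is a bright tube (the contrast-filled lumen, ~250-450 HU) swept
along a smooth spline centerline through a darker soft-tissue background,
optionally with a fusiform bulge (aneurysm), short side branches, and bright
distractor blobs whose intensity lies in the lumen range but which never touch
the lumen — so any false positive on them is attributable to the model, not to
label noise.  A Gaussian point-spread blur and additive HU noise emulate
scanner partial-volume and quantum noise.

The generator is the package's stand-in for clinical angiography data: it
reproduces the geometry and contrast regime the pipeline is built for, at desk
scale, with exact ground truth and bit-reproducibility from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .volume import Volume, write_volume


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of one synthetic phantom.

    Coordinates are voxel indices in ``(z, y, x)`` order; radii and lengths
    are in mm.  ``aneurysm`` is ``(center_fraction_along_centerline,
    bulge_factor >= 1)``; each branch is ``(attach_fraction, direction_zyx,
    length_mm, radius_mm)``.
    """

    shape: tuple[int, int, int] = (128, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    centerline_ctrl_points: tuple[tuple[float, float, float], ...] = (
        (8.0, 48.0, 48.0),
        (40.0, 54.0, 42.0),
        (72.0, 44.0, 52.0),
        (104.0, 50.0, 46.0),
        (120.0, 48.0, 48.0),
    )
    radius_profile: tuple[float, ...] = (6.0, 6.0, 6.0, 6.0, 6.0)
    aneurysm: tuple[float, float] | None = None
    branches: tuple[tuple[float, tuple[float, float, float], float, float], ...] = ()
    lumen_hu: tuple[float, float] = (250.0, 450.0)
    background_hu: tuple[float, float] = (-50.0, 80.0)
    distractors: int = 0
    noise_sd: float = 0.0
    psf_sigma_vox: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.centerline_ctrl_points) < 4:
            raise ValueError("centerline needs at least 4 control points")
        if len(self.radius_profile) != len(self.centerline_ctrl_points):
            raise ValueError("radius_profile must match centerline control points")
        if any(r <= 0 for r in self.radius_profile):
            raise ValueError("radii must be positive")
        if self.aneurysm is not None and self.aneurysm[1] < 1:
            raise ValueError("aneurysm bulge factor must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for frac, _, length, radius in self.branches:
            if not 0 <= frac <= 1:
                raise ValueError("branch attach fraction must be in [0, 1]")
            if length <= 0 or radius <= 0:
                raise ValueError("branch length and radius must be positive")


def _sample_centerline(
    ctrl: np.ndarray, radii: np.ndarray, max_step_vox: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Densely sample a cubic-spline centerline and its radius profile.

    Returns points (n, 3) in voxel coords and per-point radii (mm), with
    consecutive samples at most ``max_step_vox`` voxels apart.
    """
    t = np.linspace(0.0, 1.0, len(ctrl))
    spline = CubicSpline(t, ctrl, axis=0)
    rad = CubicSpline(t, radii)
    # estimate arc length on a fine grid, then sample uniformly in arc length
    tf = np.linspace(0.0, 1.0, 20 * len(ctrl))
    pts = spline(tf)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = float(seg.sum())
    n = max(int(np.ceil(arclen / max_step_vox)) + 1, 2)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    ts = np.interp(np.linspace(0.0, arclen, n), cum, tf)
    return spline(ts), np.maximum(rad(ts), 1e-3)


def _sweep_tube(
    label: np.ndarray,
    points: np.ndarray,
    radii_mm: np.ndarray,
    spacing: tuple[float, float, float],
) -> None:
    """Mark all voxels whose centre lies within radius of any sample point."""
    shape = np.asarray(label.shape)
    sp = np.asarray(spacing, dtype=float)
    r_vox = radii_mm[:, None] / sp[None, :]  # per-point radius in voxels, per axis
    if (points - r_vox < -0.5).any() or (points + r_vox > shape - 0.5).any():
        raise ValueError(
            "tube exceeds volume bounds; enlarge the grid or shrink the tube"
        )
    for p, r in zip(points, radii_mm):
        rv = r / sp
        lo = np.maximum(np.floor(p - rv).astype(int), 0)
        hi = np.minimum(np.ceil(p + rv).astype(int) + 1, shape)
        grids = np.meshgrid(
            *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
        )
        d2 = sum(((g - p[a]) * sp[a]) ** 2 for a, g in enumerate(grids))
        sub = label[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub |= d2 <= r * r


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Build one phantom; returns (intensity volume in HU, binary lumen mask).

    Deterministic for a given ``spec.seed``.  When branches attach to the main
    tube the mask is a single connected component by construction.
    """
    rng = np.random.default_rng(spec.seed)
    label = np.zeros(spec.shape, dtype=bool)

    ctrl = np.asarray(spec.centerline_ctrl_points, dtype=float)
    radii = np.asarray(spec.radius_profile, dtype=float)
    points, r_mm = _sample_centerline(ctrl, radii)

    if spec.aneurysm is not None:
        frac, bulge = spec.aneurysm
        s = np.linspace(0.0, 1.0, len(points))
        # fusiform dilation: smooth radial bump centred at `frac`
        r_mm = r_mm * (1.0 + (bulge - 1.0) * np.exp(-((s - frac) ** 2) / (2 * 0.08**2)))

    _sweep_tube(label, points, r_mm, spec.spacing)

    for frac, direction, length_mm, radius_mm in spec.branches:
        idx = int(round(frac * (len(points) - 1)))
        start = points[idx]
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        sp = np.asarray(spec.spacing)
        n = max(int(np.ceil(length_mm / 0.5)) + 1, 2)
        # straight branch sampled every <=0.5 mm, converted to voxel steps
        bpts = start[None, :] + np.linspace(0, length_mm, n)[:, None] * d[None, :] / sp
        _sweep_tube(label, bpts, np.full(n, radius_mm), spec.spacing)

    lumen_val = rng.uniform(*spec.lumen_hu)
    background_val = rng.uniform(*spec.background_hu)
    intensity = np.full(spec.shape, background_val, dtype=np.float32)
    intensity[label] = lumen_val

    # distractor blobs: bright ellipsoids in the lumen HU range, kept clear of
    # the lumen (>= 2 voxel margin) so they never overlap the ground truth
    margin = ndimage.binary_dilation(label, iterations=2)
    placed = 0
    attempts = 0
    shape = np.asarray(spec.shape)
    while placed < spec.distractors and attempts < 200 * max(spec.distractors, 1):
        attempts += 1
        centre = rng.uniform(6, shape - 6)
        radii_vox = rng.uniform(2.0, 4.5, size=3)
        lo = np.maximum(np.floor(centre - radii_vox).astype(int), 0)
        hi = np.minimum(np.ceil(centre + radii_vox).astype(int) + 1, shape)
        grids = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
        blob = (
            sum(((g - centre[a]) / radii_vox[a]) ** 2 for a, g in enumerate(grids))
            <= 1.0
        )
        region = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        if (blob & margin[region]).any():
            continue
        vals = np.where(blob, rng.uniform(*spec.lumen_hu), intensity[region])
        intensity[region] = vals.astype(np.float32)
        placed += 1

    if spec.psf_sigma_vox > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.psf_sigma_vox)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, spec.shape).astype(
            np.float32
        )

    img = Volume(intensity.astype(np.float32), spec.spacing, role="intensity")
    msk = Volume(label.astype(np.uint8), spec.spacing, role="label")
    return img, msk


def random_spec(base: PhantomSpec, seed: int) -> PhantomSpec:
    """Randomize centerline curvature, radii, aneurysm and branches of a spec.

    Used by :func:`generate_dataset` to give each case its own anatomy while
    keeping the intensity regime of the base spec.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = base.shape
    n_ctrl = 5
    radii = tuple(float(r) for r in rng.uniform(5.0, 7.0, n_ctrl))
    # end caps need one radius of clearance along z
    z_margin = max(0.07 * nz, max(radii) / base.spacing[0] + 1.0)
    z = np.linspace(z_margin, nz - 1 - z_margin, n_ctrl)
    wander = min(ny, nx) * 0.12
    y = ny / 2 + rng.uniform(-wander, wander, n_ctrl)
    x = nx / 2 + rng.uniform(-wander, wander, n_ctrl)
    ctrl = tuple((float(zi), float(yi), float(xi)) for zi, yi, xi in zip(z, y, x))
    aneurysm = None
    if rng.random() < 0.5:
        aneurysm = (float(rng.uniform(0.3, 0.7)), float(rng.uniform(1.3, 1.8)))
    branches = ()
    if rng.random() < 0.5:
        frac = float(rng.uniform(0.25, 0.75))
        direction = rng.normal(size=3)
        direction[0] *= 0.3  # mostly lateral, like renal/visceral branches
        direction = tuple(float(d) for d in direction / np.linalg.norm(direction))
        # branch length scales with the in-plane field of view so the tube
        # always stays inside the grid
        length = float(rng.uniform(0.10, 0.17) * min(ny, nx) * min(base.spacing[1:]))
        branches = ((frac, direction, length, 2.5),)
    return replace(
        base,
        centerline_ctrl_points=ctrl,
        radius_profile=radii,
        aneurysm=aneurysm,
        branches=branches,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n_train: int,
    n_val: int,
    n_test: int,
    base_spec: PhantomSpec,
    seed: int,
    out_dir: str | Path,
) -> dict:
    """Write a train/val/test phantom dataset plus a JSON manifest.

    Each case gets randomized anatomy (curvature, radii, aneurysm presence,
    branches) derived deterministically from ``seed``.  Returns the manifest
    dict; the same call always reproduces identical files.
    """
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("all split counts must be >= 1")
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise FileNotFoundError(f"directory {out_dir.parent} does not exist")
    out_dir.mkdir(exist_ok=True)
    root = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(n_train + n_val + n_test)]
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    manifest = {"seed": int(seed), "cases": []}
    for i, (split, cseed) in enumerate(zip(splits, case_seeds)):
        spec = random_spec(base_spec, cseed)
        img, msk = generate_phantom(spec)
        case_id = f"case_{i:03d}"
        img_path = out_dir / f"{case_id}_image.nii.gz"
        msk_path = out_dir / f"{case_id}_mask.nii.gz"
        write_volume(img, img_path)
        write_volume(msk, msk_path)
        manifest["cases"].append(
            {
                "case_id": case_id,
                "split": split,
                "image": img_path.name,
                "mask": msk_path.name,
                "seed": int(cseed),
            }
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
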