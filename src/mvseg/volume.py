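"""Volumetric image container and file I/O.

The package-wide convention is a 3D array indexed ``(z, y, x)`` with 0-based
indices: ``data[k]`` is the k-th axial slice, ``data[:, j, :]`` the j-th
coronal slice, ``data[:, :, i]`` the i-th sagittal slice.  Per-axis voxel
spacing and origin are carried in millimetres in the same ``(z, y, x)`` order.

Files are read and written through SimpleITK, which supports NIfTI-1
(``.nii``/``.nii.gz``) and MetaImage (``.mhd``/``.mha``).  SimpleITK reports
spacing and origin in ``(x, y, z)`` order; both are reversed on the way in and
out.  Direction cosines other than identity are not reoriented — a warning is
logged for oblique inputs (all synthetic phantoms are axis-aligned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

ROLES = ("intensity", "probability", "label")

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mhd", ".mha")


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``.
    spacing:
        Voxel size ``(sz, sy, sx)`` in mm, all strictly positive.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in mm, ``(oz, oy, ox)``.
    role:
        What the scalars mean: ``intensity`` (HU or windowed grey values),
        ``probability`` (values in [0, 1]) or ``label`` (binary {0, 1}).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) == 0:
            raise ValueError(
                f"Volume data must be non-empty 3D, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role == "probability":
            if self.data.min() < 0 or self.data.max() > 1:
                raise ValueError("probability volume has values outside [0, 1]")
        if self.role == "label":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("label volume has values outside {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, role: str | None = None) -> "Volume":
        """Copy of this volume with new voxel data (same grid metadata)."""
        return replace(self, data=data, role=role or self.role)


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported file format {path.name!r}; "
            f"expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path: str | Path, role: str = "intensity") -> Volume:
    """Read a NIfTI or MetaImage file into a :class:`Volume`.

    ``role`` declares how the scalars are to be interpreted (the formats carry
    no such notion); label volumes are validated as binary on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path} is {img.GetDimension()}D; expected a 3D image")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        logger.warning(
            "%s has non-identity direction cosines; axes are taken as-is", path
        )
    data = sitk.GetArrayFromImage(img)  # already (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if role == "label":
        data = data.astype(np.uint8)
    return Volume(data=data, spacing=spacing, origin=origin, role=role)


def write_volume(v: Volume, path: str | Path) -> Path:
    """Write a volume to NIfTI or MetaImage; returns the path written.

    Label volumes are stored as unsigned 8-bit integers so the binary values
    round-trip exactly.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory {path.parent} does not exist")
    data = v.data
    if v.role == "label":
        data = data.astype(np.uint8)
    elif not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(reversed(v.spacing)))
    img.SetOrigin(tuple(reversed(v.origin)))
    sitk.WriteImage(img, str(path))
    return path
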