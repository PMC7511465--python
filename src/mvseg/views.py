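"""Orthogonal 2D view extraction and lossless reassembly.

With the (z, y, x) convention: axial slices are taken at fixed z (shape
ny x nx), coronal at fixed y (nz x nx), sagittal at fixed x (nz x ny).
A :class:`ViewStack` keeps the provenance needed to put per-slice results
back into a 3D volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

AXES = ("axial", "coronal", "sagittal")

# stacking axis of each view within the (z, y, x) volume
STACK_AXIS = {"axial": 0, "coronal": 1, "sagittal": 2}


@dataclass(frozen=True)
class ViewStack:
    """An ordered stack of 2D slices from one anatomical view."""

    axis: str
    slices: np.ndarray  # (n_slices, h, w)
    source_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n, h, w) array")

    def reassemble(self, slices: np.ndarray | None = None) -> np.ndarray:
        """Rebuild the 3D (z, y, x) array from per-slice data (default: own)."""
        s = self.slices if slices is None else np.asarray(slices)
        if s.shape != self.slices.shape:
            raise ValueError(
                f"slice stack shape {s.shape} does not match {self.slices.shape}"
            )
        if self.axis == "axial":  # (z, y, x) already
            return s
        if self.axis == "coronal":  # stacked as (y, z, x)
            return s.transpose(1, 0, 2)
        return s.transpose(1, 2, 0)  # sagittal: stacked as (x, z, y)

    def to_volume(self, slices: np.ndarray, role: str) -> Volume:
        return Volume(self.reassemble(slices), self.spacing, self.origin, role)


def slice_views(v: Volume) -> tuple[ViewStack, ViewStack, ViewStack]:
    """Decompose a volume into (axial, sagittal, coronal) slice stacks."""
    common = dict(source_shape=v.shape, spacing=v.spacing, origin=v.origin)
    axial = ViewStack("axial", v.data, **common)
    sagittal = ViewStack("sagittal", v.data.transpose(2, 0, 1), **common)
    coronal = ViewStack("coronal", v.data.transpose(1, 0, 2), **common)
    return axial, sagittal, coronal
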