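"""Pipeline configuration: one auditable home for every numeric setting.

``PipelineConfig()`` reproduces the reference settings of the full-scale
pipeline: 200/800 HU window, 0.62/0.73 mm voxel size, in-plane downsample
factors 4 (coarse) and 2 (working), a 480 x 144 x 144 cuboid ROI, the
stage-specific augmentation ranges, Adam at 1e-4 with batch 20 (coarse) / 10
(single-view) and patience 15, and a 0.05-step binarization threshold grid.

``desk_config()`` is the scaled-down counterpart used for synthetic-phantom
experiments on one CPU (see docs/methods.md for the reasoning behind each
desk-scale value).

Configs load from YAML with unknown keys rejected, so a typo cannot silently
fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomSpec
from .preprocess import AugmentParams
from .segnet import DEFAULT_THRESHOLD_GRID


@dataclass(frozen=True)
class StageConfig:
    """Architecture + optimization settings for one network stage."""

    depth: int = 4
    base_filters: int = 16
    learning_rate: float = 1e-4
    batch_size: int = 10
    patience: int = 15
    max_epochs: int = 100
    steps_per_epoch: int | None = None
    augment: AugmentParams = field(default_factory=AugmentParams)


def _reference_stage(batch_size: int, augment: AugmentParams) -> StageConfig:
    return StageConfig(batch_size=batch_size, augment=augment)


@dataclass(frozen=True)
class PipelineConfig:
    window_level: float = 200.0
    window_width: float = 800.0
    target_spacing: tuple[float, float, float] = (0.62, 0.73, 0.73)
    coarse_factor: int = 4
    working_factor: int = 2
    roi_size: tuple[int, int, int] = (480, 144, 144)
    sigma: float = 1.0
    fusion: str = "combined"
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    seed: int = 0
    coarse: StageConfig = field(
        default_factory=lambda: _reference_stage(
            20,
            AugmentParams(
                rotation_deg=(-10, 10),
                shift_x_px=(-20, 20),
                shift_y_px=(-22, 22),
                zoom=(0.85, 1.15),
            ),
        )
    )
    axial: StageConfig = field(
        default_factory=lambda: _reference_stage(
            10,
            AugmentParams(
                rotation_deg=(-7, 7),
                shift_x_px=(-22, 22),
                shift_y_px=(-22, 22),
                zoom=(0.85, 1.15),
            ),
        )
    )
    sagittal: StageConfig = field(
        default_factory=lambda: _reference_stage(
            10,
            AugmentParams(
                rotation_deg=(-7, 7),
                shift_x_px=(-22, 22),
                shift_y_px=(-72, 72),
                zoom=(0.85, 1.15),
            ),
        )
    )
    coronal: StageConfig = field(
        default_factory=lambda: _reference_stage(
            10,
            AugmentParams(
                rotation_deg=(-7, 7),
                shift_x_px=(-22, 22),
                shift_y_px=(-72, 72),
                zoom=(0.85, 1.15),
            ),
        )
    )


def desk_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale configuration for 128 x 96 x 96 phantoms at 1 mm spacing.

    Tiny depth-2 / 8-filter networks, learning rate 1e-3, 50 optimizer steps
    per epoch, 8 epochs; a full-z 128 x 40 x 40 cuboid; augmentation ranges
    scaled to the small grids.  Trains in minutes on one CPU.
    """
    mild = AugmentParams(
        rotation_deg=(-7, 7),
        shift_x_px=(-2, 2),
        shift_y_px=(-2, 2),
        zoom=(0.9, 1.1),
    )
    desk_stage = lambda batch: StageConfig(  # noqa: E731
        depth=2,
        base_filters=8,
        learning_rate=1e-3,
        batch_size=batch,
        patience=15,
        max_epochs=8,
        steps_per_epoch=50,
        augment=mild,
    )
    return PipelineConfig(
        target_spacing=(1.0, 1.0, 1.0),
        roi_size=(128, 40, 40),
        seed=seed,
        coarse=desk_stage(20),
        axial=desk_stage(10),
        sagittal=desk_stage(10),
        coronal=desk_stage(10),
    )


def desk_phantom_spec() -> PhantomSpec:
    """Base phantom conditions for desk-scale experiments.

    20 HU noise and three bright distractor blobs per case give the networks a
    realistic contrast regime with non-trivial false-positive structures.
    """
    return PhantomSpec(noise_sd=20.0, distractors=3)


# -- YAML (de)serialization ----------------------------------------------------

_TUPLE_FIELDS = {
    "target_spacing",
    "roi_size",
    "threshold_grid",
    "rotation_deg",
    "shift_x_px",
    "shift_y_px",
    "zoom",
    "input_shape",
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _from_plain(cls, d: dict):
    if not isinstance(d, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(d)}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in d.items():
        f = names[key]
        if f.name in ("coarse", "axial", "sagittal", "coronal") and cls is PipelineConfig:
            kwargs[key] = _from_plain(StageConfig, value)
        elif f.name == "augment" and value is not None:
            kwargs[key] = _from_plain(AugmentParams, value)
        elif f.name in _TUPLE_FIELDS and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def to_yaml(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)
    return path


def from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _from_plain(PipelineConfig, data or {})
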