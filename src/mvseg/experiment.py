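"""End-to-end experiment orchestration over a phantom (or real) dataset.

Given a directory with a manifest (as written by
:func:`mvseg.phantom.generate_dataset`), :func:`train_pipeline` trains the
coarse localizer and the three single-view networks, selects every
binarization threshold on the validation split, and saves the artifacts.
:func:`evaluate_split` then runs full inference on a split and scores each
case against its ground truth.

Training data for the single-view networks is cropped with cuboids derived
from the trained coarse model's own predictions (falling back to the
ground-truth bounding box, with a warning, if localization fails on a
training case), so the view networks see the same ROI statistics they will
see at inference time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, pipeline, segnet
from .config import PipelineConfig, to_yaml
from .preprocess import apply_window, downsample_inplane, resample_volume
from .segnet import SegModelConfig, SliceSet, TrainConfig, TrainedModel
from .views import slice_views
from .volume import Volume, read_volume

logger = logging.getLogger(__name__)

VIEW_KEYS = ("axial", "sagittal", "coronal")


@dataclass
class Case:
    case_id: str
    split: str
    image: Volume
    mask: Volume


def load_cases(data_dir: str | Path) -> list[Case]:
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    cases = []
    for entry in manifest["cases"]:
        cases.append(
            Case(
                case_id=entry["case_id"],
                split=entry["split"],
                image=read_volume(data_dir / entry["image"], role="intensity"),
                mask=read_volume(data_dir / entry["mask"], role="label"),
            )
        )
    return cases


def _preprocess(case: Case, cfg: PipelineConfig) -> dict:
    pre = resample_volume(case.image, cfg.target_spacing, interp="linear")
    gt = resample_volume(case.mask, cfg.target_spacing, interp="nearest")
    win = apply_window(pre, cfg.window_level, cfg.window_width)
    return {
        "coarse_img": downsample_inplane(win, cfg.coarse_factor),
        "coarse_gt": downsample_inplane(gt, cfg.coarse_factor),
        "working_img": downsample_inplane(win, cfg.working_factor),
        "working_gt": downsample_inplane(gt, cfg.working_factor),
    }


def _axial_sliceset(pairs: list[tuple[Volume, Volume]]) -> SliceSet:
    imgs = np.concatenate([img.data for img, _ in pairs], axis=0)
    msks = np.concatenate([msk.data for _, msk in pairs], axis=0)
    return SliceSet(imgs.astype(np.float32), msks.astype(np.uint8))


def _view_sliceset(pairs: list[tuple[Volume, Volume]], view: str) -> SliceSet:
    idx = VIEW_KEYS.index(view)
    imgs, msks = [], []
    for img, msk in pairs:
        imgs.append(slice_views(img)[idx].slices)
        msks.append(slice_views(msk)[idx].slices)
    return SliceSet(
        np.concatenate(imgs, axis=0).astype(np.float32),
        np.concatenate(msks, axis=0).astype(np.uint8),
    )


def _crop_case(prep: dict, cfg: PipelineConfig, models: dict, coarse_thr: float):
    """ROI-crop the working-grid image and ground truth for one case."""
    try:
        coarse_mask = pipeline.coarse_localize(
            prep["coarse_img"], models["coarse"], coarse_thr
        )
    except pipeline.LocalizationError:
        logger.warning("coarse localization failed; falling back to GT bounding box")
        coarse_mask = prep["coarse_gt"]
    scale = cfg.coarse_factor // cfg.working_factor
    roi_img, roi = pipeline.extract_roi(
        prep["working_img"], coarse_mask, cfg.roi_size, inplane_scale=scale
    )
    roi_gt, _ = pipeline.extract_roi(
        prep["working_gt"], coarse_mask, cfg.roi_size, inplane_scale=scale
    )
    return roi_img, roi_gt, roi


def _stage_train_config(stage, seed: int) -> TrainConfig:
    return TrainConfig(
        learning_rate=stage.learning_rate,
        batch_size=stage.batch_size,
        patience=stage.patience,
        max_epochs=stage.max_epochs,
        steps_per_epoch=stage.steps_per_epoch,
        augment=stage.augment,
        seed=seed,
    )


def train_pipeline(
    data_dir: str | Path, cfg: PipelineConfig, out_dir: str | Path
) -> dict:
    """Train all four networks and select thresholds; save artifacts.

    Returns ``{"models": {...}, "thresholds": {...}}``.  Thresholds include a
    validated ``final_average`` and ``final_combined`` for the two fusion
    rules that need a final binarization.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = load_cases(data_dir)
    train_cases = [c for c in cases if c.split == "train"]
    val_cases = [c for c in cases if c.split == "val"]
    if not train_cases or not val_cases:
        raise ValueError("dataset must contain train and val cases")

    prep = {c.case_id: _preprocess(c, cfg) for c in cases}
    seed = cfg.seed

    # ---- stage 1: coarse localizer on downsampled axial slices -------------
    logger.info("training coarse localizer on %d cases", len(train_cases))
    coarse_shape = prep[train_cases[0].case_id]["coarse_img"].shape[1:]
    coarse_model = segnet.build_model(
        SegModelConfig(
            depth=cfg.coarse.depth,
            base_filters=cfg.coarse.base_filters,
            input_shape=coarse_shape,
            seed=seed,
        )
    )
    coarse_train = _axial_sliceset(
        [(prep[c.case_id]["coarse_img"], prep[c.case_id]["coarse_gt"]) for c in train_cases]
    )
    coarse_val = _axial_sliceset(
        [(prep[c.case_id]["coarse_img"], prep[c.case_id]["coarse_gt"]) for c in val_cases]
    )
    segnet.train(coarse_model, coarse_train, coarse_val, _stage_train_config(cfg.coarse, seed))

    coarse_val_probs = [
        segnet.predict_stack(coarse_model, slice_views(prep[c.case_id]["coarse_img"])[0])
        for c in val_cases
    ]
    coarse_thr = segnet.select_threshold(
        coarse_val_probs,
        [prep[c.case_id]["coarse_gt"] for c in val_cases],
        cfg.threshold_grid,
    )
    logger.info("coarse threshold: %.2f", coarse_thr)

    models: dict[str, TrainedModel] = {"coarse": coarse_model}
    thresholds: dict[str, float] = {"coarse": float(coarse_thr)}

    # ---- stage 2: ROI crops driven by the coarse model ----------------------
    crops = {
        c.case_id: _crop_case(prep[c.case_id], cfg, models, coarse_thr)
        for c in train_cases + val_cases
    }

    # ---- stage 3: one network per orthogonal view ---------------------------
    for i, view in enumerate(VIEW_KEYS):
        stage = getattr(cfg, view)
        train_set = _view_sliceset(
            [crops[c.case_id][:2] for c in train_cases], view
        )
        val_set = _view_sliceset([crops[c.case_id][:2] for c in val_cases], view)
        logger.info(
            "training %s view on %d slices of shape %s",
            view,
            len(train_set),
            train_set.images.shape[1:],
        )
        model = segnet.build_model(
            SegModelConfig(
                depth=stage.depth,
                base_filters=stage.base_filters,
                input_shape=train_set.images.shape[1:],
                seed=seed + 1 + i,
            )
        )
        segnet.train(model, train_set, val_set, _stage_train_config(stage, seed + 1 + i))
        models[view] = model

    # ---- stage 4: validated thresholds per view (on smoothed ROI maps) ------
    val_view_probs = {view: [] for view in VIEW_KEYS}
    val_roi_gts = []
    for c in val_cases:
        roi_img, roi_gt, _ = crops[c.case_id]
        val_roi_gts.append(roi_gt)
        stacks = slice_views(roi_img)
        for stack in stacks:
            raw = segnet.predict_stack(models[stack.axis], stack)
            val_view_probs[stack.axis].append(
                pipeline.smooth_stack(raw, stack.axis, cfg.sigma)
            )
    for view in VIEW_KEYS:
        thresholds[view] = float(
            segnet.select_threshold(val_view_probs[view], val_roi_gts, cfg.threshold_grid)
        )
        logger.info("%s threshold: %.2f", view, thresholds[view])

    # ---- stage 5: validated final threshold per fusion rule -----------------
    for fusion in ("average", "combined"):
        fused_probs, gts = [], []
        for c in val_cases:
            probs, roi, pre_shape = pipeline.predict_views(
                c.image,
                models,
                thresholds["coarse"],
                sigma=cfg.sigma,
                target_spacing=cfg.target_spacing,
                window_level=cfg.window_level,
                window_width=cfg.window_width,
                coarse_factor=cfg.coarse_factor,
                working_factor=cfg.working_factor,
                roi_size=cfg.roi_size,
            )
            fused, _ = pipeline.fuse_views(
                probs, fusion, {k: thresholds[k] for k in VIEW_KEYS}
            )
            fused_probs.append(pipeline.prob_to_scan_grid(fused, roi, pre_shape, c.image))
            gts.append(c.mask)
        thresholds[f"final_{fusion}"] = float(
            segnet.select_threshold(fused_probs, gts, cfg.threshold_grid)
        )
        logger.info("final %s threshold: %.2f", fusion, thresholds[f"final_{fusion}"])

    save_artifacts(models, thresholds, cfg, out_dir)
    return {"models": models, "thresholds": thresholds}


def save_artifacts(
    models: dict[str, TrainedModel],
    thresholds: dict[str, float],
    cfg: PipelineConfig,
    out_dir: str | Path,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, model in models.items():
        segnet.save_model(model, out_dir / f"{name}.npz")
        pd.DataFrame(model.history).to_csv(out_dir / f"{name}_history.csv", index=False)
    with open(out_dir / "thresholds.json", "w") as fh:
        json.dump(thresholds, fh, indent=2, sort_keys=True)
    to_yaml(cfg, out_dir / "config.yaml")


def load_artifacts(models_dir: str | Path) -> tuple[dict, dict]:
    models_dir = Path(models_dir)
    models = {
        name: segnet.load_model(models_dir / f"{name}.npz")
        for name in ("coarse",) + VIEW_KEYS
    }
    with open(models_dir / "thresholds.json") as fh:
        thresholds = json.load(fh)
    return models, thresholds


def _run_thresholds(thresholds: dict, fusion: str) -> dict:
    out = {k: thresholds[k] for k in ("coarse",) + VIEW_KEYS}
    if fusion in ("average", "combined"):
        out["final"] = thresholds[f"final_{fusion}"]
    else:
        out["final"] = 0.5
    return out


def predict_case(
    scan: Volume,
    models: dict[str, TrainedModel],
    thresholds: dict[str, float],
    cfg: PipelineConfig,
    fusion: str | None = None,
) -> Volume:
    """Segment one scan with the trained pipeline artifacts."""
    fusion = fusion or cfg.fusion
    return pipeline.run_pipeline(
        scan,
        models,
        _run_thresholds(thresholds, fusion),
        fusion=fusion,
        sigma=cfg.sigma,
        target_spacing=cfg.target_spacing,
        window_level=cfg.window_level,
        window_width=cfg.window_width,
        coarse_factor=cfg.coarse_factor,
        working_factor=cfg.working_factor,
        roi_size=cfg.roi_size,
    )


def evaluate_split(
    data_dir: str | Path,
    models: dict[str, TrainedModel],
    thresholds: dict[str, float],
    cfg: PipelineConfig,
    split: str = "test",
    fusion: str | None = None,
    per_view: bool = False,
) -> pd.DataFrame:
    """Segment and score every case of a split.

    With ``per_view=True`` each single-view segmentation (thresholded,
    pasted back, resampled) is scored alongside the fused result, mirroring
    the single-view vs multi-view comparison the pipeline is designed around.
    """
    fusion = fusion or cfg.fusion
    cases = [c for c in load_cases(data_dir) if c.split == split]
    if not cases:
        raise ValueError(f"no cases in split {split!r}")
    rows = []
    for c in cases:
        probs, roi, pre_shape = pipeline.predict_views(
            c.image,
            models,
            thresholds["coarse"],
            sigma=cfg.sigma,
            target_spacing=cfg.target_spacing,
            window_level=cfg.window_level,
            window_width=cfg.window_width,
            coarse_factor=cfg.coarse_factor,
            working_factor=cfg.working_factor,
            roi_size=cfg.roi_size,
        )
        fused, implied = pipeline.fuse_views(
            probs, fusion, {k: thresholds[k] for k in VIEW_KEYS}
        )
        final_thr = implied if implied is not None else thresholds[f"final_{fusion}"]
        fused_full = pipeline.prob_to_scan_grid(fused, roi, pre_shape, c.image)
        pred = fused_full.with_data(
            (fused_full.data >= final_thr).astype(np.uint8), role="label"
        )
        rows.append(_score(c, pred, "fused"))
        if per_view:
            for view in VIEW_KEYS:
                vfull = pipeline.prob_to_scan_grid(probs[view], roi, pre_shape, c.image)
                vpred = vfull.with_data(
                    (vfull.data >= thresholds[view]).astype(np.uint8), role="label"
                )
                rows.append(_score(c, vpred, view))
    return pd.DataFrame(rows)


def _score(case: Case, pred: Volume, output: str) -> dict:
    """Score one prediction; surface distances are NaN for an empty mask."""
    try:
        row = metrics.evaluate_case(case.mask, pred, case_id=case.case_id).as_dict()
    except ValueError:
        row = {
            "case_id": case.case_id,
            "dsc": metrics.dice(case.mask, pred),
            "jaccard": metrics.jaccard(case.mask, pred),
            "mean_sd_mm": float("nan"),
            "std_sd_mm": float("nan"),
            "max_sd_mm": float("nan"),
        }
    row["output"] = output
    return row
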