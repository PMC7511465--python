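# mvseg — coarse-to-fine multi-view segmentation of the aortic lumen

`mvseg` segments the contrast-enhanced aortic lumen in volumetric CT
angiography (CTA) with a cascade of small 2D convolutional networks, for
people who need automatic 3D lumen masks (vessel sizing, preoperative
planning, hemodynamic model building) without manual initialization.

Fully 3D networks are memory-hungry; single-slice 2D networks ignore
3D coherence. `mvseg` takes the middle road:

1. **Coarse localization** — a 2D U-Net segments ×4-downsampled axial
   slices; the bounding box of the resulting rough mask locates the aorta.
2. **Cuboid ROI** — a fixed-size cuboid (144 × 144 × 480 voxels at full
   scale) centred on that box is cropped from the ×2-resolution scan.
3. **Single-view segmentation** — three U-Nets segment the ROI from the
   axial, sagittal, and coronal views; each per-view probability stack is
   smoothed with a 1D Gaussian along its stacking axis.
4. **Multi-view fusion** — the three maps are fused per voxel and
   binarized with a threshold validated on held-out cases:
   - *majority voting* over the binarized views,
   - *averaging*: p(x) = ⅓·p_ax(x) + ⅓·p_sag(x) + ⅓·p_cor(x),
   - *combined*: unanimous views give exactly 1 (lumen) or 0
     (background); disagreements fall back to the average.

Inputs are NIfTI or MetaImage volumes in Hounsfield Units with per-axis
spacing; preprocessing resamples to a common voxel size and maps the HU
window level 200 / width 800 (i.e. [−200, 600] HU) onto [0, 255].
Evaluation reports the Dice coefficient DSC = 2|GT∩P| / (|GT|+|P|), the
Jaccard index J = |GT∩P| / |GT∪P|, and mean/std/max symmetric
surface-to-surface distances in mm computed from exact Euclidean distance
maps.

Clinical CTA data is not bundled. The package ships a **synthetic phantom
generator** — bright spline-swept lumen tubes with aneurysm bulges, side
branches, lumen-intensity distractor blobs, scanner blur and noise, plus
exact ground truth — so the entire pipeline trains and is evaluated
end-to-end from nothing but a seed. The networks are implemented
self-contained in NumPy (exact analytic backprop, Adam, early stopping);
desk-scale models train in minutes on one CPU.

## Worked example

```bash
mvseg phantoms --out data --n-train 16 --n-val 2 --n-test 4 --seed 1
mvseg train    --data data --out models --profile desk --seed 1
mvseg predict  --scan data/case_018_image.nii.gz --models models \
               --fusion combined --out mask.nii.gz
mvseg evaluate --data data --models models --per-view --report report.csv
```

Training prints the validated binarization thresholds:

```
trained 4 models; thresholds: {"axial": 0.35, "coarse": 0.45,
 "coronal": 0.5, "final_average": 0.4, "final_combined": 0.4,
 "sagittal": 0.45}
```

and `mvseg evaluate` summarizes per-case scores per output:

```
               dsc             jaccard           mean_sd_mm
              mean       std      mean       std       mean       std
output
axial     0.909546  0.010806  0.834235  0.018289   0.789731  0.337377
coronal   0.918627  0.005162  0.849532  0.008828   0.684919  0.154027
fused     0.934214  0.008537  0.876639  0.015096   0.601668  0.263726
sagittal  0.935719  0.008088  0.879284  0.014282   0.636710  0.229006
```

Reading: each single view recovers the held-out lumens with Dice
0.91–0.94; fusing the three orthogonal views matches the best single view
on Dice and improves the mean surface distance to ≈ 0.6 mm (sub-voxel) —
the spatial-coherence benefit the multi-view design exists for.

The same works from Python:

```python
from mvseg import desk_config, desk_phantom_spec, generate_dataset
from mvseg import experiment

generate_dataset(16, 2, 4, desk_phantom_spec(), seed=1, out_dir="data")
cfg = desk_config(seed=1)
artifacts = experiment.train_pipeline("data", cfg, "models")
df = experiment.evaluate_split("data", artifacts["models"],
                               artifacts["thresholds"], cfg,
                               split="test", per_view=True)
print(df.groupby("output")["dsc"].mean())
```

See `examples/` for short scripts covering phantom generation, the fusion
rules, and the evaluation metrics.

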