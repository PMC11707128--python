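# crestseg

Automated segmentation of the bony pelvis from CT, aimed at harvesting the
**iliac crest** as a vascularized graft for mandibular reconstruction.
Surgical planning needs the bone as a clean triangulated surface, and
producing it by manual thresholding and editing is the bottleneck of the
virtual-planning workflow. `crestseg` implements the full automated
pipeline: a **two-stage cascade of 3D U-Nets** (a coarse network localizes
the bone in the whole field of view at 160×160×224; a second network
re-segments a cropped region of interest at 256×144×144), **mesh
post-processing** (one-voxel binary erosion, Gaussian smoothing, marching
cubes — disconnected fragments are kept), and **mesh-based evaluation**
restricted to the transplant-relevant crest region.

The building blocks are importable on their own:

* `crestseg.grid` — CT volumes (NIfTI / DICOM series) with spacing/origin
  bookkeeping, intensity windowing, anisotropic resampling, cropping.
* `crestseg.meshes` — STL/PLY I/O, marching cubes in patient mm,
  **greedy voxelization** (every voxel with *some extent* inside the mesh,
  the superset mask used as training target), surface sampling, plane
  clipping.
* `crestseg.unet` — the 3D U-Net (10 encoder convs / 4 max-pools, 9 decoder
  convs / 4 up-samplings, feature doubling, sigmoid output) with soft Dice
  loss `L = 1 − DS`, Adam, and transfer initialization of stage 1 from
  stage-2 weights; NumPy + numba, no GPU framework required.
* `crestseg.train` — batch-1 training loop with the reduce-on-plateau
  (÷10 after 10 stagnant epochs) and early-stop (30 stagnant epochs)
  schedule, 360/40-style dataset splitting, target preparation.
* `crestseg.metrics` — volumetric Dice between meshes (shared-grid
  voxelization), symmetric average surface distance, symmetric 95%
  Hausdorff distance, per-point distances for colour-mapped surfaces, plus
  a brute-force oracle.
* `crestseg.roi` — the transplant ROI as a cutting plane recorded relative
  to the bone's geometric centre, transferable between bones and mirrorable
  left↔right.
* `crestseg.phantoms` — procedural pelvis phantoms (bilateral thin-walled
  curved wings + sacrum block in soft-tissue background, HU-scale noise)
  with exact ground-truth meshes, so everything is testable without data.

## Worked example

Generate a small phantom cohort, evaluate a "prediction" against ground
truth, and look at the metrics (here the prediction is the truth mesh of the
same case, so the numbers are perfect):

```python
import numpy as np
from crestseg import phantoms, metrics, roi

spec = phantoms.PhantomSpec(seed=7)
case = phantoms.generate_phantom(spec, case_seed=1)
print(case.volume.shape, np.round(case.volume.spacing, 2))

left = roi.RoiDefinition(anchor=[-0.35, 0.0, 0.15],
                         normal=np.array([-0.55, 0.0, 0.835]), side="left")
reports = metrics.evaluate_case(case.mesh, case.mesh,
                                [left, roi.mirror_roi(left)],
                                pitch=1.0, n_points=8000, seed=0)
for scope, rep in reports.items():
    print(f"{scope:10s} DSC {rep.dsc:.3f}  ASD {rep.asd_mm:.3f} mm  "
          f"HD95 {rep.hd95_mm:.3f} mm")
```

prints

```
(78, 77, 85) [1.51 1.5  1.66]
whole      DSC 1.000  ASD 0.000 mm  HD95 0.000 mm
left_roi   DSC 1.000  ASD 0.000 mm  HD95 0.000 mm
right_roi  DSC 1.000  ASD 0.000 mm  HD95 0.000 mm
```

`DSC` is volumetric overlap (1 = identical), `ASD` the mean closest-point
distance between the two surfaces, `HD95` the 95th percentile of those
distances — the three numbers reported per case, for the whole bone and for
each crest ROI.

The same workflow from the shell:

```sh
crestseg phantom --n 45 --out cohort/ --seed 7
crestseg train --stage 2 --data-dir cohort/ --out-weights w2.npz --seed 1
crestseg train --stage 1 --data-dir cohort/ --out-weights w1.npz \
               --init-from w2.npz --seed 1
crestseg predict --ct cohort/case_000001_ct.nii.gz \
                 --weights1 w1.npz --weights2 w2.npz --out-mesh pred.stl
crestseg evaluate --pred-dir preds/ --truth-dir cohort/ \
                  --roi-json left_roi.json --out-csv summary.csv
```

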