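"""Desk-scale two-stage segmentation study on procedural phantoms.

This is the package's end-to-end experiment: generate a phantom cohort,
train the stage-2 network from Glorot initialization, transfer its weights
to initialize stage-1 training, run the full two-stage pipeline with mesh
post-processing on held-out phantoms, and evaluate with the mesh metrics
(whole bone and left/right crest ROI).

The default problem sizes are the desk-scale analogue of the clinical
protocol: 45 phantoms split 30/5/10 (the 360/40 train/validation proportions
at reduced scale plus a held-out test set), base_filters 4, stage grids
48x48x48 and 64x48x48.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import grid, meshes, metrics, pipeline, roi, train, unet


#: Crest ROI for phantoms: an oblique plane keeping the superior outer part
#: of one iliac wing, recorded in normalized mesh-relative coordinates.
PHANTOM_LEFT_ROI = roi.RoiDefinition(
    anchor=np.array([-0.35, 0.0, 0.15]),
    normal=np.array([-0.55, 0.0, 0.835]) / np.linalg.norm([-0.55, 0.0, 0.835]),
    side="left",
)
PHANTOM_RIGHT_ROI = roi.mirror_roi(PHANTOM_LEFT_ROI)


@dataclasses.dataclass
class StudyConfig:
    n_train: int = 30
    n_val: int = 5
    n_test: int = 10
    base_filters: int = 4
    stage1_shape: tuple = (48, 48, 48)
    stage2_shape: tuple = (64, 48, 48)
    #: matches the inference-time ROI margin so the stage-2 crop statistics
    #: agree between training (ground-truth box) and prediction (stage-1 box)
    roi_margin_train: float = 0.05
    #: stage-2 trains from scratch and gets the longer schedule; stage-1
    #: starts from the transferred stage-2 weights and needs fewer epochs
    max_epochs_stage2: int = 40
    max_epochs_stage1: int = 20
    eval_n_points: int = 8000
    eval_pitch_mm: float = 1.0
    seed: int = 0


def build_training_pairs(case, config: StudyConfig):
    """(stage-1 pair, stage-2 pair) for one phantom, sharing one greedy mask."""
    ct = case.volume
    mask = meshes.greedy_voxelize(case.mesh, ct.shape, ct.spacing, ct.origin)
    ct_n = grid.normalize_intensities(ct)
    x1 = grid.resample_to_shape(ct_n, config.stage1_shape, "linear")
    t1 = grid.resample_mask_to_shape(mask, config.stage1_shape)
    box = train.mask_bounding_box(mask, config.roi_margin_train)
    x2 = grid.resample_to_shape(grid.crop_to_box(ct_n, box), config.stage2_shape, "linear")
    t2 = grid.resample_mask_to_shape(grid.crop_to_box(mask, box), config.stage2_shape)
    return (x1.data, t1.data), (x2.data, t2.data)


def _mask_to_native(mask: grid.BinaryMask, native_shape, box=None) -> np.ndarray:
    """Map a stage mask back to the native grid (into ``box`` if cropped)."""
    if box is None:
        return grid.resample_mask_to_shape(mask, native_shape).data
    crop_shape = tuple(hi - lo for lo, hi in box)
    crop = grid.resample_mask_to_shape(mask, crop_shape).data
    out = np.zeros(native_shape, dtype=bool)
    out[tuple(slice(lo, hi) for lo, hi in box)] = crop
    return out


def _binary_dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / max(a.sum() + b.sum(), 1)


def run_study(config: StudyConfig | None = None, verbose: bool = False) -> dict:
    """Run the full desk-scale study; returns per-case rows and cohort medians."""
    from . import phantoms

    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_train + config.n_val + config.n_test
    spec = phantoms.PhantomSpec(seed=int(rng.integers(0, 2 ** 31 - 1)))
    cases, _manifest = phantoms.generate_cohort(
        spec, n_total, seed=int(rng.integers(0, 2 ** 31 - 1))
    )
    fractions = (config.n_train / n_total, config.n_val / n_total)
    train_cases, val_cases, test_cases = train.split_dataset(
        cases, fractions, seed=int(rng.integers(0, 2 ** 31 - 1))
    )

    if verbose:
        print(f"cohort: {len(train_cases)} train / {len(val_cases)} val / "
              f"{len(test_cases)} test")
    pairs = {c.case_id: build_training_pairs(c, config)
             for c in train_cases + val_cases}
    s1 = lambda cs: [pairs[c.case_id][0] for c in cs]
    s2 = lambda cs: [pairs[c.case_id][1] for c in cs]

    net_cfg = unet.UNetConfig(base_filters=config.base_filters)
    tcfg = train.TrainConfig(max_epochs=config.max_epochs_stage2,
                             seed=int(rng.integers(0, 2 ** 31 - 1)))

    # Stage 2 first (Glorot init), then stage 1 initialized by transfer.
    net2 = unet.build_network(net_cfg, seed=int(rng.integers(0, 2 ** 31 - 1)))
    w2, hist2 = train.train_stage(net2, s2(train_cases), s2(val_cases), tcfg,
                                  verbose=verbose)
    net1 = unet.build_network(net_cfg, seed=int(rng.integers(0, 2 ** 31 - 1)))
    unet.transfer_init(net1, w2)
    tcfg1 = dataclasses.replace(tcfg, max_epochs=config.max_epochs_stage1,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
    w1, hist1 = train.train_stage(net1, s1(train_cases), s1(val_cases), tcfg1,
                                  verbose=verbose)
    net1.set_weights(w1)
    net2.set_weights(w2)

    pipe_cfg = pipeline.PipelineConfig(
        stage1_shape=config.stage1_shape, stage2_shape=config.stage2_shape
    )
    eval_seed = int(rng.integers(0, 2 ** 31 - 1))
    rows = []
    for case in test_cases:
        result = pipeline.run_pipeline(case.volume, net1, net2, pipe_cfg)
        # stage-level masks are scored against the greedy mask — the
        # segmentation target the stages are trained to produce; the mesh
        # metrics below compare against the ground-truth surface after the
        # erosion has removed the greedy dilation
        native = meshes.greedy_voxelize(
            case.mesh, case.volume.shape, case.volume.spacing, case.volume.origin
        ).data
        stage1_native = _mask_to_native(result.stage1_mask, case.volume.shape)
        stage2_native = _mask_to_native(result.stage2_mask, case.volume.shape,
                                        result.roi_box)
        reports = metrics.evaluate_case(
            result.mesh, case.mesh,
            roi_defs=[PHANTOM_LEFT_ROI, PHANTOM_RIGHT_ROI],
            pitch=config.eval_pitch_mm,
            n_points=config.eval_n_points,
            seed=eval_seed,
        )
        row = {
            "case_id": case.case_id,
            "voxel_mm": float(case.volume.spacing.mean()),
            "stage1_dice": _binary_dice(stage1_native, native),
            "stage2_dice": _binary_dice(stage2_native, native),
            "whole_dsc": reports["whole"].dsc,
            "whole_asd_mm": reports["whole"].asd_mm,
            "whole_hd95_mm": reports["whole"].hd95_mm,
            "left_roi_dsc": reports["left_roi"].dsc,
            "left_roi_asd_mm": reports["left_roi"].asd_mm,
            "right_roi_dsc": reports["right_roi"].dsc,
            "right_roi_asd_mm": reports["right_roi"].asd_mm,
        }
        rows.append(row)
        if verbose:
            print(f"{case.case_id}: whole DSC {row['whole_dsc']:.3f} "
                  f"ASD {row['whole_asd_mm']:.2f} mm")

    med = lambda key: float(np.median([r[key] for r in rows if r[key] is not None]))
    summary = {
        "n_test": len(rows),
        "stage1_dice_median": med("stage1_dice"),
        "stage2_dice_median": med("stage2_dice"),
        "whole_dsc_median": med("whole_dsc"),
        "whole_asd_mm_median": med("whole_asd_mm"),
        "whole_hd95_mm_median": med("whole_hd95_mm"),
        "left_roi_dsc_median": med("left_roi_dsc"),
        "right_roi_dsc_median": med("right_roi_dsc"),
        "asd_over_voxel_median": float(np.median(
            [r["whole_asd_mm"] / r["voxel_mm"] for r in rows
             if r["whole_asd_mm"] is not None])),
    }
    return {
        "config": config,
        "rows": rows,
        "summary": summary,
        "history_stage1": hist1,
        "history_stage2": hist2,
        "weights_stage1": w1,
        "weights_stage2": w2,
    }
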