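"""Training loop, plateau schedule, dataset split and target preparation.

Optimization follows the study protocol: Adam with batch size 1 and an
initial learning rate of 5e-4; the learning rate drops by a factor of 10
after 10 epochs without validation-loss improvement, and training stops
after 30 epochs without improvement. "Improvement" means a validation-loss
decrease of more than ``min_delta`` (default 1e-5). The stagnation counter
driving the learning-rate reduction resets after each reduction, while the
early-stop counter runs from the last actual improvement, so a schedule of
reductions at epochs k+10 and k+20 and a stop at k+30 is possible.
No data augmentation is applied.
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np
import pandas as pd
import yaml

from . import grid, meshes, unet


@dataclasses.dataclass
class TrainConfig:
    initial_lr: float = 5e-4
    batch_size: int = 1
    lr_reduce_factor: float = 10.0
    lr_patience_epochs: int = 10
    early_stop_epochs: int = 30
    min_delta: float = 1e-5
    max_epochs: int = 1000
    #: optional global-norm gradient clipping; tames the occasional huge
    #: single-sample Dice gradient under batch-size-1 training
    clip_grad_norm: float | None = None
    #: the plateau/early-stop machinery watches a running mean of this many
    #: validation epochs (1 = raw). With small validation sets the raw
    #: per-epoch loss is noisy enough that a single lucky epoch can set an
    #: unbeatable reference and freeze the learning rate prematurely
    val_smoothing_epochs: int = 3
    split: tuple[float, float] = (0.9, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.lr_patience_epochs >= self.early_stop_epochs:
            raise ValueError("lr patience must be smaller than the early-stop horizon")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "split" in raw:
            raw["split"] = tuple(raw["split"])
        return cls(**raw)


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list = dataclasses.field(default_factory=list)
    val_loss: list = dataclasses.field(default_factory=list)
    learning_rate: list = dataclasses.field(default_factory=list)
    wall_time_s: list = dataclasses.field(default_factory=list)

    def append(self, train_loss, val_loss, lr, wall):
        self.train_loss.append(float(train_loss))
        self.val_loss.append(float(val_loss))
        self.learning_rate.append(float(lr))
        self.wall_time_s.append(float(wall))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "learning_rate": self.learning_rate,
                "wall_time_s": self.wall_time_s,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class PlateauScheduler:
    """Reduce-on-plateau + early-stop state machine.

    Drives the learning rate from scripted or live validation losses:
    divide by ``factor`` after ``patience`` consecutive epochs without
    improvement, terminate after ``stop_after`` epochs without improvement.
    """

    def __init__(self, initial_lr: float, factor: float = 10.0, patience: int = 10,
                 stop_after: int = 30, min_delta: float = 1e-5):
        self.lr = float(initial_lr)
        self.factor = float(factor)
        self.patience = int(patience)
        self.stop_after = int(stop_after)
        self.min_delta = float(min_delta)
        self.best = np.inf
        self._since_improve = 0     # epochs since last improvement (early stop)
        self._since_reduce = 0      # epochs since last improvement or reduction (LR)

    def step(self, val_loss: float) -> tuple[float, bool]:
        """Record one epoch's validation loss; return (lr for next epoch, stop?)."""
        if val_loss < self.best - self.min_delta:
            self.best = float(val_loss)
            self._since_improve = 0
            self._since_reduce = 0
            return self.lr, False
        self._since_improve += 1
        self._since_reduce += 1
        if self._since_improve >= self.stop_after:
            return self.lr, True
        if self._since_reduce >= self.patience:
            self.lr /= self.factor
            self._since_reduce = 0
        return self.lr, False


def split_dataset(cases: list, fractions=(0.9, 0.1), seed: int = 0):
    """Reproducible disjoint train/validation(/test) split of case ids.

    ``fractions`` holds the train and validation fractions; anything left
    over becomes the test set. The default 0.9/0.1 reproduces a 360/40
    split on 400 cases.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
        raise ValueError(f"invalid fractions {fractions}")
    n = len(cases)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n)) if len(fractions) > 1 else 0
    if n_train < 1 or n_train + n_val > n:
        raise ValueError(f"too few cases ({n}) for fractions {fractions}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    cases = [cases[i] for i in order]
    train = cases[:n_train]
    val = cases[n_train:n_train + n_val]
    test = cases[n_train + n_val:]
    return train, val, test


def prepare_targets(
    mesh,
    ct: grid.ImageVolume,
    stage: int,
    stage_shape: tuple[int, int, int],
    roi_box=None,
    hu_window=grid.DEFAULT_HU_WINDOW,
):
    """Build one (input, target) training pair at the stage resolution.

    The greedy mask is computed at native CT resolution, then the normalized
    CT and the mask are resampled to the stage grid; stage 2 first crops both
    to ``roi_box`` (ground-truth bounding box with margin at training time).
    """
    lo, hi = ct.physical_extent()
    if np.any(mesh.vertices.min(axis=0) < lo) or np.any(mesh.vertices.max(axis=0) > hi):
        raise ValueError("mesh extends outside the CT volume")
    mask = meshes.greedy_voxelize(mesh, ct.shape, ct.spacing, ct.origin)
    ct_n = grid.normalize_intensities(ct, hu_window)
    if stage == 2:
        if roi_box is None:
            raise ValueError("stage 2 requires a roi_box")
        ct_n = grid.crop_to_box(ct_n, roi_box)
        mask = grid.crop_to_box(mask, roi_box)
    elif stage != 1:
        raise ValueError(f"stage must be 1 or 2, got {stage}")
    x = grid.resample_to_shape(ct_n, stage_shape, mode="linear")
    t = grid.resample_mask_to_shape(mask, stage_shape)
    return x, t


def mask_bounding_box(mask: grid.BinaryMask, margin: float = 0.1):
    """Index box of the set voxels, expanded by ``margin`` per side, clamped."""
    idx = np.nonzero(mask.data)
    if idx[0].size == 0:
        raise ValueError("empty mask has no bounding box")
    box = []
    for axis in range(3):
        lo, hi = int(idx[axis].min()), int(idx[axis].max()) + 1
        pad = int(np.ceil((hi - lo) * margin))
        box.append((max(0, lo - pad), min(mask.shape[axis], hi + pad)))
    return tuple(box)


def _clip_gradients(net: unet.UNet3D, max_norm: float) -> None:
    total = 0.0
    for layer in net._layers():
        for attr in layer.param_names():
            g = getattr(layer, "d" + attr)
            total += float((g.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / norm)
        for layer in net._layers():
            for attr in layer.param_names():
                getattr(layer, "d" + attr)[...] *= scale


def train_stage(
    net: unet.UNet3D,
    train_pairs: list,
    val_pairs: list,
    config: TrainConfig,
    verbose: bool = False,
):
    """Train one stage network; returns (best weight set, history).

    ``train_pairs``/``val_pairs`` hold ``(input volume, binary target)`` numpy
    pairs at the stage resolution. The returned weights are those of the
    epoch with minimum validation loss.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be non-empty")
    sched = PlateauScheduler(
        config.initial_lr, config.lr_reduce_factor,
        config.lr_patience_epochs, config.early_stop_epochs, config.min_delta,
    )
    opt = unet.Adam(net, lr=config.initial_lr)
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = net.get_weights()
    recent_val: list[float] = []
    for epoch in range(config.max_epochs):
        t0 = time.time()
        order = rng.permutation(len(train_pairs))
        losses = []
        for i in order:
            x, t = train_pairs[i]
            net.zero_grad()
            prob = net.forward(np.asarray(x, dtype=np.float32), train=True)
            loss, dprob = unet.dice_loss_grad(prob, np.asarray(t, dtype=np.float32))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, sample {i}: {loss}"
                )
            net.backward(dprob)
            if config.clip_grad_norm is not None:
                _clip_gradients(net, config.clip_grad_norm)
            opt.lr = sched.lr
            opt.step()
            losses.append(loss)
        val_losses = [
            unet.dice_loss(net.forward(np.asarray(x, dtype=np.float32)),
                           np.asarray(t, dtype=np.float32))
            for x, t in val_pairs
        ]
        val_loss = float(np.mean(val_losses))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        if val_loss < best_val:
            best_val = val_loss
            best_weights = net.get_weights()
        recent_val.append(val_loss)
        window = max(1, config.val_smoothing_epochs)
        smoothed = float(np.mean(recent_val[-window:]))
        lr_before = sched.lr
        _lr, stop = sched.step(smoothed)
        history.append(np.mean(losses), val_loss, lr_before, time.time() - t0)
        if verbose:
            print(f"epoch {epoch}: train {np.mean(losses):.4f} "
                  f"val {val_loss:.4f} lr {lr_before:.2e}")
        if stop:
            break
    return best_weights, history
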