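"""Training and inference for the dose-prediction network.

The training objective combines a voxel-wise mean-squared error with a
DVH term on the target:

    loss = MSE(D_ref, D_pred) + lambda * (|dD1%| + |dD95%| + |dD98%|)

where ``dDV%`` is the error in the PTV dose-volume metric ``D_V%`` (the
minimum dose to the hottest V% of the PTV) and ``lambda`` defaults to 0.25.
``D_V%`` is an order statistic; its subgradient with respect to the
prediction is carried by the selected voxel, which is what the manual
backward pass uses.

Training is patch-based: random 64^3 patches (configurable) drawn uniformly
from the training plans, Adam with initial learning rate 0.001, the rate
halved after every 55 epochs without validation improvement, early stopping,
and a cap of 1000 epochs.  Inference tiles each plan with overlapping
patches (stride 16), predicts every patch with every ensemble member, and
averages all covering predictions per voxel; the averaged volume is then
rescaled so its PTV D95% matches the reference plan's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np

from .grids import GeometryError, StructureMask, VolumeGrid
from .metrics import dose_percentile
from .nn import Adam, DenseDilatedUNet, NetworkConfig

__all__ = [
    "LossConfig",
    "TrainConfig",
    "PatchSpec",
    "LRState",
    "TrainingDiverged",
    "combined_loss",
    "sample_training_patch",
    "lr_schedule_step",
    "train_model",
    "train_ensemble",
    "tile_patches",
    "predict_volume",
    "normalize_to_reference_d95",
    "Predictor",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class LossConfig:
    """Weight and target percentiles of the DVH loss term."""

    dvh_weight: float = 0.25
    target_percentiles: tuple[float, ...] = (1.0, 95.0, 98.0)

    def __post_init__(self) -> None:
        if self.dvh_weight < 0:
            raise ValueError("DVH weight must be non-negative")
        if any(not (0 < v < 100) for v in self.target_percentiles):
            raise ValueError("percentiles must lie in (0, 100)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer schedule and patch sampling parameters."""

    initial_lr: float = 0.001
    plateau_patience_epochs: int = 55
    lr_factor: float = 0.5
    max_epochs: int = 1000
    early_stop_patience_epochs: int = 150
    patch_size: int = 64
    patches_per_epoch: int = 32
    batch_size: int = 4
    val_patch_size: int | None = None  # None: validate on the full volume
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr factor must lie in (0, 1)")
        if self.patch_size < 1 or self.patches_per_epoch < 1 or self.batch_size < 1:
            raise ValueError("patch settings must be positive")


@dataclass(frozen=True)
class PatchSpec:
    """Overlapping-patch tiling for inference."""

    size: int = 64
    stride: int = 16

    def __post_init__(self) -> None:
        if not (1 <= self.stride <= self.size):
            raise ValueError("stride must lie in [1, size]")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _percentile_index(n: int, volume_percent: float) -> int:
    """Index (into an ascending sort) of the D_V% order statistic."""
    k = math.ceil(volume_percent * n / 100.0)
    return n - k


def _loss_and_grad(
    pred: np.ndarray, ref: np.ndarray, ptv: np.ndarray, cfg: LossConfig
) -> tuple[float, np.ndarray]:
    """Combined loss and its (sub)gradient with respect to ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    diff = pred - ref
    n_vox = pred.size
    loss = float(np.mean(diff**2))
    grad = (2.0 / n_vox) * diff

    ptv_idx = np.flatnonzero(np.asarray(ptv).ravel())
    if cfg.dvh_weight > 0 and ptv_idx.size > 0:
        pred_flat = pred.ravel()
        ref_flat = ref.ravel()
        pv = pred_flat[ptv_idx]
        rv = ref_flat[ptv_idx]
        order_p = np.argsort(pv, kind="stable")
        rv_sorted = np.sort(rv)
        grad_flat = grad.ravel()
        for v in cfg.target_percentiles:
            i = _percentile_index(ptv_idx.size, v)
            d_pred = pv[order_p[i]]
            d_ref = rv_sorted[i]
            delta = d_pred - d_ref
            loss += cfg.dvh_weight * abs(delta)
            # subgradient flows to the voxel realizing the order statistic
            grad_flat[ptv_idx[order_p[i]]] += cfg.dvh_weight * np.sign(delta)
        grad = grad_flat.reshape(pred.shape)
    return loss, grad


def combined_loss(
    pred: VolumeGrid | np.ndarray,
    reference: VolumeGrid | np.ndarray,
    ptv: StructureMask | np.ndarray,
    cfg: LossConfig = LossConfig(),
) -> float:
    """MSE plus the weighted sum of absolute PTV D_V% errors."""
    if isinstance(pred, VolumeGrid):
        pred.require_same_geometry(reference)  # type: ignore[arg-type]
        pred_a, ref_a = pred.values, reference.values  # type: ignore[union-attr]
    else:
        pred_a, ref_a = np.asarray(pred), np.asarray(reference)
        if pred_a.shape != ref_a.shape:
            raise GeometryError("prediction and reference shapes differ")
    ptv_a = ptv.values if isinstance(ptv, StructureMask) else np.asarray(ptv)
    loss, _ = _loss_and_grad(pred_a, ref_a, ptv_a, cfg)
    return loss


# ---------------------------------------------------------------------------
# patch sampling and tiling
# ---------------------------------------------------------------------------

def sample_training_patch(
    stack: np.ndarray, dose: np.ndarray, ptv: np.ndarray, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Crop one random cubic patch, identically across channels and targets."""
    shape = dose.shape
    if any(size > s for s in shape):
        raise ValueError(f"patch size {size} exceeds grid shape {shape}")
    off = tuple(int(rng.integers(0, s - size + 1)) for s in shape)
    sl = tuple(slice(o, o + size) for o in off)
    return stack[(slice(None),) + sl], dose[sl], ptv[sl]


def tile_patches(grid_shape: tuple[int, int, int], spec: PatchSpec) -> list[tuple[int, int, int]]:
    """Overlapping-patch offsets: multiples of the stride per axis, with the
    final offset clamped so the last patch abuts the grid boundary."""
    per_axis = []
    for n in grid_shape:
        if spec.size > n:
            raise ValueError(f"patch size {spec.size} exceeds axis length {n}")
        offs = list(range(0, n - spec.size + 1, spec.stride))
        if offs[-1] != n - spec.size:
            offs.append(n - spec.size)
        per_axis.append(offs)
    return list(product(*per_axis))


# ---------------------------------------------------------------------------
# learning-rate plateau schedule
# ---------------------------------------------------------------------------

@dataclass
class LRState:
    """Plateau scheduler state: halve the rate after ``patience`` unimproved epochs."""

    lr: float
    best_val_loss: float = math.inf
    stagnation: int = 0


def lr_schedule_step(
    state: LRState,
    epoch_val_loss: float,
    patience: int = 55,
    factor: float = 0.5,
) -> LRState:
    """Advance the plateau schedule by one epoch of validation loss."""
    if epoch_val_loss < state.best_val_loss:
        return LRState(lr=state.lr, best_val_loss=epoch_val_loss, stagnation=0)
    stagnation = state.stagnation + 1
    if stagnation >= patience:
        return LRState(lr=state.lr * factor, best_val_loss=state.best_val_loss, stagnation=0)
    return LRState(lr=state.lr, best_val_loss=state.best_val_loss, stagnation=stagnation)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Predictor:
    """A trained network bound to its configuration; callable on input stacks."""

    def __init__(self, net: DenseDilatedUNet, loss_cfg: LossConfig, train_cfg: TrainConfig,
                 seed: int):
        self.net = net
        self.loss_cfg = loss_cfg
        self.train_cfg = train_cfg
        self.seed = seed

    def __call__(self, stack: np.ndarray) -> np.ndarray:
        return self.net.predict(stack)

    # checkpoints embed the configs and seed for reproducibility
    def save(self, path: str | Path) -> None:
        import json

        weights = self.net.get_weights()
        meta = {
            "network": self.net.config.__dict__,
            "loss": {"dvh_weight": self.loss_cfg.dvh_weight,
                     "target_percentiles": list(self.loss_cfg.target_percentiles)},
            "train": self.train_cfg.__dict__,
            "seed": self.seed,
        }
        np.savez_compressed(
            path, meta=json.dumps(meta, default=list),
            **{f"w{i}": w for i, w in enumerate(weights)},
        )

    @classmethod
    def load(cls, path: str | Path) -> "Predictor":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        net_meta = dict(meta["network"])
        net_meta["dilations"] = tuple(net_meta["dilations"])
        net = DenseDilatedUNet(NetworkConfig(**net_meta), seed=meta["seed"])
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        net.set_weights(weights)
        loss_meta = meta["loss"]
        loss_cfg = LossConfig(loss_meta["dvh_weight"], tuple(loss_meta["target_percentiles"]))
        train_meta = dict(meta["train"])
        return cls(net, loss_cfg, TrainConfig(**train_meta), meta["seed"])


def _center_crop(arr: np.ndarray, size: int) -> np.ndarray:
    sl = tuple(slice((s - size) // 2, (s - size) // 2 + size) for s in arr.shape[-3:])
    return arr[(Ellipsis,) + sl]


def _validation_loss(
    net: DenseDilatedUNet, samples, loss_cfg: LossConfig, patch_size: int | None = None
) -> float:
    total = 0.0
    for stack, dose, ptv in samples:
        if patch_size is not None:
            stack = _center_crop(stack, patch_size)
            dose = _center_crop(dose, patch_size)
            ptv = _center_crop(ptv, patch_size)
        pred = net.forward(stack, store=False)[0]
        loss, _ = _loss_and_grad(pred, dose, ptv, loss_cfg)
        total += loss
    return total / len(samples)


def _as_arrays(samples) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = []
    for s in samples:
        if hasattr(s, "input_stack"):
            out.append(
                (
                    s.input_stack(),
                    np.asarray(s.reference_dose.values, dtype=np.float32),
                    np.asarray(s.ptv_mask.values),
                )
            )
        else:
            out.append(s)
    return out


def train_model(
    train_samples,
    val_samples,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    loss_cfg: LossConfig = LossConfig(),
) -> tuple[Predictor, list[dict]]:
    """Train one network; returns the best-validation predictor and history.

    ``train_samples``/``val_samples`` are :class:`~dosepred3d.pipeline.PlanSample`
    objects or pre-built ``(stack, dose, ptv)`` array triples.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    train_arrays = _as_arrays(train_samples)
    val_arrays = _as_arrays(val_samples)

    net = DenseDilatedUNet(net_cfg, seed=train_cfg.seed)
    opt = Adam(net)
    rng = np.random.default_rng(train_cfg.seed)
    state = LRState(lr=train_cfg.initial_lr)
    best_val = math.inf
    best_weights = net.get_weights()
    stagnant = 0
    history: list[dict] = []

    for epoch in range(train_cfg.max_epochs):
        epoch_loss = 0.0
        n_steps = 0
        done = 0
        while done < train_cfg.patches_per_epoch:
            net.zero_grad()
            batch = min(train_cfg.batch_size, train_cfg.patches_per_epoch - done)
            for _ in range(batch):
                stack, dose, ptv = train_arrays[rng.integers(len(train_arrays))]
                ps, pd, pp = sample_training_patch(stack, dose, ptv, train_cfg.patch_size, rng)
                pred = net.forward(ps, store=True)
                loss, grad = _loss_and_grad(pred[0], pd, pp, loss_cfg)
                if not math.isfinite(loss):
                    raise TrainingDiverged(f"non-finite training loss at epoch {epoch}")
                net.backward((grad / batch)[None].astype(np.float32))
                epoch_loss += loss
                n_steps += 1
            opt.step(state.lr)
            done += batch

        val_loss = _validation_loss(net, val_arrays, loss_cfg, train_cfg.val_patch_size)
        if not math.isfinite(val_loss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_steps, "val_loss": val_loss,
             "lr": state.lr}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = net.get_weights()
            stagnant = 0
        else:
            stagnant += 1
        state = lr_schedule_step(
            state, val_loss, patience=train_cfg.plateau_patience_epochs,
            factor=train_cfg.lr_factor,
        )
        if stagnant >= train_cfg.early_stop_patience_epochs:
            break

    net.set_weights(best_weights)
    return Predictor(net, loss_cfg, train_cfg, train_cfg.seed), history


def train_ensemble(
    train_samples,
    val_samples,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    loss_cfg: LossConfig = LossConfig(),
    n_models: int = 3,
    seeds: tuple[int, ...] | None = None,
) -> tuple[list[Predictor], list[list[dict]]]:
    """Train ``n_models`` networks differing only by random seed."""
    if n_models < 1:
        raise ValueError("need at least one model")
    if seeds is None:
        seeds = tuple(train_cfg.seed + i for i in range(n_models))
    if len(seeds) != n_models or len(set(seeds)) != n_models:
        raise ValueError("seeds must be distinct and one per model")
    predictors, histories = [], []
    for s in seeds:
        p, h = train_model(
            train_samples, val_samples, net_cfg, replace(train_cfg, seed=int(s)), loss_cfg
        )
        predictors.append(p)
        histories.append(h)
    return predictors, histories


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_volume(models, sample, spec: PatchSpec = PatchSpec()) -> VolumeGrid:
    """Overlapping-patch ensemble prediction.

    Every patch of every model contributes; each voxel's value is the
    arithmetic mean over all (model, covering patch) predictions.
    ``models`` are callables mapping a (C, z, y, x) stack to a (z, y, x) dose
    array; ``sample`` is a PlanSample or a bare input stack.
    """
    if not models:
        raise ValueError("need at least one model")
    if hasattr(sample, "input_stack"):
        stack = sample.input_stack()
        spacing, origin = sample.reference_dose.spacing_mm, sample.reference_dose.origin_mm
    else:
        stack = np.asarray(sample, dtype=np.float32)
        spacing, origin = (3.0, 3.0, 3.0), (0.0, 0.0, 0.0)
    shape = stack.shape[1:]
    offsets = tile_patches(shape, spec)
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int64)
    for model in models:
        for off in offsets:
            sl = tuple(slice(o, o + spec.size) for o in off)
            patch = stack[(slice(None),) + sl]
            pred = np.asarray(model(patch), dtype=np.float64)
            if pred.shape != (spec.size,) * 3:
                raise ValueError(f"model returned shape {pred.shape}, expected patch shape")
            acc[sl] += pred
            cnt[sl] += 1
    out = np.maximum(acc / cnt, 0.0)
    return VolumeGrid(out.astype(np.float32), spacing, origin)


def normalize_to_reference_d95(
    pred: VolumeGrid, reference: VolumeGrid, ptv: StructureMask
) -> VolumeGrid:
    """Rescale the prediction so its PTV D95% matches the reference plan's."""
    d95_pred = dose_percentile(pred, ptv, 95.0)
    if d95_pred <= 0:
        raise ValueError("predicted D95% is zero; cannot renormalize")
    d95_ref = dose_percentile(reference, ptv, 95.0)
    factor = d95_ref / d95_pred
    return pred.with_values((np.asarray(pred.values, dtype=np.float64) * factor).astype(np.float32))
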