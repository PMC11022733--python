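"""Poisson-loss training with a plateau learning-rate schedule and
split-ensembling.

A model (shared core + per-subject readouts) is fit with Adam at batch size
128 on the Poisson objective ``(1/m) * sum_i (o_i - r_i log o_i)``. After
each epoch the mean per-neuron correlation between eval-mode predictions and
standardized responses on the validation trials is computed (pooled across
subjects); a ReduceLROnPlateau-style scheduler starts at 0.009 and multiplies
the rate by 0.3 (floored at 1e-4) after more than five consecutive epochs
with improvement below 1e-6, stopping at the fourth decay event or 200
epochs, whichever comes first. The parameters with the best validation
correlation — batch-norm running statistics included — are kept.

The ensemble repeats the whole procedure on freshly drawn train/validation
splits (split k and its training randomness derive from ``seed + k``) and
averages eval-mode predictions elementwise.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .data import Dataset, SplitSpec, make_splits
from .encoder import CoreConfig, ModelParams
from .metrics import _pearson_rows
from .objects import YoloBox, fallback_box
from .stimulus import build_inputs, standardize_responses

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 128
    lr_init: float = 0.009
    lr_min: float = 0.0001
    lr_factor: float = 0.3
    plateau_patience: int = 5       # epochs; decay on the (patience+1)-th bad epoch
    plateau_threshold: float = 1e-6  # absolute improvement on validation correlation
    max_decays: int = 4
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")
        if not self.lr_min < self.lr_init:
            raise ValueError("lr_min must be below lr_init")


@dataclass
class TrainState:
    epoch: int = 0
    current_lr: float = 0.009
    best_val_corr: float = -np.inf
    epochs_since_improve: int = 0
    n_decays: int = 0
    best_params: dict | None = None


def poisson_loss(o: np.ndarray, r: np.ndarray) -> float:
    """``(1/m) * sum(o - r * log o)`` per trial; batches (N, m) average the
    per-trial losses. Predictions must be strictly positive."""
    o = np.asarray(o, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if o.shape != r.shape:
        raise ValueError(f"shape mismatch {o.shape} vs {r.shape}")
    if np.any(o <= 0):
        raise ValueError("Poisson loss requires strictly positive predictions")
    per_trial = (o - r * np.log(o)).mean(axis=-1)
    return float(per_trial.mean())


def scheduler_step(state: TrainState, val_corr: float, config: TrainConfig) -> tuple[TrainState, bool]:
    """Advance the plateau scheduler by one epoch; returns (state, stop).

    An improvement larger than ``plateau_threshold`` over the best value
    resets the patience counter. Otherwise, once more than
    ``plateau_patience`` consecutive epochs have failed to improve, a decay
    event fires: the ``max_decays``-th event stops training, earlier ones
    multiply the rate by ``lr_factor`` (floored at ``lr_min``).
    """
    if not np.isfinite(val_corr):
        raise ValueError("validation metric must be finite")
    stop = False
    if val_corr > state.best_val_corr + config.plateau_threshold:
        state.best_val_corr = float(val_corr)
        state.epochs_since_improve = 0
    else:
        state.epochs_since_improve += 1
        if state.epochs_since_improve > config.plateau_patience:
            state.n_decays += 1
            state.epochs_since_improve = 0
            if state.n_decays >= config.max_decays:
                stop = True
            else:
                state.current_lr = max(state.current_lr * config.lr_factor, config.lr_min)
    state.epoch += 1
    if state.epoch >= config.max_epochs:
        stop = True
    return state, stop


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def prepare_inputs(dataset: Dataset, boxes: list[YoloBox] | None = None) -> np.ndarray:
    """6-channel tensors for every trial of a dataset. With no detections the
    whole-image fallback box fills the object channels."""
    if boxes is None:
        boxes = [fallback_box()] * dataset.n_trials
    return build_inputs(dataset.images, dataset.image_mean, dataset.image_std, boxes)


def predict(
    model: ModelParams,
    inputs: np.ndarray,
    subject_id: str,
    batch_size: int = 128,
) -> np.ndarray:
    """Eval-mode predictions (N, m) for a stack of prepared inputs."""
    chunks = [
        model.forward(inputs[i : i + batch_size], subject_id, training=False)
        for i in range(0, len(inputs), batch_size)
    ]
    return np.concatenate(chunks, axis=0)


@dataclass
class PredictionSet:
    """Per-trial, per-neuron positive predictions for one subject/split."""

    subject_id: str
    trial_indices: np.ndarray
    values: np.ndarray  # (n_trials, m)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _as_list(x):
    return x if isinstance(x, (list, tuple)) else [x]


def train_model(
    datasets,
    splits,
    config: TrainConfig,
    core_config: CoreConfig | None = None,
    boxes=None,
    seed: int | None = None,
    inputs=None,
) -> tuple[ModelParams, list[dict]]:
    """Fit one model (shared core, per-subject readouts).

    ``datasets`` and ``splits`` are one per subject (a bare Dataset/SplitSpec
    is accepted). Batches are homogeneous in subject and interleaved
    round-robin across subjects within an epoch. Returns the best-validation
    parameters and a per-epoch history (epoch, lr, train_loss, val_corr).

    ``inputs`` can carry precomputed 6-channel tensors (one stack per
    subject) to avoid rebuilding them across ensemble members.
    """
    datasets = _as_list(datasets)
    splits = _as_list(splits)
    if len(datasets) != len(splits):
        raise ValueError("one SplitSpec per dataset required")
    core_config = core_config or CoreConfig()
    seed = config.seed if seed is None else seed
    shapes = {d.image_shape for d in datasets}
    if len(shapes) != 1:
        raise ValueError(f"all datasets must share image dimensions, got {shapes}")
    for d, s in zip(datasets, splits):
        if len(s.train_indices) == 0:
            raise ValueError(f"subject {d.subject_id}: empty training split")

    from .stimulus import normalize_coordinates

    subject_coords = {d.subject_id: normalize_coordinates(d.coords) for d in datasets}
    model = ModelParams.init(core_config, subject_coords, seed=seed, split_seed=splits[0].seed)

    if inputs is None:
        boxes = boxes if boxes is not None else [None] * len(datasets)
        inputs = [prepare_inputs(d, b) for d, b in zip(datasets, boxes)]
    targets = [
        standardize_responses(d.responses, d.response_std).astype(np.float32) for d in datasets
    ]

    opt = Adam(model.params(), lr=config.lr_init)
    state = TrainState(current_lr=config.lr_init)
    rng = np.random.default_rng(seed + 1)
    history: list[dict] = []
    best_corr = -np.inf
    best_state = model.state()

    while True:
        # round-robin, subject-homogeneous batches
        order = []
        per_subject = []
        for si, sp in enumerate(splits):
            idx = sp.train_indices.copy()
            rng.shuffle(idx)
            per_subject.append([idx[i : i + config.batch_size] for i in range(0, len(idx), config.batch_size)])
        n_max = max(len(b) for b in per_subject)
        for j in range(n_max):
            for si in range(len(splits)):
                if j < len(per_subject[si]):
                    order.append((si, per_subject[si][j]))

        opt.lr = state.current_lr
        losses = []
        for si, idx in order:
            x = inputs[si][idx]
            y = targets[si][idx]
            opt.zero_grad()
            out = model.forward(x, datasets[si].subject_id, training=True, rng=rng)
            out64 = out.astype(np.float64)
            losses.append(float((out64 - y * np.log(out64)).mean()))
            dout = (1.0 - y / out64) / out.size
            model.backward(dout.astype(np.float32), datasets[si].subject_id)
            opt.step()
        train_loss = float(np.mean(losses))

        val_corr = _validation_correlation(model, datasets, splits, inputs, targets, config.batch_size)
        if val_corr > best_corr:
            best_corr = val_corr
            best_state = model.state()
        state, stop = scheduler_step(state, val_corr, config)
        history.append(
            {"epoch": state.epoch, "lr": state.current_lr, "train_loss": train_loss, "val_corr": val_corr}
        )
        log.info("epoch %d lr %.5f loss %.5f val_corr %.4f", state.epoch, state.current_lr, train_loss, val_corr)
        if stop:
            break

    model.load_state(best_state)
    return model, history


def _validation_correlation(model, datasets, splits, inputs, targets, batch_size) -> float:
    """Mean per-neuron Pearson correlation on validation trials, neurons
    pooled across subjects; neurons with undefined correlation are skipped."""
    corrs = []
    for d, sp, x, y in zip(datasets, splits, inputs, targets):
        idx = sp.validation_indices
        preds = predict(model, x[idx], d.subject_id, batch_size)
        corrs.append(_pearson_rows(preds.astype(np.float64), y[idx].astype(np.float64)))
    pooled = np.concatenate(corrs)
    return float(np.nanmean(pooled)) if np.any(~np.isnan(pooled)) else 0.0


def train_ensemble(
    datasets,
    n_models: int = 10,
    config: TrainConfig | None = None,
    core_config: CoreConfig | None = None,
    boxes=None,
    out_dir=None,
) -> tuple[list[ModelParams], list[list[dict]]]:
    """Train ``n_models`` members on freshly drawn train/validation splits.

    Member k uses split seed and initialization seed ``config.seed + k``.
    Checkpoints are written to ``out_dir`` when given.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    config = config or TrainConfig()
    datasets = _as_list(datasets)
    all_splits = [make_splits(d, n_models, config.seed) for d in datasets]
    boxes = boxes if boxes is not None else [None] * len(datasets)
    inputs = [prepare_inputs(d, b) for d, b in zip(datasets, boxes)]
    models, histories = [], []
    for k in range(n_models):
        member_splits = [s[k] for s in all_splits]
        model, hist = train_model(
            datasets, member_splits, config, core_config, seed=config.seed + k, inputs=inputs
        )
        models.append(model)
        histories.append(hist)
        if out_dir is not None:
            from pathlib import Path

            Path(out_dir).mkdir(parents=True, exist_ok=True)
            model.save(Path(out_dir) / f"model_{k:02d}.npz")
    return models, histories


def ensemble_predict(
    models: list[ModelParams],
    inputs: np.ndarray,
    subject_id: str,
    n_members: int | None = None,
    trial_indices: np.ndarray | None = None,
    batch_size: int = 128,
) -> PredictionSet:
    """Elementwise mean of eval-mode member predictions ("Ensemble N" uses
    the first ``n_members`` models)."""
    if not models:
        raise ValueError("need at least one model")
    members = models[: n_members] if n_members is not None else models
    preds = None
    m = None
    for model in members:
        p = predict(model, inputs, subject_id, batch_size)
        if m is None:
            m = p.shape[1]
        elif p.shape[1] != m:
            raise ValueError("ensemble members disagree on the neuron count")
        preds = p if preds is None else preds + p
    preds /= len(members)
    if trial_indices is None:
        trial_indices = np.arange(len(inputs))
    return PredictionSet(subject_id=subject_id, trial_indices=trial_indices, values=preds)
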