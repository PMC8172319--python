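"""Training loop: Adam, custom early stopping, per-task best checkpoints.

One training session optimizes the joint objective but saves *three* model
versions — the parameters at the epoch where each task's validation loss
(MSE for age, BCE for gender/diagnosis) reached its minimum.  Training stops
once ``patience`` consecutive epochs pass in which *no* task improved (the
patience counter is global and resets whenever any task improves; a strictly
per-task counter is available behind ``per_task_patience``), or at
``max_epochs``.

The loop itself is written against the small ``Trainable`` protocol below so
its checkpoint/stopping logic can be verified independently of the network
(e.g. with scripted validation-loss sequences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .folds import FoldSplit
from .nn import (LossWeights, ModelConfig, MultitaskCNN3D, TASKS, build_model,
                 objective_gradients, objective_loss, task_losses)
from .volume_io import SampleTensor

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TaskCheckpointSet", "TrainingHistory", "Trainable",
    "run_training_loop", "NetworkTrainable", "train_fold",
    "select_best_across_folds", "BestAcrossFolds",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (defaults follow the method: Adam at
    1e-3 with moment decays 0.9/0.999, batches of 32, up to 1000 epochs,
    patience 75)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 1000
    patience: int = 75
    seed: int = 0
    per_task_patience: bool = False
    #: initialise the age head's shift to the training-set mean age so the
    #: regression head does not spend its first epochs learning the intercept
    init_age_bias_to_mean: bool = True
    #: clip the global gradient norm before each Adam step (None = off);
    #: stabilises the higher learning rates used at small problem sizes
    grad_clip_norm: float | None = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("need 0 < patience < max_epochs")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class TaskCheckpointSet:
    """Best-per-task model states from one training session."""

    states: dict[str, object]
    best_epochs: dict[str, int]
    best_val_losses: dict[str, float]
    fold_index: int = 0


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_losses: dict[str, list[float]] = field(
        default_factory=lambda: {t: [] for t in TASKS})
    stop_epoch: int = 0
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"epoch": np.arange(len(self.train_loss)),
                           "train_loss": self.train_loss})
        for task in TASKS:
            df[f"val_{task}"] = self.val_losses[task]
        return df


class Trainable(Protocol):
    """What the loop needs from a model under training."""

    def train_epoch(self, epoch: int) -> float: ...
    def validation_losses(self) -> dict[str, float]: ...
    def snapshot(self) -> object: ...


def run_training_loop(trainable: Trainable, max_epochs: int, patience: int,
                      per_task_patience: bool = False
                      ) -> tuple[TaskCheckpointSet, TrainingHistory]:
    """Drive epochs until early stopping; returns checkpoints + history.

    "Improvement" means a strict decrease below the running per-task minimum
    (min-delta 0).
    """
    history = TrainingHistory()
    best_losses: dict[str, float] = {t: np.inf for t in TASKS}
    best_epochs: dict[str, int] = {t: -1 for t in TASKS}
    states: dict[str, object] = {}
    since_improvement = {t: 0 for t in TASKS}
    global_counter = 0
    stop_reason = "max_epochs"
    epoch = 0
    for epoch in range(max_epochs):
        train_loss = trainable.train_epoch(epoch)
        if not np.isfinite(train_loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        val = trainable.validation_losses()
        history.train_loss.append(float(train_loss))
        any_improved = False
        for task in TASKS:
            loss = float(val[task])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite validation loss for {task} at epoch {epoch}")
            history.val_losses[task].append(loss)
            if loss < best_losses[task]:
                best_losses[task] = loss
                best_epochs[task] = epoch
                states[task] = trainable.snapshot()
                since_improvement[task] = 0
                any_improved = True
            else:
                since_improvement[task] += 1
        global_counter = 0 if any_improved else global_counter + 1
        log.info("epoch=%d val_age=%.6g val_gender=%.6g val_diagnosis=%.6g patience=%d",
                 epoch, val["age"], val["gender"], val["diagnosis"], global_counter)
        if per_task_patience:
            if all(v >= patience for v in since_improvement.values()):
                stop_reason = "early_stopping(per_task)"
                break
        elif global_counter >= patience:
            stop_reason = "early_stopping"
            break
    history.stop_epoch = epoch + 1
    history.stop_reason = stop_reason
    checkpoints = TaskCheckpointSet(states=states, best_epochs=best_epochs,
                                    best_val_losses=best_losses)
    return checkpoints, history


# ---------------------------------------------------------------------------
# the real network trainable


class Adam:
    """Adaptive-moment gradient descent (bias-corrected)."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.value -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(np.float32)


def _targets_of(phenotypes) -> dict[str, np.ndarray]:
    return {
        "age": np.array([p.age for p in phenotypes], dtype=np.float64),
        "gender": np.array([p.gender for p in phenotypes], dtype=np.float64),
        "diagnosis": np.array([p.diagnosis for p in phenotypes], dtype=np.float64),
    }


class NetworkTrainable:
    """Adapts a :class:`MultitaskCNN3D` + data arrays to the training loop."""

    EVAL_CHUNK = 64

    def __init__(self, model: MultitaskCNN3D, x_train: np.ndarray, train_phenotypes,
                 x_val: np.ndarray, val_phenotypes, config: TrainConfig,
                 loss_weights: LossWeights = LossWeights()):
        if len(x_train) == 0 or len(x_val) == 0:
            raise ValueError("empty training or validation set")
        self.model = model
        self.x_train = np.asarray(x_train, dtype=np.float32)
        self.x_val = np.asarray(x_val, dtype=np.float32)
        self.y_train = _targets_of(train_phenotypes)
        self.y_val = _targets_of(val_phenotypes)
        self.config = config
        self.weights = loss_weights
        self.optimizer = Adam(model.parameters(), lr=config.learning_rate,
                              beta1=config.beta1, beta2=config.beta2)
        if config.init_age_bias_to_mean:
            # the age head's batch-norm shift is the model's age intercept
            age_bn = model.heads["age"][1]
            age_bn.beta.value[...] = np.float32(self.y_train["age"].mean())

    def train_epoch(self, epoch: int) -> float:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, epoch])  # epoch-derived stream
        order = rng.permutation(len(self.x_train))
        total, count = 0.0, 0
        l2 = self.model.config.l2_coefficient
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = self.x_train[idx]
            yb = {k: v[idx] for k, v in self.y_train.items()}
            out = self.model.forward(xb, training=True, dropout_rng=rng)
            loss = objective_loss(yb, out, self.weights)
            grads = objective_gradients(yb, out, self.weights)
            self.model.zero_grads()
            self.model.backward({k: g.astype(np.float32) for k, g in grads.items()})
            if l2 > 0:
                for p in self.model.parameters():
                    if p.regularized:
                        p.grad += np.float32(2.0 * l2) * p.value
            if cfg.grad_clip_norm is not None:
                total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                                    for p in self.model.parameters()))
                if total > cfg.grad_clip_norm:
                    scale = np.float32(cfg.grad_clip_norm / total)
                    for p in self.model.parameters():
                        p.grad *= scale
            self.optimizer.step()
            total += loss * len(idx)
            count += len(idx)
        return total / count

    def _predict(self, x: np.ndarray) -> dict[str, np.ndarray]:
        outs = {t: [] for t in TASKS}
        for start in range(0, len(x), self.EVAL_CHUNK):
            out = self.model.forward(x[start:start + self.EVAL_CHUNK], training=False)
            for t in TASKS:
                outs[t].append(out[t])
        return {t: np.concatenate(v) for t, v in outs.items()}

    def validation_losses(self) -> dict[str, float]:
        preds = self._predict(self.x_val)
        return task_losses(self.y_val, preds)

    def snapshot(self) -> dict:
        return self.model.get_state()


def stack_samples(samples: Sequence[SampleTensor]) -> tuple[np.ndarray, list]:
    x = np.stack([s.values for s in samples])
    return x, [s.phenotype for s in samples]


def train_fold(samples: Mapping[str, SampleTensor], split: FoldSplit,
               model_config: ModelConfig, train_config: TrainConfig,
               loss_weights: LossWeights = LossWeights(),
               ) -> tuple[TaskCheckpointSet, TrainingHistory]:
    """Train one cross-validation round; test subjects are never touched."""
    missing = [sid for sid in (*split.train_ids, *split.val_ids) if sid not in samples]
    if missing:
        raise KeyError(f"subjects missing from samples: {missing[:5]}")
    x_train, ph_train = stack_samples([samples[s] for s in split.train_ids])
    x_val, ph_val = stack_samples([samples[s] for s in split.val_ids])
    model = build_model(model_config, x_train.shape[1:4],
                        seed=train_config.seed + split.round_index)
    trainable = NetworkTrainable(model, x_train, ph_train, x_val, ph_val,
                                 train_config, loss_weights)
    checkpoints, history = run_training_loop(
        trainable, train_config.max_epochs, train_config.patience,
        train_config.per_task_patience)
    checkpoints.fold_index = split.round_index
    return checkpoints, history


@dataclass(frozen=True)
class BestAcrossFolds:
    state: object
    fold_index: int
    val_loss: float
    task: str


def select_best_across_folds(checkpoint_sets: Sequence[TaskCheckpointSet],
                             task: str) -> BestAcrossFolds:
    """Pick the fold whose ``task`` checkpoint has the lowest validation loss
    (ties -> lowest fold index); test data never enters the selection."""
    if task not in TASKS:
        raise KeyError(f"unknown task {task!r}")
    if not checkpoint_sets:
        raise ValueError("no folds trained")
    best = min(checkpoint_sets, key=lambda cs: (cs.best_val_losses[task], cs.fold_index))
    return BestAcrossFolds(state=best.states[task], fold_index=best.fold_index,
                           val_loss=float(best.best_val_losses[task]), task=task)
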