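"""Training loop, evaluation metrics, and the plateau learning-rate schedule.

Metrics are the two used throughout the grading experiments:

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    loss     = -(1/N) sum_i [ y_i log(p_i) + (1 - y_i) log(1 - p_i) ]

and the learning-rate rule is reduce-on-plateau: whenever the monitored
metric fails to improve for two consecutive epochs, lr' = lr * factor
(initial lr 0.01, factor 0.5), bounded below by a positive floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InvalidInputError
from .nn import SGD
from .revnet import RevisedResNet50

EPS = 1e-7


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total < 1:
        raise InvalidInputError("accuracy undefined on an empty confusion table")
    return (c.tp + c.tn) / c.total


def confusion_from_predictions(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold probabilities and tabulate the binary confusion counts."""
    y_true = np.asarray(y_true).astype(int).reshape(-1)
    pred = (np.asarray(y_prob).reshape(-1) >= threshold).astype(int)
    if y_true.shape != pred.shape:
        raise InvalidInputError("label/prediction length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y_true == 1))),
        tn=int(np.sum((pred == 0) & (y_true == 0))),
        fp=int(np.sum((pred == 1) & (y_true == 0))),
        fn=int(np.sum((pred == 0) & (y_true == 1))),
    )


def cross_entropy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Mean binary cross-entropy (natural log), probabilities clipped to
    [EPS, 1 - EPS]."""
    y = np.asarray(y_true, dtype=np.float64).reshape(-1)
    p = np.clip(np.asarray(y_prob, dtype=np.float64).reshape(-1), EPS, 1 - EPS)
    if y.shape != p.shape:
        raise InvalidInputError("label/prediction length mismatch")
    if y.size < 1:
        raise InvalidInputError("cross entropy undefined on empty input")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class ScheduleState:
    """State of the reduce-on-plateau rule (monitored metric: lower is better)."""

    lr: float = 0.01
    factor: float = 0.5
    patience: int = 2
    min_delta: float = 1e-4
    floor: float = 1e-12
    best: float = math.inf
    wait: int = 0

    def __post_init__(self):
        if self.lr <= 0 or not (0 < self.factor < 1) or self.floor <= 0:
            raise ConfigError("require lr > 0, 0 < factor < 1, floor > 0")


def step_on_plateau(state: ScheduleState, metric: float) -> ScheduleState:
    """Advance the schedule by one epoch's monitored value.

    An improvement larger than min_delta resets the stagnation counter;
    otherwise the counter grows and, at patience (two epochs), the rate is
    multiplied by factor — never below the floor.
    """
    if not math.isfinite(metric):
        raise InvalidInputError(f"non-finite monitored metric: {metric}")
    if state.best - metric > state.min_delta:
        state.best = metric
        state.wait = 0
        return state
    state.wait += 1
    if state.wait >= state.patience:
        state.lr = max(state.lr * state.factor, state.floor)
        state.wait = 0
    return state


@dataclass
class TrainConfig:
    epochs: int = 70
    batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0
    schedule: ScheduleState = field(default_factory=ScheduleState)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


def train(
    model: RevisedResNet50,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> list[dict]:
    """SGD-with-momentum training with per-epoch plateau scheduling.

    ``train_set`` / ``val_set`` are (X, y) with X an (N,3,S,S) float32 batch
    in [0,1] and y binary labels. The schedule is applied once per epoch on
    the validation loss. Returns one record per epoch with train/val
    accuracy and loss (cross-entropy plus regularization penalty) and the
    learning rate used that epoch.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0 or len(x_val) == 0:
        raise InvalidInputError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    sched = cfg.schedule
    opt = SGD(model.params, lr=sched.lr, momentum=cfg.momentum)
    history: list[dict] = []
    n = len(x_train)
    for epoch in range(cfg.epochs):
        opt.lr = sched.lr
        order = rng.permutation(n)
        losses, probs_all, y_all = [], [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, probs = model.loss(x_train[idx], y_train[idx], train=True)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            probs_all.append(probs)
            y_all.append(y_train[idx])
        train_loss = float(np.sum(losses) / n)
        train_acc = accuracy(
            confusion_from_predictions(np.concatenate(y_all), np.concatenate(probs_all))
        )
        val = evaluate(model, x_val, y_val, include_penalty=True)
        step_on_plateau(sched, val["loss"])
        history.append(
            {
                "epoch": epoch + 1,
                "train_acc": train_acc,
                "train_loss": train_loss,
                "val_acc": val["accuracy"],
                "val_loss": val["loss"],
                "lr": opt.lr,
            }
        )
    return history


def evaluate(
    model: RevisedResNet50,
    x: np.ndarray,
    y: np.ndarray,
    batch_size: int = 32,
    include_penalty: bool = False,
) -> dict:
    """Accuracy (threshold 0.5) and cross-entropy loss on a dataset.

    ``include_penalty`` adds the model's regularization terms, matching the
    training objective; plain evaluation reports pure cross-entropy.
    """
    if len(x) == 0:
        raise InvalidInputError("empty evaluation set")
    probs = []
    for start in range(0, len(x), batch_size):
        probs.append(model.predict_proba(x[start : start + batch_size]))
    probs = np.concatenate(probs)
    loss = cross_entropy(y, probs)
    if include_penalty:
        from .revnet import penalty

        loss += penalty(model.head.weight.data, probs, model.reg)
    return {
        "accuracy": accuracy(confusion_from_predictions(y, probs)),
        "loss": loss,
        "probabilities": probs,
    }


def samples_to_arrays(samples, preprocess_side: int | None = None):
    """Stack synthetic samples into (X, y) training arrays.

    With ``preprocess_side`` set, each image first runs the full SOP resized
    to that side; otherwise images are used as rendered.
    """
    from .preprocess import SOPConfig, run_sop
    from .revnet import images_to_batch

    images, labels = [], []
    for s in samples:
        img = s.image
        if preprocess_side is not None:
            img = run_sop(img, SOPConfig(output_side=preprocess_side)).image
        images.append(img)
        labels.append(s.label)
    return images_to_batch(images), np.asarray(labels, dtype=np.float32)
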