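"""From-scratch SGD training recipe and the repeated-run experiment protocol.

The recipe: stochastic gradient descent with momentum 0.9, batch size 64,
cross-entropy loss over the three classes, 120 epochs, learning rate
starting at 0.1 and divided by 10 every 30 epochs, weight decay 1e-4
(applied to convolution and classifier weights only). Runs are fully
seeded: the same seed and data give identical per-epoch history and final
weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import evaluation
from .nirs_io import SplitSpec, Window, split_dataset, windows_to_arrays
from .nn import SGD, softmax_cross_entropy
from .resnet1d import ArchitectureConfig, ResNet1D, build_model, save_checkpoint

__all__ = ["TrainConfig", "lr_at_epoch", "train", "run_experiment"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    epochs: int = 120
    momentum: float = 0.9
    initial_lr: float = 0.1
    lr_drop_factor: float = 10.0
    lr_drop_every: int = 30
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.lr_drop_every < 1:
            raise ValueError("batch_size, epochs and lr_drop_every must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step schedule: initial_lr / drop_factor**floor(epoch / drop_every).

    Epochs are 0-based, so with the defaults the drops land at epochs 30,
    60 and 90.
    """
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    return config.initial_lr * config.lr_drop_factor ** (
        -(epoch // config.lr_drop_every))


def _as_arrays(data, normalize: bool):
    if isinstance(data, tuple):
        x, y = data
        return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=np.int64)
    return windows_to_arrays(data, normalize=normalize)


def train(
    model: ResNet1D,
    train_data: Sequence[Window] | tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    normalize: bool = True,
    checkpoint_path=None,
) -> tuple[ResNet1D, list[dict]]:
    """Train in place; return the model and per-epoch history.

    ``train_data`` is either a window sequence or a pre-built
    ``(values, labels)`` pair (in which case ``normalize`` is ignored).
    Mini-batches are reshuffled every epoch; the last partial batch is kept.
    History rows carry epoch, lr, mean loss and training accuracy.
    """
    x, y = _as_arrays(train_data, normalize)
    if len(x) == 0:
        raise ValueError("empty training set")
    n_classes = model.config.num_classes
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")

    rng = np.random.default_rng(config.seed)
    opt = SGD(model.params(), lr=config.initial_lr, momentum=config.momentum,
              weight_decay=config.weight_decay)
    history: list[dict] = []
    n = len(x)
    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(epoch, config)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((np.argmax(logits, axis=1) == y[idx]).sum())
        history.append({
            "epoch": epoch,
            "lr": opt.lr,
            "loss": float(np.sum(losses) / n),
            "train_accuracy": 100.0 * correct / n,
        })
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return model, history


def run_experiment(
    arch: ArchitectureConfig,
    windows: Sequence[Window],
    train_cfg: TrainConfig,
    split_spec: SplitSpec | None = None,
    n_repeats: int = 5,
    resplit_each_run: bool = True,
    normalize: bool = True,
) -> evaluation.EvalReport:
    """Repeat train+evaluate cycles and summarize them.

    Each repeat derives its own seeds (model init, batch order and — unless
    ``resplit_each_run`` is False — the split) from ``train_cfg.seed`` and
    the run index, then trains from scratch and evaluates on the held-out
    set. The report carries per-run accuracies with their mean, standard
    deviation and best, plus the confusion matrix and per-class recalls of
    the best run.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    spec = split_spec if split_spec is not None else SplitSpec(seed=train_cfg.seed)
    ss = np.random.SeedSequence(train_cfg.seed)
    run_seeds = ss.generate_state(2 * n_repeats) % (2**31)

    accuracies: list[float] = []
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for r in range(n_repeats):
        split_seed = int(run_seeds[2 * r]) if resplit_each_run else spec.seed
        run_spec = SplitSpec(train_fraction=spec.train_fraction,
                             mode=spec.mode, seed=split_seed)
        train_set, test_set = split_dataset(windows, run_spec)
        model = build_model(arch, seed=int(run_seeds[2 * r + 1]))
        model, _ = train(model, train_set, TrainConfig(
            **{**train_cfg.to_dict(), "seed": int(run_seeds[2 * r + 1])}),
            normalize=normalize)
        x_test, y_test = windows_to_arrays(test_set, normalize=normalize)
        preds = _predict_batched(model, x_test)
        acc = evaluation.accuracy(preds, y_test)
        accuracies.append(acc)
        if best is None or acc > best[0]:
            best = (acc, preds, y_test)

    _, best_preds, best_truth = best
    report = evaluation.build_report(best_preds, best_truth)
    report.repeats = evaluation.RepeatSummary(
        accuracies=accuracies,
        mean=float(np.mean(accuracies)),
        std=float(np.std(accuracies, ddof=1)) if n_repeats > 1 else 0.0,
        best=float(np.max(accuracies)),
    )
    return report


def _predict_batched(model: ResNet1D, x: np.ndarray,
                     batch_size: int = 256) -> np.ndarray:
    preds = [model.predict(x[i:i + batch_size])
             for i in range(0, len(x), batch_size)]
    return np.concatenate(preds)
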