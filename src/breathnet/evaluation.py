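"""Classification metrics: accuracy, confusion matrix, recall, balanced accuracy.

Accuracy is the percentage of correctly classified windows
(100 x true positives / dataset size). The confusion matrix follows the
rows-are-true-labels convention; per-class recall is its diagonal divided
by row sums; balanced accuracy is the unweighted mean of the three recalls,
robust to the class imbalance of the window counts. Metrics are carried at
full precision internally and printed to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .nirs_io import Condition

__all__ = [
    "CLASS_ORDER",
    "RepeatSummary",
    "EvalReport",
    "accuracy",
    "confusion_and_recall",
    "balanced_accuracy",
    "build_report",
]

#: Fixed class order everywhere: (baseline, loaded, rapid/shallow).
CLASS_ORDER: tuple[Condition, ...] = tuple(Condition)


def _as_indices(labels: Sequence, class_order: Sequence[Condition]) -> np.ndarray:
    order = [Condition(c) for c in class_order]
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if isinstance(lab, (int, np.integer)):
            idx = int(lab)
            if not 0 <= idx < len(order):
                raise ValueError(f"label index {idx} outside class order")
        else:
            idx = order.index(Condition(lab))
        out[i] = idx
    return out


def accuracy(predictions: Sequence, truths: Sequence) -> float:
    """Percentage of matching prediction/truth pairs."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    if len(predictions) == 0:
        raise ValueError("empty input")
    preds = np.asarray(predictions)
    truth = np.asarray(truths)
    return 100.0 * float(np.mean(preds == truth))


def confusion_and_recall(
    predictions: Sequence,
    truths: Sequence,
    class_order: Sequence[Condition] = CLASS_ORDER,
) -> dict:
    """Confusion matrix (rows = true), row-normalized form, per-class recall.

    Recall for a class absent from the truth labels is reported as ``None``
    (undefined), and its normalized row as NaN — never silently as zero.
    """
    preds = _as_indices(predictions, class_order)
    truth = _as_indices(truths, class_order)
    k = len(class_order)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (truth, preds), 1)
    row_sums = confusion.sum(axis=1)
    normalized = np.full((k, k), np.nan)
    recalls: dict[Condition, float | None] = {}
    for i, cls in enumerate(class_order):
        if row_sums[i] > 0:
            normalized[i] = confusion[i] / row_sums[i]
            recalls[Condition(cls)] = float(confusion[i, i] / row_sums[i])
        else:
            recalls[Condition(cls)] = None
    return {"confusion": confusion, "normalized": normalized,
            "per_class_recall": recalls}


def balanced_accuracy(per_class_recall: Mapping | Sequence[float]) -> float:
    """Unweighted mean of per-class recalls, as a percentage."""
    values = (list(per_class_recall.values())
              if isinstance(per_class_recall, Mapping) else list(per_class_recall))
    if any(v is None for v in values):
        raise ValueError("balanced accuracy undefined: a class has no test "
                         "windows (undefined recall)")
    return 100.0 * float(np.mean([float(v) for v in values]))


@dataclass
class RepeatSummary:
    """Accuracy summary over repeated independent runs."""

    accuracies: list[float]
    mean: float
    std: float
    best: float


@dataclass
class EvalReport:
    """Evaluation of one test set, plus an optional repeated-run summary."""

    n_test: int
    accuracy: float
    per_class_recall: dict
    balanced_accuracy: float | None
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    repeats: RepeatSummary | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "n_test": self.n_test,
            "accuracy": self.accuracy,
            "per_class_recall": {c.value: r for c, r in self.per_class_recall.items()},
            "balanced_accuracy": self.balanced_accuracy,
            "confusion": self.confusion.tolist(),
            "confusion_normalized": [
                [None if np.isnan(v) else v for v in row]
                for row in self.confusion_normalized
            ],
            "repeats": None if self.repeats is None else asdict(self.repeats),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def render(self) -> str:
        names = [c.value for c in CLASS_ORDER]
        width = max(len(n) for n in names) + 2
        lines = [f"test windows: {self.n_test}",
                 f"accuracy: {self.accuracy:.2f}%"]
        if self.balanced_accuracy is not None:
            lines.append(f"balanced accuracy: {self.balanced_accuracy:.2f}%")
        lines.append("confusion (rows = true):")
        header = " " * width + "".join(f"{n:>{width}}" for n in names)
        lines.append(header)
        for i, n in enumerate(names):
            lines.append(f"{n:>{width}}" + "".join(
                f"{self.confusion[i, j]:>{width}}" for j in range(len(names))))
        for c in CLASS_ORDER:
            r = self.per_class_recall[c]
            lines.append(f"recall {c.value}: "
                         + ("undefined" if r is None else f"{r:.2f}"))
        if self.repeats is not None:
            lines.append(
                f"repeats: mean {self.repeats.mean:.2f}% "
                f"STD {self.repeats.std:.3f} best {self.repeats.best:.2f}% "
                f"({len(self.repeats.accuracies)} runs)")
        return "\n".join(lines)

    def plot_confusion(self, path) -> None:
        """Write a normalized confusion-matrix heatmap to ``path``."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = [c.value for c in CLASS_ORDER]
        fig, ax = plt.subplots(figsize=(4.2, 3.6))
        im = ax.imshow(self.confusion_normalized, vmin=0, vmax=1, cmap="Blues")
        for i in range(len(names)):
            for j in range(len(names)):
                v = self.confusion_normalized[i, j]
                if not np.isnan(v):
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                            color="black" if v < 0.6 else "white")
        ax.set_xticks(range(len(names)), names, rotation=30, ha="right")
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("predicted label")
        ax.set_ylabel("true label")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_report(
    predictions: Sequence,
    truths: Sequence,
    class_order: Sequence[Condition] = CLASS_ORDER,
) -> EvalReport:
    """Assemble the full report from prediction/truth label sequences."""
    acc = accuracy(predictions, truths)
    parts = confusion_and_recall(predictions, truths, class_order)
    recalls = parts["per_class_recall"]
    try:
        bal = balanced_accuracy(recalls)
    except ValueError:
        bal = None
    return EvalReport(
        n_test=len(truths),
        accuracy=acc,
        per_class_recall=recalls,
        balanced_accuracy=bal,
        confusion=parts["confusion"],
        confusion_normalized=parts["normalized"],
    )
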