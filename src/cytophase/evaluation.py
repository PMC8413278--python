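"""Per-condition accuracy, confusion matrix, and one-vs-rest ROC/AUC.

Three-class predictions are evaluated the way the field reports them:
per-class accuracy (correct predictions over the number of cells with that
true label), a rows-true × cols-predicted confusion matrix, and one ROC
curve per class treating its softmax probability as a binary score against
the rest. AUC is the trapezoidal area under that curve, which — with ties
given half credit — equals the probability that a random positive outranks
a random negative; :func:`auc_pair_counting` computes that probability by
brute-force pair enumeration and serves as the independent oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_curve

from .classifier import CLASS_ORDER


def per_class_accuracy(predictions, labels, classes=CLASS_ORDER) -> dict[str, float | None]:
    """accuracy[c] = #(pred == c and label == c) / #(label == c).

    A class absent from the labels is reported as None (undefined), not 0.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must be aligned")
    if len(labels) == 0:
        raise ValueError("empty input")
    out: dict[str, float | None] = {}
    for cls in classes:
        mask = labels == cls
        out[cls] = float(np.mean(predictions[mask] == cls)) if mask.any() else None
    return out


def roc_ovr(scores, labels, positive_class) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC and AUC for one class.

    ``scores`` are that class's probabilities (or any monotone score);
    labels are binarized against ``positive_class``. Sweeps every distinct
    score threshold and integrates with the trapezoid rule. Returns
    ``(fpr, tpr, auc)``; the curve runs from (0, 0) to (1, 1).

    Raises if only one class is present (AUC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_class).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def auc_pair_counting(scores, labels, positive_class=1) -> float:
    """Brute-force AUC: P(score_pos > score_neg) + ½·P(tie) over all pairs.

    O(n_pos · n_neg); intended as an independent oracle at small n.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_class]
    neg = scores[labels != positive_class]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: need both classes")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


@dataclass
class EvalReport:
    """Full evaluation bundle for a three-class prediction run."""

    per_class_accuracy: dict[str, float | None]
    confusion: np.ndarray  # (3, 3), rows true, cols predicted, CLASS_ORDER
    roc: dict[str, list[tuple[float, float]]]  # class -> [(fpr, tpr), ...]
    auc: dict[str, float]
    n_per_class: dict[str, int]
    class_order: tuple[str, ...] = CLASS_ORDER

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "per_class_accuracy": self.per_class_accuracy,
            "confusion": self.confusion.tolist(),
            "auc": self.auc,
            "n_per_class": self.n_per_class,
            "roc": {cls: [[float(f), float(t)] for f, t in pts] for cls, pts in self.roc.items()},
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path

    def to_csv(self, out_dir: str | Path) -> None:
        """Write confusion matrix and ROC points as CSV files."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.confusion, index=list(self.class_order), columns=list(self.class_order)).to_csv(
            out_dir / "confusion.csv"
        )
        rows = [
            {"class": cls, "fpr": f, "tpr": t}
            for cls, pts in self.roc.items()
            for f, t in pts
        ]
        pd.DataFrame(rows).to_csv(out_dir / "roc_points.csv", index=False)


def build_report(predictions, scores, labels, class_order=CLASS_ORDER) -> EvalReport:
    """Assemble accuracies, confusion and per-class ROC/AUC.

    ``scores`` is (n, 3) of class probabilities in ``class_order``;
    ``predictions`` and ``labels`` are class-name arrays.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not (len(predictions) == len(labels) == len(scores)):
        raise ValueError("predictions, scores and labels must be aligned")
    acc = per_class_accuracy(predictions, labels, class_order)
    conf = confusion_matrix(labels, predictions, labels=list(class_order))
    roc: dict[str, list[tuple[float, float]]] = {}
    auc: dict[str, float] = {}
    for i, cls in enumerate(class_order):
        fpr, tpr, a = roc_ovr(scores[:, i], labels, cls)
        roc[cls] = list(zip(fpr.tolist(), tpr.tolist()))
        auc[cls] = a
    n_per_class = {cls: int((labels == cls).sum()) for cls in class_order}
    return EvalReport(
        per_class_accuracy=acc,
        confusion=conf,
        roc=roc,
        auc=auc,
        n_per_class=n_per_class,
        class_order=tuple(class_order),
    )


def plot_roc(report: EvalReport, path: str | Path) -> Path:
    """Optional ROC figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, pts in report.roc.items():
        arr = np.asarray(pts)
        ax.plot(arr[:, 0], arr[:, 1], label=f"{cls} (AUC {report.auc[cls]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="random (AUC 0.500)")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
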