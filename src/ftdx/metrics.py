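"""Balanced-accuracy evaluation for the three-way subtype problem.

Per-class balanced accuracy is the mean of one-vs-rest sensitivity
(TP / (TP + FN)) and specificity (TN / (TN + FP)) computed from the
multi-class confusion matrix; the overall balanced accuracy is the mean
of the three per-class values. Note this differs from macro-recall
"balanced accuracy" as defined elsewhere: specificity enters explicitly.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .tables import DIAGNOSES


class UndefinedMetricError(ValueError):
    """A class has no true (or no predicted-negative) samples."""


def confusion(y_true, y_pred, n_classes: int = 3) -> np.ndarray:
    """True x predicted confusion matrix over integer class labels."""
    return _sk_confusion(y_true, y_pred, labels=list(range(n_classes)))


def class_balanced_accuracy(conf: np.ndarray, class_index: int) -> float:
    """One-vs-rest (sensitivity + specificity) / 2 for one class."""
    conf = np.asarray(conf, dtype=float)
    tp = conf[class_index, class_index]
    fn = conf[class_index].sum() - tp
    fp = conf[:, class_index].sum() - tp
    tn = conf.sum() - tp - fn - fp
    if tp + fn == 0:
        raise UndefinedMetricError(f"no true samples for class {class_index}")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    return float((sens + spec) / 2.0)


def overall_balanced_accuracy(conf: np.ndarray, skip_empty: bool = False) -> float:
    """Mean of the per-class balanced accuracies.

    ``skip_empty=True`` averages only over classes with true samples
    (useful for tiny validation folds); otherwise an empty class raises.
    """
    conf = np.asarray(conf)
    k = conf.shape[0]
    classes = range(k)
    if skip_empty:
        classes = [c for c in classes if conf[c].sum() > 0]
        if not classes:
            raise UndefinedMetricError("confusion matrix is empty")
    return float(np.mean([class_balanced_accuracy(conf, c) for c in classes]))


def metrics_report(y_true, y_pred) -> dict:
    """Confusion matrix plus per-class and overall balanced accuracy."""
    conf = confusion(y_true, y_pred, n_classes=len(DIAGNOSES))
    per_class = {
        dx: class_balanced_accuracy(conf, c) for c, dx in enumerate(DIAGNOSES)
    }
    return {
        "confusion": conf,
        "per_class_balanced_accuracy": per_class,
        "overall_balanced_accuracy": float(np.mean(list(per_class.values()))),
        "n": int(conf.sum()),
    }
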