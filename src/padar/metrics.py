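"""Classification metric suite: per-class one-vs-rest rates, macro averages,
one-vs-rest AUC, and multi-class Cohen's kappa.

Per-class precision, sensitivity (recall), specificity, and F1 are computed
one-vs-rest from the confusion matrix; the macro average is the unweighted
arithmetic mean over classes. AUC is one-vs-rest from the score columns
(trapezoidal ROC). A class absent from the true labels yields NaN for its
undefined rates and is excluded from the macro average with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_auc_score


@dataclass
class MetricTable:
    classes: list[str]
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "per_class": {c: {k: round(float(v), 6) for k, v in d.items()}
                          for c, d in self.per_class.items()},
            "macro": {k: round(float(v), 6) for k, v in self.macro.items()},
            "confusion": self.confusion.tolist(),
        }


def compute_metrics(labels: Sequence[str], predictions: Sequence[str],
                    scores: np.ndarray | None = None,
                    classes: Sequence[str] | None = None) -> MetricTable:
    """Full metric table for a multi-class prediction run.

    ``scores`` (n_samples, n_classes), column order matching ``classes``, is
    required for AUC; without it AUC is NaN.
    """
    labels = list(labels)
    predictions = list(predictions)
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions must align")
    if classes is None:
        classes = sorted(set(labels) | set(predictions))
    classes = list(classes)
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes present in labels")

    cm = confusion_matrix(labels, predictions, labels=classes)
    n = cm.sum()
    accuracy = np.trace(cm) / n
    kappa = cohen_kappa_score(labels, predictions, labels=classes)

    per_class: dict[str, dict[str, float]] = {}
    absent = []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        present = (tp + fn) > 0
        if not present:
            absent.append(c)
        prec = tp / (tp + fp) if (tp + fp) > 0 else (np.nan if not present else 0.0)
        sens = tp / (tp + fn) if present else np.nan
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        f1 = (2 * prec * sens / (prec + sens)
              if present and np.isfinite(prec) and (prec + sens) > 0 else
              (0.0 if present else np.nan))
        auc = np.nan
        if scores is not None and present:
            y_bin = np.array([1 if lab == c else 0 for lab in labels])
            if 0 < y_bin.sum() < len(y_bin):
                auc = roc_auc_score(y_bin, np.asarray(scores)[:, i])
        per_class[c] = {"precision": prec, "sensitivity": sens,
                        "specificity": spec, "f1": f1, "auc": auc,
                        "accuracy": (tp + tn) / n}
    if absent:
        warnings.warn(f"classes absent from labels, excluded from macro: {absent}")

    # macro average = unweighted arithmetic mean of the per-class values
    macro = {}
    for key in ("precision", "sensitivity", "specificity", "f1", "auc", "accuracy"):
        vals = [per_class[c][key] for c in classes
                if c not in absent and np.isfinite(per_class[c][key])]
        macro[key] = float(np.mean(vals)) if vals else np.nan
    macro["overall_accuracy"] = float(accuracy)
    macro["kappa"] = float(kappa)
    return MetricTable(classes, per_class, macro, cm)
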