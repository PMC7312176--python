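"""Leave-one-out 1-nearest-neighbor genotyping and per-class metrics.

Each record is assigned the class of its nearest neighbor in the distance
matrix, excluding itself (leave-one-out).  Performance is tabulated
one-vs-rest per class:

    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)

Per-class accuracy is the fraction of that class's members predicted
correctly, which is identical to sensitivity under this tabulation; an
overall accuracy (total correct / total records) is reported separately.
Dataset-level averages are unweighted means over classes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np

from .phylo import DistanceMatrix

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "ClassificationReport",
    "one_nn_predict",
    "confusion_counts",
    "metrics",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FN/FP/TN tallies per class."""

    per_class: dict[str, tuple[int, int, int, int]]  # class -> (TP, FN, FP, TN)
    total: int

    def counts(self, cls: str) -> tuple[int, int, int, int]:
        return self.per_class[cls]


@dataclass(frozen=True)
class ClassMetrics:
    """Metrics for one class; NaN marks an undefined ratio (empty class)."""

    n_members: int
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class metrics plus unweighted averages and overall accuracy."""

    classes: dict[str, ClassMetrics]
    average_sensitivity: float
    average_specificity: float
    average_accuracy: float
    overall_accuracy: float

    def to_dict(self) -> dict:
        return {
            "classes": {
                c: {
                    "number": m.n_members,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                }
                for c, m in self.classes.items()
            },
            "average": {
                "sensitivity": self.average_sensitivity,
                "specificity": self.average_specificity,
                "accuracy": self.average_accuracy,
            },
            "overall_accuracy": self.overall_accuracy,
        }


def one_nn_predict(
    matrix: DistanceMatrix, labels: Mapping[str, str]
) -> dict[str, str]:
    """Leave-one-out 1-NN prediction over a labeled distance matrix.

    Ties in nearest-neighbor distance are broken by the smallest matrix
    index, making predictions deterministic for a fixed input order.
    """
    missing = [lab for lab in matrix.labels if lab not in labels]
    if missing:
        raise ValueError(f"records without class labels: {missing}")
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least 2 records for 1-NN")
    if len(set(labels[lab] for lab in matrix.labels)) < 2:
        raise ValueError("need at least 2 classes represented")

    from collections import Counter

    singles = [c for c, k in Counter(labels[lab] for lab in matrix.labels).items() if k == 1]
    for c in singles:
        logger.warning(
            "class %r has a single member; its leave-one-out prediction is "
            "necessarily another class",
            c,
        )

    d = matrix.d.copy()
    np.fill_diagonal(d, np.inf)
    nearest = np.argmin(d, axis=1)  # argmin takes the first minimum: tie rule
    return {
        matrix.labels[i]: labels[matrix.labels[int(nearest[i])]] for i in range(n)
    }


def confusion_counts(
    truth: Mapping[str, str], predicted: Mapping[str, str]
) -> ConfusionCounts:
    """One-vs-rest confusion tallies over all classes in the truth."""
    if set(truth) != set(predicted):
        diff = set(truth) ^ set(predicted)
        raise ValueError(f"truth/prediction id sets differ: {sorted(diff)}")
    classes = sorted(set(truth.values()) | set(predicted.values()))
    per_class = {}
    for c in classes:
        tp = sum(1 for i in truth if truth[i] == c and predicted[i] == c)
        fn = sum(1 for i in truth if truth[i] == c and predicted[i] != c)
        fp = sum(1 for i in truth if truth[i] != c and predicted[i] == c)
        tn = sum(1 for i in truth if truth[i] != c and predicted[i] != c)
        per_class[c] = (tp, fn, fp, tn)
    return ConfusionCounts(per_class=per_class, total=len(truth))


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metrics(counts: ConfusionCounts) -> ClassificationReport:
    """Sensitivity, specificity, accuracy per class plus averages.

    Classes with no true members yield NaN metrics and are excluded from
    the averages (with a warning).
    """
    per_class: dict[str, ClassMetrics] = {}
    correct_total = 0
    for c, (tp, fn, fp, tn) in counts.per_class.items():
        if tp + fn == 0:
            logger.warning("class %r has no true members; metrics undefined", c)
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, fp + tn)
        per_class[c] = ClassMetrics(
            n_members=tp + fn, sensitivity=sens, specificity=spec, accuracy=sens
        )
        correct_total += tp

    defined = [m for m in per_class.values() if not math.isnan(m.sensitivity)]
    return ClassificationReport(
        classes=per_class,
        average_sensitivity=float(np.mean([m.sensitivity for m in defined])),
        average_specificity=float(np.mean([m.specificity for m in defined])),
        average_accuracy=float(np.mean([m.accuracy for m in defined])),
        overall_accuracy=correct_total / counts.total,
    )


def write_report(
    report: ClassificationReport,
    path: Union[str, Path],
    json_path: Union[str, Path, None] = None,
) -> None:
    """Write the report as a delimited table (Type, Number, Sens, Spec, Acc,
    percentages to 1 d.p.) and optionally a machine-readable JSON twin."""

    def pct(x: float) -> str:
        return "NA" if math.isnan(x) else f"{100 * x:.1f}"

    with open(path, "wt", encoding="ascii") as fh:
        fh.write("Type\tNumber\tSens(%)\tSpec(%)\tAcc(%)\n")
        for c, m in report.classes.items():
            fh.write(
                f"{c}\t{m.n_members}\t{pct(m.sensitivity)}\t"
                f"{pct(m.specificity)}\t{pct(m.accuracy)}\n"
            )
        fh.write(
            f"Ave.\t\t{pct(report.average_sensitivity)}\t"
            f"{pct(report.average_specificity)}\t{pct(report.average_accuracy)}\n"
        )
        fh.write(f"Overall\t\t\t\t{pct(report.overall_accuracy)}\n")
    if json_path is not None:
        with open(json_path, "wt", encoding="ascii") as fh:
            json.dump(report.to_dict(), fh, indent=2)
            fh.write("\n")
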