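"""Patient- and image-level evaluation metrics from prediction tables.

Input is a table with ``patient_id``, ``true_label`` and ``pred_label``
columns (plus per-class probability columns for ROC analysis).  The positive
class is malignant by convention.  Metrics whose denominator is undefined are
reported as ``None`` (missing), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PatientScore",
    "EvalCounts",
    "patient_level",
    "image_level",
    "counts_from_predictions",
    "ppv",
    "kappa",
    "f1_precision_recall",
    "roc_points",
    "evaluate_predictions",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = "malignant"


@dataclass
class PatientScore:
    """Fraction of one patient's test images classified correctly."""

    patient_id: str
    n_images: int
    n_correct: int

    def __post_init__(self):
        if not 0 <= self.n_correct <= self.n_images or self.n_images < 1:
            raise ValueError("need 0 <= n_correct <= n_images, n_images >= 1")

    @property
    def score(self) -> float:
        return self.n_correct / self.n_images


@dataclass
class EvalCounts:
    """Binary confusion tallies."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def chance_agreement(self) -> float:
        """Product of observed marginals: p(pred+)p(true+) + p(pred-)p(true-)."""
        t = self.total
        p_pred_pos = (self.tp + self.fp) / t
        p_true_pos = (self.tp + self.fn) / t
        return p_pred_pos * p_true_pos + (1 - p_pred_pos) * (1 - p_true_pos)


def _check_frame(predictions: pd.DataFrame) -> pd.DataFrame:
    if len(predictions) == 0:
        raise ValueError("empty prediction table")
    for col in ("patient_id", "true_label", "pred_label"):
        if col not in predictions.columns:
            raise ValueError(f"prediction table is missing column {col!r}")
    return predictions


def patient_level(predictions: pd.DataFrame) -> tuple[float, list[PatientScore]]:
    """Mean per-patient score: PL = sum(PS) / n_patients."""
    df = _check_frame(predictions)
    scores = []
    for pid, grp in df.groupby("patient_id", sort=False):
        correct = int((grp["true_label"] == grp["pred_label"]).sum())
        scores.append(PatientScore(str(pid), len(grp), correct))
    pl = float(np.mean([s.score for s in scores]))
    return pl, scores


def image_level(predictions: pd.DataFrame) -> float:
    """Pooled accuracy over all test images."""
    df = _check_frame(predictions)
    return float((df["true_label"] == df["pred_label"]).mean())


def counts_from_predictions(predictions: pd.DataFrame,
                            positive_class: str = POSITIVE_CLASS) -> EvalCounts:
    df = _check_frame(predictions)
    truth_pos = df["true_label"] == positive_class
    pred_pos = df["pred_label"] == positive_class
    return EvalCounts(
        tp=int((truth_pos & pred_pos).sum()),
        tn=int((~truth_pos & ~pred_pos).sum()),
        fp=int((~truth_pos & pred_pos).sum()),
        fn=int((truth_pos & ~pred_pos).sum()),
    )


def ppv(counts: EvalCounts) -> float | None:
    """Positive predictive value TP / (TP + FP); None when undefined."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom > 0 else None


def kappa(counts: EvalCounts) -> float | None:
    """Chance-corrected agreement (Acc - Acc_r) / (1 - Acc_r)."""
    if counts.total == 0:
        return None
    acc_r = counts.chance_agreement
    if acc_r >= 1.0:
        return None
    return (counts.accuracy - acc_r) / (1.0 - acc_r)


def f1_precision_recall(counts: EvalCounts
                        ) -> tuple[float | None, float | None, float | None]:
    precision = ppv(counts)
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return f1, precision, recall


def roc_points(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """(FPR, TPR) threshold sweep over unique scores, plus trapezoidal area.

    ``labels`` are truthy for the positive class; requires at least one
    positive and one negative.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[j] == s[i]:
            tp += int(y[j])
            fp += int(~y[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    area = float(np.trapezoid(tpr, fpr))
    return points, area


def evaluate_predictions(predictions: pd.DataFrame,
                         positive_class: str = POSITIVE_CLASS) -> dict:
    """Full metrics report from a prediction table."""
    pl, scores = patient_level(predictions)
    counts = counts_from_predictions(predictions, positive_class)
    f1, precision, recall = f1_precision_recall(counts)
    report = {
        "patient_level": pl,
        "image_level": image_level(predictions),
        "ppv": ppv(counts),
        "kappa": kappa(counts),
        "f1": f1,
        "precision": precision,
        "recall": recall,
        "n_patients": len(scores),
        "n_images": int(counts.total),
        "counts": {"tp": counts.tp, "tn": counts.tn,
                   "fp": counts.fp, "fn": counts.fn},
    }
    score_col = f"P_{positive_class}"
    if score_col in predictions.columns:
        truth = (predictions["true_label"] == positive_class).to_numpy()
        if truth.any() and not truth.all():
            _, area = roc_points(predictions[score_col].to_numpy(dtype=float), truth)
            report["roc_area"] = area
        else:
            report["roc_area"] = None
    return report
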