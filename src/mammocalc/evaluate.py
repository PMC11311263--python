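"""Classification and localization scoring.

Implements the standard confusion-matrix metrics for the binary
calcification decision —

    recall      = TP / (TP + FN)          (sensitivity)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / total
    F1          = 2 * precision * recall / (precision + recall)

— with degenerate denominators flagged as undefined rather than silently
zero-filled, plus ROC/AUC, per-outcome probability export, and a quantitative
localization score that greedily matches candidate centroids to planted spot
centres within a radius (default: planted spot radius + 2 px).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .localize import RegionCandidate
from .phantom import PhantomTruth

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "localization_score",
    "probability_distribution_export",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    recall: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    f1: float | None
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"recall": self.recall, "specificity": self.specificity,
                "precision": self.precision, "accuracy": self.accuracy,
                "f1": self.f1, "undefined": list(self.undefined)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def confusion(pred_labels, true_labels) -> ConfusionMatrix:
    """Exact TP/FP/FN/TN counts from two equal-length binary sequences."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    for arr, name in ((pred, "predictions"), (true, "truth")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The five confusion-matrix metrics, with undefined cases flagged."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    specificity = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    accuracy = (cm.tp + cm.tn) / cm.total
    if precision is None or recall is None:
        undefined.append("f1")
        f1 = None
    elif precision + recall == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(recall=recall, specificity=specificity,
                         precision=precision, accuracy=accuracy, f1=f1,
                         undefined=tuple(undefined))


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep over unique scores) and trapezoid AUC.

    Ties are handled by rank-averaging, so the AUC equals the Mann-Whitney
    statistic P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return points, auc


def localization_score(candidates: list[RegionCandidate], truth: PhantomTruth,
                       match_radius_px: float | None = None
                       ) -> tuple[float | None, float | None, list[tuple[int, int]]]:
    """Greedy one-to-one matching of candidates to planted spots.

    Pairs are matched in order of ascending centroid-to-centre distance
    within ``match_radius_px`` (default: mean planted spot radius + 2 px).
    Returns (spot_recall, candidate_precision, matched index pairs); a
    recall/precision is None when its denominator is empty.
    """
    spots = truth.spots
    if match_radius_px is None:
        if spots:
            match_radius_px = float(np.mean([s.diameter_px for s in spots]) / 2.0 + 2.0)
        else:
            match_radius_px = 3.0
    if match_radius_px <= 0:
        raise ValueError("match_radius_px must be positive")

    pairs = []
    for ci, cand in enumerate(candidates):
        for si, spot in enumerate(spots):
            dist = float(np.hypot(cand.centroid[0] - spot.row,
                                  cand.centroid[1] - spot.col))
            if dist <= match_radius_px:
                pairs.append((dist, ci, si))
    pairs.sort()
    used_c: set[int] = set()
    used_s: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, ci, si in pairs:
        if ci in used_c or si in used_s:
            continue
        used_c.add(ci)
        used_s.add(si)
        matched.append((ci, si))
    recall = len(matched) / len(spots) if spots else None
    precision = len(matched) / len(candidates) if candidates else None
    return recall, precision, matched


def probability_distribution_export(probabilities, pred_labels, true_labels,
                                    path=None) -> dict[str, list[float]]:
    """Split predicted probabilities into TP/FP/TN/FN lists.

    Optionally writes a two-column CSV (outcome, probability) for plotting.
    """
    prob = np.asarray(probabilities, dtype=np.float64)
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if not (prob.shape == pred.shape == true.shape):
        raise ValueError("inputs must have equal lengths")
    out = {
        "tp": prob[(pred == 1) & (true == 1)].tolist(),
        "fp": prob[(pred == 1) & (true == 0)].tolist(),
        "tn": prob[(pred == 0) & (true == 0)].tolist(),
        "fn": prob[(pred == 0) & (true == 1)].tolist(),
    }
    if path is not None:
        rows = [{"outcome": k, "probability": p} for k, ps in out.items() for p in ps]
        pd.DataFrame(rows, columns=["outcome", "probability"]).to_csv(path, index=False)
    return out
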