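"""Retrospective virtual-screening statistics.

Confusion matrices and the derived screening metrics, the docking-score
cutoff scan, and the replication-count selection rule.

The enrichment factor used here is the positive likelihood ratio,

    EF = sensitivity / false-positive rate = [TP/(TP+FN)] / [FP/(FP+TN)],

i.e. how many times more likely an active is to be flagged than a decoy.
(This is not the top-fraction EF of ranking studies; it is the natural
enrichment measure for a binary classify-the-whole-library protocol.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "metrics",
    "confusion",
    "classify_by_score",
    "scan_cutoff",
    "select_replication",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary screening outcome counts (active = positive class)."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_actives(self) -> int:
        return self.TP + self.FN

    @property
    def n_decoys(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    precision: float
    F1: float
    BA: float
    EF: float


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Screening statistics from a confusion matrix.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP) (0 when nothing is predicted active);
    F1 = 2·TP/(2·TP+FP+FN); BA = (sensitivity+specificity)/2;
    EF = sensitivity / FPR (+inf when FP = 0 and TP > 0, 0 when TP = 0).

    Requires at least one labelled active and one labelled decoy.
    """
    if cm.n_actives == 0 or cm.n_decoys == 0:
        raise ValueError("metrics need ≥1 active and ≥1 decoy")
    sens = cm.TP / cm.n_actives
    spec = cm.TN / cm.n_decoys
    prec = cm.TP / (cm.TP + cm.FP) if (cm.TP + cm.FP) else 0.0
    f1 = 2 * cm.TP / (2 * cm.TP + cm.FP + cm.FN) if cm.TP else 0.0
    fpr = cm.FP / cm.n_decoys
    if cm.TP == 0:
        ef = 0.0
    elif fpr == 0.0:
        ef = math.inf
    else:
        ef = sens / fpr
    return Metrics(sensitivity=sens, specificity=spec, precision=prec,
                   F1=f1, BA=(sens + spec) / 2, EF=ef)


def confusion(labels, predictions, forced_negative=None) -> ConfusionMatrix:
    """Count TP/FN/TN/FP from binary labels and predictions.

    ``forced_negative`` optionally marks compounds that never entered the
    pipeline (e.g. failed structure preparation); they are counted as
    predicted inactive regardless of ``predictions``.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if forced_negative is not None:
        forced = np.asarray(forced_negative, dtype=bool)
        predictions = np.where(forced, 0, predictions)
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    return ConfusionMatrix(TP=tp, FN=fn, TN=tn, FP=fp)


def classify_by_score(dg_values, cutoff: float) -> np.ndarray:
    """Predict active iff dg ≤ cutoff (a "maximum cutoff docking score";
    the boundary value itself counts as active)."""
    return (np.asarray(dg_values, dtype=float) <= cutoff).astype(int)


def scan_cutoff(dg_values, labels) -> tuple[float, float, list[tuple[float, float]]]:
    """Scan every distinct dg value as the classification cutoff.

    Returns ``(best_cutoff, best_F1, curve)`` where ``curve`` is the list of
    (cutoff, F1) pairs over all distinct scores, most negative first.  Ties
    on F1 go to the most negative (strictest) cutoff.
    """
    dg = np.asarray(dg_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("scan needs ≥1 active and ≥1 decoy")
    curve = []
    best_cutoff, best_f1 = math.nan, -1.0
    for cutoff in np.unique(dg):  # ascending, so strictest first
        m = metrics(confusion(y, classify_by_score(dg, cutoff)))
        curve.append((float(cutoff), m.F1))
        if m.F1 > best_f1:
            best_cutoff, best_f1 = float(cutoff), m.F1
    return best_cutoff, best_f1, curve


def select_replication(f1_by_k: dict[int, float], tolerance: float = 0.0) -> int:
    """Smallest replicate count whose F1 is within ``tolerance`` of the best.

    Encodes the protocol-economy rule: once additional docking replicates
    stop improving F1, use the fewest runs that achieve the plateau.
    """
    if not f1_by_k:
        raise ValueError("empty F1 series")
    if tolerance < 0:
        raise ValueError("tolerance must be ≥ 0")
    best = max(f1_by_k.values())
    return min(k for k, f1 in f1_by_k.items() if f1 >= best - tolerance)
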