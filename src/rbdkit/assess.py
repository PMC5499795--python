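"""Classifier assessment: confusion-matrix metrics, ROC/AUC, cut-off
optimization, and residue-interval overlap sensitivity.

Metric definitions (TP/FP/TN/FN true/false positives/negatives):

    SN  = TP / (TP + FN)                      sensitivity (true positive rate)
    SP  = TN / (TN + FP)                      specificity
    ACC = (TP + TN) / (TP + TN + FP + FN)     accuracy
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))
    F   = 2 * SN * SP / (SN + SP)

Note the F-measure here is the harmonic mean of sensitivity and
SPECIFICITY, not the precision/recall F1 — a deliberate, documented choice.
Any metric with a zero denominator is defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateLabelsError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts", "Metrics", "ROCCurve", "metrics", "roc",
    "optimize_cutoff", "CutoffResult", "residue_overlap", "OverlapReport",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero (report convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float
    fmeasure: float

    def rounded(self, decimals: int = 2) -> "Metrics":
        return Metrics(*(round_half_up(v, decimals) for v in
                         (self.sn, self.sp, self.acc, self.mcc, self.fmeasure)))


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(c: ConfusionCounts) -> Metrics:
    """The five binary-classification metrics from a confusion matrix."""
    sn = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn)
    denom = sqrt(
        float(c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(c.tp * c.tn - c.fn * c.fp, denom)
    fmeasure = _ratio(2.0 * sn * sp, sn + sp)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc, fmeasure=fmeasure)


@dataclass
class ROCCurve:
    """ROC points ordered by FPR, with trapezoidal AUC."""

    points: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    auc: float


def _check_labels(labels: Sequence[bool]) -> np.ndarray:
    arr = np.asarray(labels, dtype=bool)
    if arr.all() or (~arr).all():
        raise DegenerateLabelsError("both classes must be present")
    return arr


def roc(scores: Sequence[float], labels: Sequence[bool]) -> ROCCurve:
    """ROC curve over the distinct score thresholds, high to low.

    Tied scores cross each threshold together. AUC is the trapezoidal area,
    equal to the probability that a random positive outscores a random
    negative (with ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    arr = _check_labels(labels)
    if len(scores) != len(arr):
        raise ValueError("scores and labels differ in length")
    fpr, tpr, thresholds = _sk_roc_curve(arr, scores, drop_intermediate=False)
    area = float(_sk_auc(fpr, tpr))
    points = [(float(f), float(t), float(th))
              for f, t, th in zip(fpr, tpr, thresholds)]
    return ROCCurve(points=points, auc=area)


@dataclass
class CutoffResult:
    threshold: float
    counts: ConfusionCounts
    metrics: Metrics
    direction: str
    sweep: list[dict]  # one row per swept threshold, for plotting/reports


def _confusion_at(values: np.ndarray, labels: np.ndarray, t: float,
                  direction: str) -> ConfusionCounts:
    if direction == "min-threshold":
        pred = values >= t
    else:
        pred = values <= t
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def optimize_cutoff(
    values: Sequence[float],
    labels: Sequence[bool],
    direction: str = "min-threshold",
) -> CutoffResult:
    """Sweep every distinct value as a cut-off and pick the best.

    ``min-threshold`` predicts positive when value >= t (coverage,
    similarity, identity); ``max-threshold`` when value <= t (E-value, gap
    fraction). The chosen threshold maximizes accuracy; ties break toward
    higher Youden's J (TPR - FPR), then toward the less stringent
    threshold. The full sweep table is returned for ROC-style plots.
    """
    if direction not in ("min-threshold", "max-threshold"):
        raise ValueError(f"unknown direction {direction!r}")
    vals = np.asarray(values, dtype=float)
    labs = _check_labels(labels)
    if len(vals) != len(labs):
        raise ValueError("values and labels differ in length")
    sweep: list[dict] = []
    best: tuple | None = None
    best_row: dict | None = None
    for t in np.unique(vals):
        c = _confusion_at(vals, labs, float(t), direction)
        m = metrics(c)
        youden = m.sn - (1.0 - m.sp)
        row = {"threshold": float(t), "counts": c, "metrics": m,
               "tpr": m.sn, "fpr": 1.0 - m.sp, "youden": youden}
        sweep.append(row)
        # less stringent = smaller t for min-threshold, larger for max-threshold
        leniency = -float(t) if direction == "min-threshold" else float(t)
        key = (m.acc, youden, leniency)
        if best is None or key > best:
            best = key
            best_row = row
    assert best_row is not None
    return CutoffResult(
        threshold=best_row["threshold"],
        counts=best_row["counts"],
        metrics=best_row["metrics"],
        direction=direction,
        sweep=sweep,
    )


@dataclass
class OverlapReport:
    """Residue-level agreement between predicted sites and known binding residues."""

    per_protein: dict[str, float]       # overlap fraction per assessable protein
    recovered: dict[str, bool]          # fraction > 0
    sensitivity: float                  # recovered / assessable
    n_high_overlap: int                 # proteins with fraction > 0.70
    n_total: int
    excluded: list[str]                 # proteins with no annotated residues


def residue_overlap(
    predicted_intervals: Mapping[str, Iterable[tuple[int, int]]],
    binding_residues: Mapping[str, Iterable[int]],
    high_overlap_cutoff: float = 0.70,
) -> OverlapReport:
    """Fraction of annotated binding residues inside predicted site intervals.

    A protein counts as recovered when at least one of its binding residues
    falls inside the union of its predicted intervals; cohort sensitivity is
    the recovered fraction. Proteins without annotated residues are excluded
    with a warning.
    """
    per_protein: dict[str, float] = {}
    recovered: dict[str, bool] = {}
    excluded: list[str] = []
    for protein, residues in binding_residues.items():
        residues = list(residues)
        if not residues:
            logger.warning("protein %s has no annotated residues; excluded", protein)
            excluded.append(protein)
            continue
        covered: set[int] = set()
        for start, end in predicted_intervals.get(protein, []):
            if start < 1 or end < start:
                raise ValueError(f"bad interval ({start}, {end}) for {protein}")
            covered.update(range(start, end + 1))
        inside = sum(1 for r in residues if r in covered)
        frac = inside / len(residues)
        per_protein[protein] = frac
        recovered[protein] = frac > 0.0
    n_total = len(per_protein)
    sens = _ratio(sum(recovered.values()), n_total)
    n_high = sum(1 for f in per_protein.values() if f > high_overlap_cutoff)
    return OverlapReport(
        per_protein=per_protein, recovered=recovered, sensitivity=sens,
        n_high_overlap=n_high, n_total=n_total, excluded=excluded,
    )
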