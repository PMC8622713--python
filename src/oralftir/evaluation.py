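"""Grouped venetian-blinds cross-validation and binary performance metrics.

Folds interleave samples: samples are ordered lexicographically by id and
sample j goes to fold j mod k, both of its representative spectra riding
together (no sample is ever split across folds). Metrics use OSCC (class C)
as the positive class: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
plus an ROC curve and its trapezoidal AUC over the pooled held-out scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dataset import SpectrumSet

POSITIVE_CLASS = "C"  # OSCC


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """Per-row fold indices, grouped by sample."""

    folds: np.ndarray  # (n_rows,)
    sample_order: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        self.folds = np.asarray(self.folds, dtype=int)


def venetian_blinds(sample_ids: Sequence[str] | SpectrumSet, k: int = 10) -> FoldAssignment:
    """Interleaved grouped folds: sorted sample j -> fold j mod k.

    Every sample must contribute exactly two rows (its representative
    pair); both inherit the sample's fold.
    """
    if isinstance(sample_ids, SpectrumSet):
        sample_ids = sample_ids.sample_ids
    sample_ids = np.asarray(sample_ids)
    unique, counts = np.unique(sample_ids, return_counts=True)
    if not np.all(counts == 2):
        bad = unique[counts != 2].tolist()
        raise ValueError(f"every sample needs exactly 2 spectra; violated by {bad}")
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    if k > unique.size:
        raise ValueError(f"k={k} exceeds the {unique.size} available samples")
    order = tuple(sorted(unique))
    fold_of = {sid: j % k for j, sid in enumerate(order)}
    folds = np.array([fold_of[sid] for sid in sample_ids])
    return FoldAssignment(folds=folds, sample_order=order, k=k)


# ---------------------------------------------------------------------------
# confusion matrix, sensitivity/specificity, ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_matrix(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionMatrix:
    t = np.asarray(y_true) == POSITIVE_CLASS
    p = np.asarray(y_pred) == POSITIVE_CLASS
    return ConfusionMatrix(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive-class rows")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP)."""
    if cm.tn + cm.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative-class rows")
    return cm.tn / (cm.tn + cm.fp)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> ROCCurve:
    """ROC over all score thresholds with trapezoidal AUC (ties step jointly)."""
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    y = (labels == POSITIVE_CLASS).astype(int)
    fpr, tpr, thresholds = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Pooled held-out predictions plus headline metrics."""

    folds: FoldAssignment
    predictions: pd.DataFrame  # row-aligned: sample_id, fold, y_true, score, y_pred
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    roc: ROCCurve
    calibration_confusion: ConfusionMatrix | None = None
    calibration_roc: ROCCurve | None = None

    def to_dict(self) -> dict:
        out = {
            "k": self.folds.k,
            "confusion": vars(self.confusion),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.roc.auc,
        }
        if self.calibration_confusion is not None:
            out["calibration_confusion"] = vars(self.calibration_confusion)
        if self.calibration_roc is not None:
            out["calibration_auc"] = self.calibration_roc.auc
        return out


def cross_validate(
    model_factory: Callable[[SpectrumSet, np.ndarray], object],
    spectra: SpectrumSet,
    labels: Sequence[str],
    folds: FoldAssignment,
    calibration: bool = True,
) -> CVReport:
    """Fit on each fold's complement, predict the held-out rows, pool.

    ``model_factory(train_set, train_labels)`` must return an object with
    ``predict_scores(set)`` and ``predict_classes(scores)`` (PLSDA and the
    comparators both qualify). The grouping invariant - no sample split
    across folds - is asserted on every run.
    """
    labels = np.asarray(labels)
    fold_ids = folds.folds
    for sid in np.unique(spectra.sample_ids):
        if len(set(fold_ids[spectra.sample_ids == sid])) != 1:
            raise AssertionError(f"sample {sid} is split across folds")

    n = spectra.n_spectra
    scores = np.empty(n)
    y_pred = np.empty(n, dtype=object)
    for f in np.unique(fold_ids):
        held = fold_ids == f
        model = model_factory(spectra.select_rows(~held), labels[~held])
        s = model.predict_scores(spectra.select_rows(held))
        scores[held] = s
        y_pred[held] = model.predict_classes(s)

    cm = confusion_matrix(labels, y_pred)
    report = CVReport(
        folds=folds,
        predictions=pd.DataFrame(
            {
                "sample_id": spectra.sample_ids,
                "fold": fold_ids,
                "y_true": labels,
                "score": scores,
                "y_pred": y_pred.astype(str),
            }
        ),
        confusion=cm,
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        roc=roc_auc(scores, labels),
    )
    if calibration:
        full = model_factory(spectra, labels)
        cal_scores = full.predict_scores(spectra)
        cal_pred = full.predict_classes(cal_scores)
        report.calibration_confusion = confusion_matrix(labels, cal_pred)
        report.calibration_roc = roc_auc(cal_scores, labels)
    return report
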