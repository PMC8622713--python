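"""Comparator classifiers behind the same fit/predict contract as PLSDA.

Two comparators are supported: an RBF-kernel support vector machine and
gradient-boosted decision trees. Both expose scores on the same 0..1 scale
with the 0.5 decision threshold, and both tune their hyperparameters by
grid search under the caller-supplied grouped folds, so fold assignments
are byte-identical to the PLSDA evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SpectrumSet

DEFAULT_GRIDS = {
    "svm_rbf": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1, 1.0]},
    "gradient_boosted_trees": {
        "n_estimators": [50, 200],
        "max_depth": [2, 3],
        "learning_rate": [0.1, 0.3],
    },
}


@dataclass(frozen=True)
class ComparatorSpec:
    """Which comparator to fit and over which hyperparameter grid."""

    kind: str
    hyperparameters: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_GRIDS:
            raise ValueError(
                f"unknown comparator {self.kind!r}; expected one of {sorted(DEFAULT_GRIDS)}"
            )

    def grid(self) -> dict:
        return self.hyperparameters or DEFAULT_GRIDS[self.kind]


@dataclass
class ComparatorModel:
    """A fitted comparator honoring the PLSDA predict contract."""

    kind: str
    estimator: object
    hyperparameters: dict
    wavenumbers: np.ndarray
    threshold: float = 0.5

    def predict_scores(self, spectra: SpectrumSet) -> np.ndarray:
        if not np.array_equal(spectra.grid.values, self.wavenumbers):
            raise ValueError("spectra are not on the model's wavenumber grid")
        X = spectra.intensities
        if self.kind == "svm_rbf":
            # squash the SVM margin onto the 0..1 score scale, 0 margin -> 0.5
            margin = self.estimator.decision_function(X)
            return 1.0 / (1.0 + np.exp(-margin))
        return self.estimator.predict_proba(X)[:, 1]

    def predict_classes(self, scores: np.ndarray) -> np.ndarray:
        return np.where(scores >= self.threshold, "C", "H")


def _build_estimator(kind: str, params: dict, seed: int):
    if kind == "svm_rbf":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", random_state=seed, **params)
    try:
        from xgboost import XGBClassifier
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise RuntimeError(
            "the gradient_boosted_trees comparator requires xgboost; "
            "install the 'comparators' extra (PLSDA is unaffected)"
        ) from exc
    return XGBClassifier(
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        **params,
    )


def fit_comparator(
    spec: ComparatorSpec,
    spectra: SpectrumSet,
    labels: Sequence[str],
    folds: np.ndarray,
    seed: int = 0,
) -> ComparatorModel:
    """Grid-search hyperparameters under the given folds, refit on all rows.

    The selection criterion is pooled CV misclassification; ties resolve to
    the first candidate in grid order, so the result is deterministic.
    """
    labels = np.asarray(labels)
    y = (labels == "C").astype(int)
    folds = np.asarray(folds)
    X = spectra.intensities

    grid = spec.grid()
    keys = sorted(grid)
    grid = {k: v if isinstance(v, (list, tuple)) else [v] for k, v in grid.items()}
    candidates = [dict(zip(keys, values)) for values in product(*(grid[k] for k in keys))]
    if len(candidates) == 1:  # fixed hyperparameters: nothing to search
        final = _build_estimator(spec.kind, candidates[0], seed)
        final.fit(X, y)
        return ComparatorModel(
            kind=spec.kind,
            estimator=final,
            hyperparameters=candidates[0],
            wavenumbers=spectra.grid.values.copy(),
        )
    best_params, best_err = None, np.inf
    for params in candidates:
        wrong = 0
        for f in np.unique(folds):
            est = _build_estimator(spec.kind, params, seed)
            est.fit(X[folds != f], y[folds != f])
            wrong += int((est.predict(X[folds == f]) != y[folds == f]).sum())
        err = wrong / len(y)
        if err < best_err:
            best_params, best_err = params, err

    final = _build_estimator(spec.kind, best_params, seed)
    final.fit(X, y)
    return ComparatorModel(
        kind=spec.kind,
        estimator=final,
        hyperparameters=best_params,
        wavenumbers=spectra.grid.values.copy(),
    )
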