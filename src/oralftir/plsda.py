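"""Partial least squares discriminant analysis (PLSDA) for HK vs OSCC.

The model is PLS1 fitted by NIPALS with X-block deflation: the single
response is the class code (H -> 0, C -> 1) and each latent variable (LV)
is the direction in spectral space maximizing covariance with the residual
response. Prediction is linear, ``y_hat = (x - x_mean) . b + y_mean``, and
classification thresholds y_hat at 0.5 (ties go to the positive class C).
LV-count selection minimizes the grouped cross-validation classification
error; feature bands are the prominent extrema of the LV loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SpectrumSet

#: Class coding of the single PLS response.
CLASS_CODING = {"H": 0.0, "C": 1.0}


@dataclass
class PLSDAModel:
    """Fitted PLS1 discriminant model.

    Houses the latent-variable decomposition (X = t p^T + E, y = u q^T + f):
    ``weights`` W, ``x_loadings`` P, ``x_scores`` T, ``y_loadings`` q and
    ``y_scores`` U (for a single response, each u_k is the running response
    residual before LV k is extracted), plus the assembled regression
    vector ``coef``.
    """

    wavenumbers: np.ndarray
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (k, p)
    x_loadings: np.ndarray  # (k, p)
    x_scores: np.ndarray  # (n, k)
    y_loadings: np.ndarray  # (k,)
    y_scores: np.ndarray  # (n, k)
    coef: np.ndarray  # (p,)
    explained_x_variance: np.ndarray  # (k,) percent
    threshold: float = 0.5
    input_mode: str = "derivative"

    def predict_scores(self, spectra: SpectrumSet) -> np.ndarray:
        if not np.array_equal(spectra.grid.values, self.wavenumbers):
            raise ValueError("spectra are not on the model's wavenumber grid")
        return (spectra.intensities - self.x_mean) @ self.coef + self.y_mean

    def predict_classes(self, scores: np.ndarray) -> np.ndarray:
        # ties at the threshold break toward the positive class C
        return np.where(scores >= self.threshold, "C", "H")


def _encode_labels(labels: Sequence[str]) -> np.ndarray:
    labels = np.asarray(labels)
    unknown = set(labels) - set(CLASS_CODING)
    if unknown:
        raise ValueError(f"labels must be binary H/C; got extra {sorted(unknown)}")
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes H and C")
    return np.array([CLASS_CODING[l] for l in labels])


def fit_plsda(
    spectra: SpectrumSet,
    labels: Sequence[str] | None = None,
    n_lv: int = 4,
    threshold: float = 0.5,
) -> PLSDAModel:
    """Fit PLS1 by NIPALS on centered X and the 0/1 class code.

    Per LV: weight w = X^T y / |X^T y|; score t = X w; X-loading
    p = X^T t / (t^T t); y-loading q = y^T t / (t^T t); deflate X by t p^T
    and y by q t. The regression vector is b = W (P^T W)^{-1} q.
    """
    if labels is None:
        labels = spectra.classes
    y = _encode_labels(labels)
    X = spectra.intensities
    n, p = X.shape
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} exceeds min(rows-1, cols)={min(n - 1, p)}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    total_var = (Xr**2).sum()

    W = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    T = np.zeros((n, n_lv))
    U = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    explained = np.zeros(n_lv)

    n_extracted = n_lv
    for k in range(n_lv):
        U[:, k] = yr
        w = Xr.T @ yr
        norm_w = np.linalg.norm(w)
        if norm_w < 1e-12:
            # response residual exhausted (perfectly fit): keep the LVs we have
            n_extracted = k
            break
        w /= norm_w
        t = Xr @ w
        tt = float(t @ t)
        pk = Xr.T @ t / tt
        qk = float(yr @ t) / tt
        Xr = Xr - np.outer(t, pk)
        yr = yr - qk * t
        W[k], P[k], T[:, k], q[k] = w, pk, t, qk
        explained[k] = 100.0 * tt * float(pk @ pk) / total_var if total_var > 0 else 0.0

    if n_extracted == 0:
        raise ValueError("could not extract a single latent variable (constant response?)")
    W, P, T, U, q = W[:n_extracted], P[:n_extracted], T[:, :n_extracted], U[:, :n_extracted], q[:n_extracted]
    explained = explained[:n_extracted]
    coef = W.T @ np.linalg.solve(P @ W.T, q)
    return PLSDAModel(
        wavenumbers=spectra.grid.values.copy(),
        n_lv=n_extracted,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=q,
        y_scores=U,
        coef=coef,
        explained_x_variance=explained,
        threshold=threshold,
        input_mode=spectra.mode,
    )


def predict(model: PLSDAModel, spectra: SpectrumSet) -> pd.DataFrame:
    """Per-row predicted score, class, and distance to the decision line."""
    scores = model.predict_scores(spectra)
    return pd.DataFrame(
        {
            "sample_id": spectra.sample_ids,
            "area_id": spectra.meta["area_id"],
            "score": scores,
            "predicted_class": model.predict_classes(scores),
            "margin": scores - model.threshold,
        }
    )


def explained_variance(model: PLSDAModel) -> np.ndarray:
    """Percent of (centered) X variance captured per LV."""
    return model.explained_x_variance.copy()


def select_n_lv(
    spectra: SpectrumSet,
    labels: Sequence[str],
    folds: np.ndarray,
    max_lv: int = 10,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Choose the LV count minimizing the CV classification error.

    Returns ``(n_lv, calibration_errors, cv_errors)``, the error curves
    indexed by LV count 1..max_lv. Ties on the minimum CV error resolve to
    the smallest LV count.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    n = spectra.n_spectra
    min_fit_rows = min(
        (folds != f).sum() for f in np.unique(folds)
    )
    max_lv = min(max_lv, min_fit_rows - 1, spectra.intensities.shape[1])

    cal_errors = np.zeros(max_lv)
    cv_errors = np.zeros(max_lv)
    for k in range(1, max_lv + 1):
        model = fit_plsda(spectra, labels, n_lv=k)
        cal_pred = model.predict_classes(model.predict_scores(spectra))
        cal_errors[k - 1] = float(np.mean(cal_pred != labels))
        wrong = 0
        for f in np.unique(folds):
            train = spectra.select_rows(folds != f)
            test = spectra.select_rows(folds == f)
            m = fit_plsda(train, labels[folds != f], n_lv=k)
            pred = m.predict_classes(m.predict_scores(test))
            wrong += int((pred != labels[folds == f]).sum())
        cv_errors[k - 1] = wrong / n
    n_lv = int(np.argmin(cv_errors) + 1)
    return n_lv, cal_errors, cv_errors


# ---------------------------------------------------------------------------
# feature-band extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureBand:
    """A prominent extremum of one LV loading."""

    wavenumber: float
    sign: str  # "+" or "-"
    lv_index: int  # 1-based
    loading_value: float


def extract_feature_bands(
    model: PLSDAModel,
    lv_indices: Sequence[int] = (1, 2),
    prominence_fraction: float = 0.5,
) -> list[FeatureBand]:
    """Local extrema of the selected LV loadings above a prominence floor.

    An extremum qualifies when its absolute loading is at least
    ``prominence_fraction`` times the largest absolute loading of that LV.
    The default of 0.5 is deliberately strict: on second-derivative inputs
    each Gaussian band contributes side lobes at ~0.45 of its central lobe,
    which this floor excludes. Bands are returned sorted by descending
    wavenumber within each LV.
    """
    bands: list[FeatureBand] = []
    for lv in lv_indices:
        if not (1 <= lv <= model.n_lv):
            raise ValueError(f"LV index {lv} outside 1..{model.n_lv}")
        loading = model.x_loadings[lv - 1]
        max_abs = np.abs(loading).max()
        if max_abs == 0:
            continue
        floor = prominence_fraction * max_abs
        interior = np.arange(1, loading.size - 1)
        is_max = (loading[interior] > loading[interior - 1]) & (
            loading[interior] >= loading[interior + 1]
        )
        is_min = (loading[interior] < loading[interior - 1]) & (
            loading[interior] <= loading[interior + 1]
        )
        for idx in interior[(is_max | is_min)]:
            value = loading[idx]
            if abs(value) < floor:
                continue
            bands.append(
                FeatureBand(
                    wavenumber=float(model.wavenumbers[idx]),
                    sign="+" if value > 0 else "-",
                    lv_index=int(lv),
                    loading_value=float(value),
                )
            )
    return bands


def feature_bands_frame(bands: Sequence[FeatureBand]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wavenumber": [b.wavenumber for b in bands],
            "sign": [b.sign for b in bands],
            "lv": [b.lv_index for b in bands],
            "loading_value": [b.loading_value for b in bands],
        }
    )
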