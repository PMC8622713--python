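"""The signal-correction chain applied to raw transmission spectra.

The general chain, in fixed order: transmission -> absorbance conversion
(A = log10(1/T)); fingerprint-region selection (1800-950 cm^-1);
Savitzky-Golay smoothing; extended multiplicative signal correction (EMSC)
against a reference spectrum; automated weighted least squares (AWLS)
baseline subtraction; vector (L2) normalization. For model building a
second-derivative step (7-point Savitzky-Golay) follows, with
re-normalization because differentiation destroys the unit norm.

The order is part of the method: configs that permute the chain are
rejected. Each step is independently callable.

Notes on individual steps:

* EMSC here is the basic variant - per-spectrum least squares fit of an
  offset, a multiplicative term against the reference, and a low-order
  polynomial background, then division by the multiplicative coefficient.
  It corrects multiplicative scatter and smooth backgrounds; it is not a
  physics-based resonant-Mie model.
* AWLS is an asymmetric 0/1-reweighted polynomial fit: points above the
  current baseline estimate (peaks) are dropped from the next fit, points
  at or below keep weight one, iterated until the weight sets stop
  changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectrumSet

logger = logging.getLogger(__name__)

#: The only admissible order of the general chain.
CANONICAL_STEPS = (
    "absorbance",
    "fingerprint",
    "smooth",
    "emsc",
    "awls",
    "normalize",
)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the correction chain.

    ``region`` is the retained fingerprint window in cm^-1 (high, low);
    smoothing is second-order Savitzky-Golay over ``smooth_window`` points;
    EMSC fits a polynomial background of order ``emsc_poly_order`` against
    the cohort-mean reference (or an explicit spectrum); AWLS fits an
    order-``awls_poly_order`` baseline; the optional modeling derivative is
    a 7-point second derivative.
    """

    region: tuple[float, float] = (1800.0, 950.0)
    smooth_window: int = 9
    smooth_polyorder: int = 2
    emsc_reference: str = "cohort_mean"  # or an explicit spectrum via emsc(...)
    emsc_poly_order: int = 2
    awls_poly_order: int = 2
    awls_max_iter: int = 50
    derivative_window: int = 7
    derivative_polyorder: int = 3
    apply_derivative: bool = False
    steps: tuple[str, ...] = CANONICAL_STEPS

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_polyorder:
            raise ValueError("smooth_window must be odd and exceed smooth_polyorder")
        if self.derivative_window % 2 == 0 or self.derivative_window <= self.derivative_polyorder:
            raise ValueError("derivative_window must be odd and exceed derivative_polyorder")
        if self.awls_poly_order > 4:
            raise ValueError("awls_poly_order should stay small (<= 4)")
        if tuple(self.steps) != CANONICAL_STEPS:
            raise ValueError(
                "the correction chain order is fixed: " + " -> ".join(CANONICAL_STEPS)
            )


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------


def transmittance_to_absorbance(spectra: SpectrumSet) -> SpectrumSet:
    """A = log10(1/T), elementwise."""
    if spectra.mode != "transmission":
        raise ValueError(f"expected transmission-mode data, got {spectra.mode!r}")
    bad = np.argwhere(spectra.intensities <= 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"nonpositive transmission at row {r}, wavenumber "
            f"{spectra.grid.values[c]:.1f} cm^-1 (first of {len(bad)})"
        )
    return spectra.with_intensities(-np.log10(spectra.intensities), mode="absorbance")


def select_fingerprint(
    spectra: SpectrumSet, region: tuple[float, float] = (1800.0, 950.0)
) -> SpectrumSet:
    """Drop wavenumbers outside the fingerprint window, preserving order."""
    high, low = max(region), min(region)
    mask = spectra.grid.region_mask(high, low)
    if mask.sum() < 2:
        raise ValueError(f"region {region} retains fewer than 2 grid points")
    return spectra.select_columns(mask)


def savgol(
    spectra: SpectrumSet, window: int, polyorder: int, deriv_order: int = 0
) -> SpectrumSet:
    """Per-row Savitzky-Golay smoothing / differentiation.

    Edge points use the polynomial fitted to the first/last full window, so
    interior values match a sliding windowed polynomial fit exactly.
    Derivatives are scaled by the grid spacing (the grid runs descending;
    even derivative orders are unaffected by direction, and the second
    derivative is the only one the pipeline uses).
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if window > spectra.intensities.shape[1]:
        raise ValueError(
            f"window {window} exceeds spectrum length {spectra.intensities.shape[1]}"
        )
    if deriv_order not in (0, 1, 2):
        raise ValueError("deriv_order must be 0, 1 or 2")
    out = savgol_filter(
        spectra.intensities,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv_order,
        delta=spectra.grid.spacing,
        axis=1,
        mode="interp",
    )
    mode = "derivative" if deriv_order > 0 else spectra.mode
    return spectra.with_intensities(out, mode=mode)


def emsc(
    spectra: SpectrumSet,
    reference: np.ndarray | None = None,
    poly_order: int = 2,
    min_scale: float = 1e-8,
) -> SpectrumSet:
    """Extended multiplicative signal correction against a reference.

    Each row ``s`` is modelled as ``s ~ a + b*m + sum_i d_i P_i(x)`` with
    ``m`` the reference and ``P_i`` Legendre polynomials in the scaled
    wavenumber; the corrected row is ``(s - a - sum d_i P_i) / b``. Rows
    whose fitted ``|b|`` falls below ``min_scale`` are returned uncorrected
    and logged (an ``emsc_flagged`` metadata column marks them).
    """
    X = spectra.intensities
    n, p = X.shape
    if reference is None:
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (p,):
        raise ValueError("EMSC reference must live on the set's grid")

    x = np.linspace(-1.0, 1.0, p)
    design = np.column_stack(
        [np.ones(p), reference] + [np.polynomial.legendre.Legendre.basis(i)(x) for i in range(1, poly_order + 1)]
    )
    coeffs, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (2 + poly_order, n)
    a, b = coeffs[0], coeffs[1]
    background = design[:, 2:] @ coeffs[2:] if poly_order >= 1 else 0.0

    flagged = np.abs(b) < min_scale
    if flagged.any():
        logger.warning("EMSC: %d row(s) with near-zero scale left uncorrected", flagged.sum())
    b_safe = np.where(flagged, 1.0, b)
    corrected = (X - a[None, :].T - np.atleast_2d(background).T) / b_safe[:, None]
    corrected[flagged] = X[flagged]

    out = spectra.with_intensities(corrected)
    out.meta["emsc_flagged"] = flagged
    return out


def awls_baseline(
    spectra: SpectrumSet,
    poly_order: int = 2,
    max_iter: int = 50,
    return_baseline: bool = False,
):
    """Asymmetric 0/1-reweighted polynomial baseline subtraction.

    Iteration: fit a weighted polynomial; points strictly above the fit get
    weight 0 (treated as peaks), points at or below keep weight 1; repeat
    until the weight sets stop changing or ``max_iter`` is hit (the last
    iterate is then used, with a logged warning). All rows are iterated
    together via batched
    normal equations.
    """
    X = spectra.intensities
    n, p = X.shape
    x = np.linspace(-1.0, 1.0, p)
    V = np.polynomial.legendre.legvander(x, poly_order)  # (p, k)

    k = V.shape[1]
    iu, ju = np.triu_indices(k)
    pairwise = V[:, iu] * V[:, ju]  # (p, k(k+1)/2): entries of V^T diag(w) V

    weights = np.ones((n, p))
    baseline = np.zeros_like(X)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        idx_active = np.flatnonzero(active)
        # rows left with fewer support points than coefficients keep their
        # last baseline (degenerate weight set; happens only on pathological
        # rows such as injected outliers)
        degenerate = weights[idx_active].sum(axis=1) < k
        if degenerate.any():
            converged[idx_active[degenerate]] = True
            active = ~converged
            if not active.any():
                break
        w = weights[active]
        # batched weighted normal equations: M c = r per row (BLAS-backed)
        entries = w @ pairwise
        M = np.empty((entries.shape[0], k, k))
        M[:, iu, ju] = entries
        M[:, ju, iu] = entries
        r = (w * X[active]) @ V
        coef = np.linalg.solve(M, r[..., None])[..., 0]
        fit = coef @ V.T
        baseline[active] = fit
        new_w = (X[active] <= fit).astype(float)
        unchanged = (new_w == w).all(axis=1)
        weights[active] = new_w
        idx = np.flatnonzero(active)
        converged[idx[unchanged]] = True
    else:
        if not converged.all():
            logger.warning(
                "AWLS: %d row(s) did not converge in %d iterations; using last iterate",
                (~converged).sum(),
                max_iter,
            )
    out = spectra.with_intensities(X - baseline)
    if return_baseline:
        return out, baseline
    return out


def vector_normalize(spectra: SpectrumSet, on_zero: str = "error") -> SpectrumSet:
    """Divide each row by its Euclidean norm over the retained region.

    ``on_zero`` controls zero-norm rows: ``"error"`` (default) raises naming
    the rows; ``"keep"`` leaves them unscaled — the full chain uses this so
    that saturated outlier pixels survive to be flagged by the T2/Q step.
    """
    norms = np.linalg.norm(spectra.intensities, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        if on_zero == "error":
            raise ValueError(f"cannot normalize all-zero row(s) {zero.tolist()}")
        logger.warning("vector_normalize: %d all-zero row(s) left unscaled", zero.size)
        norms[zero] = 1.0
    return spectra.with_intensities(spectra.intensities / norms[:, None])


def second_derivative(spectra: SpectrumSet, cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """7-point second-derivative transform plus re-normalization."""
    cfg = cfg or PreprocessConfig()
    out = savgol(spectra, cfg.derivative_window, cfg.derivative_polyorder, deriv_order=2)
    return vector_normalize(out, on_zero="keep")


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def preprocess_general(
    spectra: SpectrumSet,
    cfg: PreprocessConfig | None = None,
    emsc_reference: np.ndarray | None = None,
) -> SpectrumSet:
    """Run the full correction chain in its fixed order.

    Input must be transmission-mode. If ``emsc_reference`` is None the EMSC
    reference is the mean of the (smoothed) set itself; note that the
    reference must then live on the fingerprint grid.
    """
    cfg = cfg or PreprocessConfig()
    out = transmittance_to_absorbance(spectra)
    out = select_fingerprint(out, cfg.region)
    out = savgol(out, cfg.smooth_window, cfg.smooth_polyorder, deriv_order=0)
    out = emsc(out, reference=emsc_reference, poly_order=cfg.emsc_poly_order)
    out = awls_baseline(out, poly_order=cfg.awls_poly_order, max_iter=cfg.awls_max_iter)
    out = vector_normalize(out, on_zero="keep")
    if cfg.apply_derivative:
        out = second_derivative(out, cfg)
    return out
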