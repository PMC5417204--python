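"""Substandard-medicine detection: PLSR calibration with leave-one-out
cross-validation and tolerance-band classification of predicted content.

The regression is single-response NIPALS partial least squares on
quantitative-state spectra (smoothed, baseline-subtracted absorbance);
quantitation accuracy is summarized by the standard deviation of the
cross-validated residuals in percent-of-label units, and the 95 %
coverage half-width is twice that SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessConfig, preprocess_quantitative
from .spectra import QualityClass

__all__ = [
    "PLSRModel",
    "QuantReport",
    "fit_plsr",
    "predict",
    "loocv_predict",
    "fit_pcr",
    "r_squared",
    "normalized_residual_sd",
    "coverage_halfwidth",
    "tolerance_classify",
    "quantify_brand",
    "DEFAULT_TOLERANCE_BAND",
    "PHARMACOPEIA_BAND",
]

DEFAULT_TOLERANCE_BAND = (85.0, 115.0)
PHARMACOPEIA_BAND = (90.0, 110.0)


@dataclass
class PLSRModel:
    """Single-response PLSR model in compact regression form.

    Prediction is ``ŷ(x) = y_mean + (x - x_mean)ᵀ β``, which reproduces the
    component-wise NIPALS prediction exactly.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # p x a
    loadings: np.ndarray   # p x a
    y_loadings: np.ndarray  # length a
    coefficients: np.ndarray  # length p
    a: int
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.a < 1:
            raise ValueError("component count must be >= 1")


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (samples x wavelengths) matrix")
    return X


def fit_plsr(X, y, a: int = 3, grid=None) -> PLSRModel:
    """NIPALS PLS1: sequentially extract ``a`` covariance-maximizing
    components, then assemble β = W (PᵀW)⁻¹ q."""
    X = _as_matrix(X)
    y = np.asarray(y, float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must be a length-n vector")
    if n < a + 1:
        raise ValueError(f"need at least a+1={a + 1} samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress on")
    if a > min(n - 1, p):
        raise ValueError(f"a={a} exceeds min(n-1, p)={min(n - 1, p)}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    W = np.empty((p, a))
    P = np.empty((p, a))
    q = np.empty(a)
    w0 = np.linalg.norm(Xd.T @ yd)
    t0 = float(np.sum(Xd * Xd))
    n_extracted = 0
    for j in range(a):
        # stop when the deflated covariance (or score energy) is gone:
        # the requested rank exceeds the signal rank
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(w0, 1e-300):
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-24 * max(t0, 1e-300):
            break
        pj = Xd.T @ t / tt
        qj = float(yd @ t / tt)
        Xd = Xd - np.outer(t, pj)
        yd = yd - qj * t
        W[:, j], P[:, j], q[j] = w, pj, qj
        n_extracted += 1
    if n_extracted == 0:
        raise ValueError("spectra carry no covariance with y; cannot fit any component")
    W, P, q = W[:, :n_extracted], P[:, :n_extracted], q[:n_extracted]
    beta = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, loadings=P,
        y_loadings=q, coefficients=beta, a=n_extracted,
        grid=None if grid is None else np.asarray(grid, float),
    )


def predict(model: PLSRModel, X, grid=None) -> np.ndarray:
    """ŷ = y_mean + (X - x_mean) β."""
    X = _as_matrix(X)
    if X.shape[1] != model.x_mean.size:
        raise ValueError("spectra width does not match the model")
    if model.grid is not None and grid is not None:
        grid = np.asarray(grid, float)
        if grid.size != model.grid.size or not np.array_equal(grid, model.grid):
            raise ValueError("spectrum grid does not match the model grid")
    return model.y_mean + (X - model.x_mean) @ model.coefficients


def loocv_predict(X, y, a: int = 3, fit=fit_plsr) -> np.ndarray:
    """Leave-one-out predictions: ŷ_cv[i] from a model fit without sample i."""
    X = _as_matrix(X)
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < a + 2:
        raise ValueError(f"leave-one-out with a={a} needs at least a+2={a + 2} samples, got {n}")
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit(X[keep], y[keep], a)
        out[i] = predict(model, X[i : i + 1])[0]
    return out


def fit_pcr(X, y, a: int = 3, grid=None) -> PLSRModel:
    """Principal components regression with the same prediction contract."""
    X = _as_matrix(X)
    y = np.asarray(y, float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must be a length-n vector")
    if n < a + 1:
        raise ValueError(f"need at least a+1={a + 1} samples, got {n}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    if a > np.linalg.matrix_rank(Xc):
        raise ValueError(f"a={a} exceeds the rank of the centered spectra matrix")
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    V = vt[:a].T
    T = Xc @ V
    coef_scores, *_ = np.linalg.lstsq(T, y - y_mean, rcond=None)
    beta = V @ coef_scores
    return PLSRModel(
        x_mean=x_mean, y_mean=y_mean, weights=V, loadings=V,
        y_loadings=coef_scores, coefficients=beta, a=a,
        grid=None if grid is None else np.asarray(grid, float),
    )


def r_squared(y, y_hat) -> float:
    """1 - SS_res / SS_tot; may be negative for poor CV predictions."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y has zero variance")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def normalized_residual_sd(y, y_hat_cv) -> float:
    """Sample SD (n-1 denominator) of ŷ_cv - y, in percent-of-label units."""
    y = np.asarray(y, float)
    y_hat_cv = np.asarray(y_hat_cv, float)
    if y.shape != y_hat_cv.shape:
        raise ValueError("y and y_hat_cv must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 residuals")
    return float(np.std(y_hat_cv - y, ddof=1))


def coverage_halfwidth(resid_sd: float, factor: float = 2.0) -> float:
    """±half-width of the quantitation interval: factor × residual SD."""
    if resid_sd < 0 or factor < 0:
        raise ValueError("resid_sd and factor must be >= 0")
    return factor * resid_sd


def tolerance_classify(sapi_percent: float, band=DEFAULT_TOLERANCE_BAND) -> QualityClass:
    """quality_assured iff low <= value <= high (inclusive bounds)."""
    low, high = band
    if low > high:
        raise ValueError(f"band {band} must be ordered low <= high")
    if sapi_percent < 0:
        raise ValueError("sapi_percent must be >= 0")
    if low <= sapi_percent <= high:
        return QualityClass.QUALITY_ASSURED
    return QualityClass.SUBSTANDARD


@dataclass
class QuantReport:
    """Per-brand quantitation summary."""

    brand: str
    component: str
    sample_ids: list
    y_true: np.ndarray        # % of label (reference assay)
    y_cv: np.ndarray          # LOOCV-predicted % of label
    r2: float
    resid_sd: float
    coverage_factor: float
    band: tuple
    predicted_class: list = field(default_factory=list)

    @property
    def coverage_halfwidth(self) -> float:
        return coverage_halfwidth(self.resid_sd, self.coverage_factor)

    @property
    def residuals(self) -> np.ndarray:
        return self.y_cv - self.y_true

    def to_dict(self) -> dict:
        return {
            "brand": self.brand,
            "component": self.component,
            "n": len(self.sample_ids),
            "r2": self.r2,
            "resid_sd": self.resid_sd,
            "coverage_factor": self.coverage_factor,
            "coverage_halfwidth": self.coverage_halfwidth,
            "band": list(self.band),
            "samples": [
                {
                    "sample_id": sid,
                    "sapi_true": float(t),
                    "sapi_cv": float(p),
                    "residual": float(p - t),
                    "predicted_class": cls.value,
                }
                for sid, t, p, cls in zip(
                    self.sample_ids, self.y_true, self.y_cv, self.predicted_class
                )
            ],
        }


def quantify_brand(
    records,
    component: str,
    a: int = 3,
    band=DEFAULT_TOLERANCE_BAND,
    coverage_factor: float = 2.0,
    pre_config: PreprocessConfig = PreprocessConfig(),
) -> QuantReport:
    """End-to-end per-brand quantitation.

    Preprocess each sample's scans through the quantitative pipeline,
    LOOCV-predict the component's % of label, and classify every
    prediction against the tolerance band.
    """
    records = [r for r in records if component in r.sapi_percent]
    if len(records) < a + 2:
        raise ValueError(
            f"need at least a+2={a + 2} samples with {component!r} ground truth, "
            f"got {len(records)}"
        )
    brands = {r.brand for r in records}
    if len(brands) != 1:
        raise ValueError(f"records span multiple brands: {sorted(brands)}")
    spectra = [preprocess_quantitative(r.scans, pre_config) for r in records]
    X = np.vstack([s.values for s in spectra])
    y = np.array([r.sapi_percent[component] for r in records], float)
    y_cv = loocv_predict(X, y, a)
    return QuantReport(
        brand=brands.pop(),
        component=component,
        sample_ids=[r.sample_id for r in records],
        y_true=y,
        y_cv=y_cv,
        r2=r_squared(y, y_cv),
        resid_sd=normalized_residual_sd(y, y_cv),
        coverage_factor=coverage_factor,
        band=tuple(band),
        # a negative predicted content means "no detectable API": floor at 0
        predicted_class=[tolerance_classify(max(v, 0.0), band) for v in y_cv],
    )
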