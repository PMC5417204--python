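"""Falsified-medicine detection by spectral library matching.

A brand's library entry is a PCA subspace of its quality-assured
second-derivative spectra plus the score mean and (shrunken) covariance;
a test spectrum is accepted as genuine iff its Mahalanobis distance in
score space does not exceed a chi-square-quantile threshold.

Falsified samples are never allowed into a training set, and quality-
assured samples are evaluated with the batch under test excluded from
training (leave-batch-out cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .preprocess import PreprocessConfig, preprocess_qualitative
from .spectra import QualityClass, SampleSet, Spectrum, SpectrumState

__all__ = [
    "ClassModel",
    "Verdict",
    "SensSpec",
    "AuthenticateConfig",
    "fit_class_model",
    "mahalanobis_distance",
    "calibrate_threshold",
    "classify",
    "leave_batch_out_evaluate",
    "pca_scores",
]


@dataclass
class ClassModel:
    """Trained library entry for one brand."""

    grid: np.ndarray          # wavelength grid (nm)
    projection: np.ndarray    # k x p, orthonormal rows
    center: np.ndarray        # length-p training mean (second-derivative space)
    mean: np.ndarray          # length-k score mean
    covariance: np.ndarray    # k x k, positive definite
    threshold: float
    k: int
    training_manifest: list = field(default_factory=list)  # (sample_id, batch_id)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.projection = np.atleast_2d(np.asarray(self.projection, float))
        self.center = np.asarray(self.center, float)
        self.mean = np.atleast_1d(np.asarray(self.mean, float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, float))
        gram = self.projection @ self.projection.T
        if not np.allclose(gram, np.eye(self.k), atol=1e-10):
            raise ValueError("projection rows must be orthonormal")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        try:
            self._chol = cho_factor(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    def score(self, spectrum: Spectrum) -> np.ndarray:
        _check_input(spectrum, self.grid)
        return self.projection @ (spectrum.values - self.center)


@dataclass(frozen=True)
class Verdict:
    """Audit-friendly classification result."""

    accepted: bool
    distance: float
    threshold: float

    @property
    def label(self) -> str:
        return "genuine" if self.accepted else "suspect"


@dataclass
class SensSpec:
    """Confusion counts with the falsified class as positive."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            return float("nan")
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            return float("nan")
        return 100.0 * self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class AuthenticateConfig:
    variance_kept: float = 0.99
    shrinkage: float = 0.05
    threshold_quantile: float = 0.99
    preprocess: PreprocessConfig = PreprocessConfig()


def _check_input(spectrum: Spectrum, grid: np.ndarray) -> None:
    if spectrum.state is not SpectrumState.SECOND_DERIVATIVE:
        raise ValueError(
            f"library matching requires second-derivative spectra, got {spectrum.state.value}"
        )
    if spectrum.wavelengths.size != grid.size or not np.array_equal(spectrum.wavelengths, grid):
        raise ValueError("spectrum grid does not match the model grid")


def calibrate_threshold(k: int, quantile: float = 0.99) -> float:
    """Distance threshold d* = sqrt(chi²_k quantile)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.sqrt(chi2.ppf(quantile, df=k)))


def fit_class_model(
    spectra,
    batch_ids,
    variance_kept: float = 0.99,
    shrinkage: float = 0.05,
    threshold_quantile: float = 0.99,
    sample_ids=None,
    quality_classes=None,
) -> ClassModel:
    """Fit a library entry from quality-assured second-derivative spectra.

    The PCA rank ``k`` is the smallest number of axes explaining at least
    ``variance_kept`` of the training variance, capped at ``n - 2``. The
    score covariance is shrunk toward a scaled identity:
    ``Σ ← (1 - γ)·Σ + γ·trace(Σ)/k·I``.

    Raises if any input is labeled falsified — falsified samples never
    enter a training set.
    """
    spectra = list(spectra)
    n = len(spectra)
    if n < 3:
        raise ValueError(f"need at least 3 training spectra, got {n}")
    batch_ids = list(batch_ids)
    if len(batch_ids) != n:
        raise ValueError("batch_ids must align with spectra")
    if quality_classes is not None:
        for i, qc in enumerate(quality_classes):
            if QualityClass(qc) is QualityClass.FALSIFIED:
                raise ValueError(
                    f"training input {i} is labeled falsified; falsified samples "
                    "are excluded from all training sets"
                )
    if not 0.0 < variance_kept <= 1.0:
        raise ValueError("variance_kept must lie in (0, 1]")
    if not 0.0 <= shrinkage < 1.0:
        raise ValueError("shrinkage must lie in [0, 1)")
    grid = spectra[0].wavelengths
    for s in spectra:
        _check_input(s, grid)
    X = np.vstack([s.values for s in spectra])
    center = X.mean(axis=0)
    Xc = X - center
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    ev = svals**2 / (n - 1)
    total = ev.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("training spectra show no variation; cannot fit a covariance")
    cum = np.cumsum(ev) / total
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = max(1, min(k, n - 2, int(np.sum(ev > total * 1e-12))))
    projection = vt[:k]
    scores = Xc @ projection.T
    mu = scores.mean(axis=0)
    sigma = np.atleast_2d(np.cov(scores, rowvar=False, ddof=1))
    sigma = (1.0 - shrinkage) * sigma + shrinkage * (np.trace(sigma) / k) * np.eye(k)
    if sample_ids is None:
        sample_ids = [s.meta.get("sample_id", f"train-{i}") for i, s in enumerate(spectra)]
    manifest = list(zip(sample_ids, batch_ids))
    return ClassModel(
        grid=grid,
        projection=projection,
        center=center,
        mean=mu,
        covariance=sigma,
        threshold=calibrate_threshold(k, threshold_quantile),
        k=k,
        training_manifest=manifest,
    )


def mahalanobis_distance(spectrum: Spectrum, model: ClassModel) -> float:
    """d = sqrt((s - μ)ᵀ Σ⁻¹ (s - μ)) with s the PCA score of the spectrum."""
    dev = model.score(spectrum) - model.mean
    d2 = float(dev @ cho_solve(model._chol, dev))
    return float(np.sqrt(max(d2, 0.0)))


def classify(spectrum: Spectrum, model: ClassModel) -> Verdict:
    """Accept as genuine iff d <= threshold (boundary counts as genuine)."""
    d = mahalanobis_distance(spectrum, model)
    return Verdict(accepted=d <= model.threshold, distance=d, threshold=model.threshold)


def _fit_from_records(records, config: AuthenticateConfig) -> ClassModel:
    spectra = [preprocess_qualitative(r.scans, config.preprocess) for r in records]
    return fit_class_model(
        spectra,
        batch_ids=[r.batch_id for r in records],
        variance_kept=config.variance_kept,
        shrinkage=config.shrinkage,
        threshold_quantile=config.threshold_quantile,
        sample_ids=[r.sample_id for r in records],
        quality_classes=[r.quality_class for r in records],
    )


def leave_batch_out_evaluate(
    samples: SampleSet,
    brand: str,
    config: AuthenticateConfig = AuthenticateConfig(),
    return_details: bool = False,
):
    """Leave-batch-out evaluation of one brand's library-matching classifier.

    Every quality-assured sample is classified by a model trained on the
    brand's quality-assured samples from *other* batches; every falsified
    sample is classified by a model trained on *all* quality-assured
    samples. Positive = rejection of a falsified sample.
    """
    qa = samples.select(brand=brand, quality_class=QualityClass.QUALITY_ASSURED)
    falsified = samples.select(brand=brand, quality_class=QualityClass.FALSIFIED)
    if not qa and not falsified:
        raise ValueError(f"no evaluable samples for brand {brand!r}")
    batches = sorted({r.batch_id for r in qa})
    if qa and len(batches) < 2:
        raise ValueError(
            f"brand {brand!r} has a single quality-assured batch; "
            "leave-batch-out cross-validation needs at least 2"
        )
    result = SensSpec()
    details = []
    for batch in batches:
        train = [r for r in qa if r.batch_id != batch]
        test = [r for r in qa if r.batch_id == batch]
        model = _fit_from_records(train, config)
        for rec in test:
            verdict = classify(preprocess_qualitative(rec.scans, config.preprocess), model)
            if verdict.accepted:
                result.tn += 1
            else:
                result.fp += 1
            details.append((rec.sample_id, rec.quality_class.value, verdict))
    if falsified:
        full_model = _fit_from_records(qa, config)
        for rec in falsified:
            verdict = classify(preprocess_qualitative(rec.scans, config.preprocess), full_model)
            if verdict.accepted:
                result.fn += 1
            else:
                result.tp += 1
            details.append((rec.sample_id, rec.quality_class.value, verdict))
    if return_details:
        return result, details
    return result


def pca_scores(spectra, n_components: int):
    """Scores of mean-centered spectra on the top principal axes.

    Returns ``(scores, explained_variance_fractions)``; fractions are
    non-increasing.
    """
    spectra = list(spectra)
    n = len(spectra)
    if n < 2:
        raise ValueError("need at least 2 spectra for PCA")
    grid = spectra[0].wavelengths
    for s in spectra:
        if not s.same_grid(spectra[0]):
            raise ValueError("all spectra must share one grid")
    p = grid.size
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    X = np.vstack([s.values for s in spectra])
    Xc = X - X.mean(axis=0)
    u, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    ev = svals**2
    frac = ev[:n_components] / ev.sum()
    scores = Xc @ vt[:n_components].T
    return scores, frac
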