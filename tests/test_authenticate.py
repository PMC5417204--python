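import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import chi2

from nirscreen.authenticate import (
    AuthenticateConfig,
    ClassModel,
    SensSpec,
    _fit_from_records,
    calibrate_threshold,
    classify,
    fit_class_model,
    leave_batch_out_evaluate,
    mahalanobis_distance,
    pca_scores,
)
from nirscreen.preprocess import preprocess_qualitative
from nirscreen.scenarios import SEPARABLE_AUTH, combo_brand_library
from nirscreen.spectra import QualityClass, SampleSet, Spectrum, SpectrumState
from nirscreen.synthetic_data import generate_library

from conftest import small_library_config


def d2_spectrum(values, grid=None, **meta):
    values = np.asarray(values, float)
    g = np.arange(values.size, dtype=float) if grid is None else grid
    return Spectrum(g, values, SpectrumState.SECOND_DERIVATIVE, meta)


def make_training_set(rng, n=10, p=6, rank=3):
    """Random spectra whose variation spans a `rank`-dim subspace."""
    basis = rng.normal(size=(rank, p))
    coords = rng.normal(size=(n, rank))
    X = coords @ basis + rng.normal(2.0, 0.1, size=p)
    return [d2_spectrum(x) for x in X], X


class TestFitClassModel:
    def test_falsified_input_is_hard_error(self, grid, rng):
        spectra, _ = make_training_set(rng)
        with pytest.raises(ValueError, match="falsified.*excluded"):
            fit_class_model(
                spectra,
                batch_ids=["b"] * len(spectra),
                quality_classes=[QualityClass.QUALITY_ASSURED] * 9
                + [QualityClass.FALSIFIED],
            )

    def test_too_few_spectra_rejected(self, rng):
        spectra, _ = make_training_set(rng, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            fit_class_model(spectra, batch_ids=["b", "b"])

    def test_identical_spectra_rejected(self):
        spectra = [d2_spectrum(np.ones(6)) for _ in range(5)]
        with pytest.raises(ValueError, match="no variation"):
            fit_class_model(spectra, batch_ids=["b"] * 5)

    def test_k_capped_at_n_minus_2(self, rng):
        spectra, _ = make_training_set(rng, n=5, p=20, rank=10)
        model = fit_class_model(spectra, batch_ids=["b"] * 5, variance_kept=0.999999)
        assert 1 <= model.k <= 3

    def test_projection_rows_orthonormal(self, rng):
        spectra, _ = make_training_set(rng)
        model = fit_class_model(spectra, batch_ids=["b"] * 10)
        gram = model.projection @ model.projection.T
        np.testing.assert_allclose(gram, np.eye(model.k), atol=1e-10)

    def test_covariance_positive_definite(self, rng):
        spectra, _ = make_training_set(rng)
        model = fit_class_model(spectra, batch_ids=["b"] * 10)
        assert np.all(np.linalg.eigvalsh(model.covariance) > 0)


class TestMahalanobisDistance:
    def manual_model(self, mean, cov, projection, center, threshold=3.0):
        k = len(mean)
        return ClassModel(
            grid=np.arange(np.shape(projection)[1], dtype=float),
            projection=projection,
            center=center,
            mean=mean,
            covariance=cov,
            threshold=threshold,
            k=k,
        )

    def test_distance_zero_at_mean(self, rng):
        spectra, X = make_training_set(rng)
        model = fit_class_model(spectra, batch_ids=["b"] * 10)
        at_mean = d2_spectrum(model.center)
        assert mahalanobis_distance(at_mean, model) == pytest.approx(0.0, abs=1e-8)

    def test_one_dimensional_z_score(self):
        # k=1, sigma^2=4, score at mu+4 -> d = 2
        model = self.manual_model(
            mean=np.array([1.0]),
            cov=np.array([[4.0]]),
            projection=np.array([[1.0, 0.0]]),
            center=np.zeros(2),
        )
        spec = d2_spectrum([5.0, 0.0])  # score = 5 = mu + 4
        assert mahalanobis_distance(spec, model) == pytest.approx(2.0, abs=1e-12)

    def test_two_by_two_brute_force(self):
        # oracle: invert sigma explicitly and form the quadratic form
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        dev = np.array([1.0, 1.0])
        d_oracle = np.sqrt(dev @ np.linalg.inv(cov) @ dev)
        assert d_oracle == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        model = self.manual_model(
            mean=np.zeros(2),
            cov=cov,
            projection=np.eye(2),
            center=np.zeros(2),
        )
        spec = d2_spectrum(dev)
        assert mahalanobis_distance(spec, model) == pytest.approx(d_oracle, abs=1e-12)

    def test_wrong_state_rejected(self, rng):
        spectra, _ = make_training_set(rng)
        model = fit_class_model(spectra, batch_ids=["b"] * 10)
        wrong = Spectrum(model.grid, model.center, SpectrumState.ABSORBANCE)
        with pytest.raises(ValueError, match="second-derivative"):
            mahalanobis_distance(wrong, model)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_brute_force_oracle_equivalence(self, k, rng):
        # distances via the fitted model == pseudo-inverse Mahalanobis on
        # the full covariance, for test points within the training span
        spectra, X = make_training_set(rng, n=10, p=7, rank=k)
        model = fit_class_model(
            spectra, batch_ids=["b"] * 10, variance_kept=1.0, shrinkage=0.0
        )
        assert model.k == k
        mean = X.mean(axis=0)
        cov_full = np.cov(X, rowvar=False, ddof=1)
        pinv = np.linalg.pinv(cov_full, rcond=1e-10)
        for i in range(10):
            dev = X[i] - mean
            d_oracle = np.sqrt(dev @ pinv @ dev)
            d_model = mahalanobis_distance(d2_spectrum(X[i]), model)
            assert d_model == pytest.approx(d_oracle, abs=1e-8)

    def test_affine_invariance(self, rng):
        # invertible linear map of the spectra leaves distances unchanged
        # (shrinkage 0, full variance kept, rank-2 variation)
        spectra, X = make_training_set(rng, n=8, p=6, rank=2)
        A = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        assert np.linalg.matrix_rank(A) == 6
        mapped = [d2_spectrum(A @ x) for x in X]
        m1 = fit_class_model(spectra, ["b"] * 8, variance_kept=1.0, shrinkage=0.0)
        m2 = fit_class_model(mapped, ["b"] * 8, variance_kept=1.0, shrinkage=0.0)
        assert m1.k == m2.k == 2
        for x in X:
            d1 = mahalanobis_distance(d2_spectrum(x), m1)
            d2 = mahalanobis_distance(d2_spectrum(A @ x), m2)
            assert d2 == pytest.approx(d1, abs=1e-8)


class TestCalibrateThreshold:
    def test_one_sigma_for_k1(self):
        assert calibrate_threshold(1, 0.6827) == pytest.approx(1.0, abs=1e-3)

    def test_closed_form_chi2_k2(self):
        # chi^2_2 quantile has closed form -2 ln(1-q); cross-check the
        # numerical quantile routine against it
        for q in (0.5, 0.9, 0.99):
            closed = np.sqrt(-2.0 * np.log(1.0 - q))
            assert calibrate_threshold(2, q) == pytest.approx(closed, rel=1e-10)
            numeric = brentq(lambda d: chi2.cdf(d**2, 2) - q, 0.01, 20.0)
            assert closed == pytest.approx(numeric, rel=1e-8)

    def test_monotone_in_quantile(self):
        qs = [0.5, 0.9, 0.99, 0.999, 0.999999]
        ds = [calibrate_threshold(3, q) for q in qs]
        assert all(a < b for a, b in zip(ds, ds[1:]))

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_quantile(self, q):
        with pytest.raises(ValueError, match="quantile"):
            calibrate_threshold(2, q)

    def test_invalid_k(self):
        with pytest.raises(ValueError, match="k"):
            calibrate_threshold(0, 0.99)


class TestClassify:
    @pytest.fixture
    def model(self, rng):
        spectra, _ = make_training_set(rng)
        return fit_class_model(spectra, batch_ids=["b"] * 10)

    def test_training_mean_accepted(self, model):
        verdict = classify(d2_spectrum(model.center), model)
        assert verdict.accepted
        assert verdict.label == "genuine"

    def test_tie_at_threshold_accepts(self):
        model = ClassModel(
            grid=np.arange(2, dtype=float),
            projection=np.array([[1.0, 0.0]]),
            center=np.zeros(2),
            mean=np.zeros(1),
            covariance=np.eye(1),
            threshold=2.0,
            k=1,
        )
        verdict = classify(d2_spectrum([2.0, 0.0]), model)  # d exactly 2.0
        assert verdict.distance == pytest.approx(model.threshold, abs=1e-12)
        assert verdict.accepted

    def test_falsified_rejected_in_separable_regime(self):
        lib = generate_library(small_library_config(seed=3))
        qa = lib.select(quality_class=QualityClass.QUALITY_ASSURED)
        model = _fit_from_records(qa, AuthenticateConfig())
        for rec in lib.select(quality_class=QualityClass.FALSIFIED):
            verdict = classify(preprocess_qualitative(rec.scans), model)
            assert not verdict.accepted


class TestLeaveBatchOut:
    def test_sens_spec_conserve_counts(self):
        lib = generate_library(small_library_config())
        ss = leave_batch_out_evaluate(lib, "TOY")
        assert ss.total == len(lib.records)

    def test_single_qa_batch_refused(self):
        lib = generate_library(small_library_config(qa_batches=1, qa_samples=4))
        with pytest.raises(ValueError, match="single quality-assured batch"):
            leave_batch_out_evaluate(lib, "TOY")

    def test_no_samples_errors(self, small_library):
        with pytest.raises(ValueError, match="no evaluable"):
            leave_batch_out_evaluate(small_library, "NOSUCH")

    def test_no_falsified_gives_nan_sensitivity(self):
        lib = generate_library(small_library_config(falsified_samples=0))
        ss = leave_batch_out_evaluate(lib, "TOY")
        assert np.isnan(ss.sensitivity)
        assert ss.specificity == 100.0

    def test_exclusion_audit(self):
        # no model's manifest contains the test batch (QA) or any
        # falsified sample
        lib = generate_library(small_library_config())
        falsified_ids = {
            r.sample_id for r in lib.select(quality_class=QualityClass.FALSIFIED)
        }
        qa = lib.select(quality_class=QualityClass.QUALITY_ASSURED)
        batches = sorted({r.batch_id for r in qa})
        cfg = AuthenticateConfig()
        for batch in batches:
            model = _fit_from_records([r for r in qa if r.batch_id != batch], cfg)
            manifest_batches = {b for _, b in model.training_manifest}
            manifest_ids = {s for s, _ in model.training_manifest}
            assert batch not in manifest_batches
            assert not (manifest_ids & falsified_ids)

    def test_specificity_high_when_all_qa(self):
        # chi-square 0.99 threshold covers nearly all QA samples
        lib = generate_library(small_library_config(qa_batches=3, qa_samples=30,
                                                    falsified_samples=0))
        ss = leave_batch_out_evaluate(lib, "TOY")
        assert ss.specificity >= 99.0

    def test_separable_regime_recovery_over_seeds(self):
        # sensitivity = specificity = 100 % in every run across seeds
        for seed in range(112, 117):
            lib = generate_library(combo_brand_library(seed, qa_batches=6,
                                                       qa_samples=18,
                                                       falsified_batches=2,
                                                       falsified_samples=6))
            ss = leave_batch_out_evaluate(lib, "BRAND-A", SEPARABLE_AUTH)
            assert ss.sensitivity == 100.0
            assert ss.specificity == 100.0


class TestPCAScores:
    @pytest.fixture
    def spectra(self, rng):
        spectra, _ = make_training_set(rng, n=12, p=8, rank=4)
        return spectra

    def test_scores_are_centered(self, spectra):
        scores, _ = pca_scores(spectra, 3)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_full_reconstruction(self, rng):
        spectra, X = make_training_set(rng, n=6, p=4, rank=4)
        n_comp = min(len(spectra) - 1, 4)
        scores, _ = pca_scores(spectra, n_comp)
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        recon = scores @ vt[:n_comp]
        np.testing.assert_allclose(recon, Xc, atol=1e-9)

    def test_explained_variance_non_increasing(self, spectra):
        _, frac = pca_scores(spectra, 4)
        assert all(a >= b for a, b in zip(frac, frac[1:]))
        assert frac.sum() <= 1.0 + 1e-12

    def test_too_many_components_rejected(self, spectra):
        with pytest.raises(ValueError, match="n_components"):
            pca_scores(spectra, 12)


class TestSensSpec:
    def test_formulas(self):
        ss = SensSpec(tp=8, fp=1, tn=9, fn=2)
        assert ss.sensitivity == pytest.approx(80.0)
        assert ss.specificity == pytest.approx(90.0)
        assert ss.total == 20
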